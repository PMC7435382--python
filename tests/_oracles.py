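"""Independent numerical oracles used by the test suite (kept separate from
the implementation paths they check)."""
import numpy as np


def solve_longdouble(M, b):
    """Gaussian elimination with partial pivoting in extended precision
    (numpy.linalg does not accept longdouble)."""
    M, b = M.copy(), b.copy()
    n = M.shape[0]
    for k in range(n):
        p = k + int(np.argmax(np.abs(M[k:, k])))
        M[[k, p]], b[[k, p]] = M[[p, k]], b[[p, k]]
        for i in range(k + 1, n):
            f = M[i, k] / M[k, k]
            M[i, k:] -= f * M[k, k:]
            b[i] -= f * b[k]
    x = np.zeros(n, dtype=np.longdouble)
    for k in range(n - 1, -1, -1):
        x[k] = (b[k] - M[k, k + 1:] @ x[k + 1:]) / M[k, k]
    return x


def normal_equations_oracle(A, y):
    """Explicit normal-equations least-squares solution computed in extended
    precision, so comparison error is attributable to the implementation."""
    Al, yl = A.astype(np.longdouble), y.astype(np.longdouble)
    return np.asarray(solve_longdouble(Al.T @ Al, Al.T @ yl), dtype=float)
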