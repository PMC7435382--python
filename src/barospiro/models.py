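"""Regression families mapping differential mask pressure x (Pa) to
airflow y (L/s).

Three families are provided, mirroring the calibration study design:

* **Root models** — physically motivated bases built on the orifice law.
  The positive branch (x > 0) is fitted on {x, 1, x^1/2, x^1/3, x^1/4} and
  the negative branch separately on the same basis in (−x); variants
  activate subsets: ``root2only`` (square-root term only, the ideal-orifice
  shape), ``root2`` (adds linear + intercept), ``root3`` (adds cube root),
  ``root4`` (all five terms).
* **Polynomial models** — a single degree-2..5 polynomial over the full
  signed range, coefficients ordered constant-first (p1 = constant term).
* **MLP** — a 1-N-1 feed-forward network (sigmoid hidden layer, linear
  output) trained with Levenberg–Marquardt on standardized data, with a
  random 70/15/15 train/validation/test split and validation-based early
  stopping.

Linear fits use ordinary linear least squares; the robust option is the
least-absolute-residual criterion via iteratively reweighted least squares
(weights 1/max(|r|, 1e-6)).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .traces import ConditionedPair

__all__ = [
    "RootModel",
    "PolyModel",
    "MlpModel",
    "FitReport",
    "ROOT_VARIANTS",
    "fit_root",
    "fit_poly",
    "fit_mlp",
    "fit_by_name",
    "predict",
    "gof_rmse",
    "is_monotone",
    "model_to_dict",
    "model_from_dict",
]

#: basis exponents matching coefficient order (a, b, c, d, e)
_ROOT_EXPONENTS = (1.0, 0.0, 0.5, 1.0 / 3.0, 0.25)
#: active coefficient indices per variant
ROOT_VARIANTS: dict[str, tuple[int, ...]] = {
    "root2only": (2,),
    "root2": (0, 1, 2),
    "root3": (0, 1, 2, 3),
    "root4": (0, 1, 2, 3, 4),
}

_RMIN = 1e-6  # LAR residual floor
_IRLS_TOL = 1e-8
_IRLS_MAX = 50


def _xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, ConditionedPair):
        return pairs.dp, pairs.flow
    x, y = pairs
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


@dataclass
class FitReport:
    model: object
    rmse_gof: float
    n_samples: int
    robust_iterations: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class RootModel:
    variant: str
    pos_coeffs: np.ndarray  # (a, b, c, d, e) for x >= 0
    neg_coeffs: np.ndarray  # (a, b, c, d, e) applied to (−x) for x < 0

    def __post_init__(self) -> None:
        if self.variant not in ROOT_VARIANTS:
            raise ValueError(f"unknown root variant {self.variant!r}")
        self.pos_coeffs = np.asarray(self.pos_coeffs, dtype=float)
        self.neg_coeffs = np.asarray(self.neg_coeffs, dtype=float)
        if self.pos_coeffs.shape != (5,) or self.neg_coeffs.shape != (5,):
            raise ValueError("coefficient vectors must have length 5")
        if not (np.all(np.isfinite(self.pos_coeffs)) and np.all(np.isfinite(self.neg_coeffs))):
            raise ValueError("coefficients must be finite")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x)
        pos = x >= 0  # the branch boundary x = 0 belongs to the positive side
        out[pos] = _root_design(x[pos]) @ self.pos_coeffs
        out[~pos] = _root_design(-x[~pos]) @ self.neg_coeffs
        return out


def _root_design(z: np.ndarray, active: Sequence[int] | None = None) -> np.ndarray:
    """Design matrix on nonnegative z; columns follow (a, b, c, d, e)."""
    cols = active if active is not None else range(5)
    return np.column_stack([np.power(z, _ROOT_EXPONENTS[i]) for i in cols])


@dataclass
class PolyModel:
    coeffs: np.ndarray  # (p1 .. p_{degree+1}), constant term first
    degree: int

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not 2 <= self.degree <= 5:
            raise ValueError("polynomial degree must be between 2 and 5")
        if self.coeffs.shape != (self.degree + 1,):
            raise ValueError("need degree+1 coefficients, constant first")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coeffs)


def _lstsq(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    # column scaling: basis columns (e.g. x vs x^5 over thousands of Pa)
    # span many orders of magnitude; rescaling is an exact reparametrization
    # that keeps the normal problem well-conditioned
    scale = np.max(np.abs(A), axis=0)
    scale[scale == 0.0] = 1.0
    As = A / scale
    if np.linalg.matrix_rank(As) < A.shape[1]:
        raise ValueError(
            "rank-deficient design matrix (e.g. all pressures identical); cannot fit"
        )
    return np.linalg.lstsq(As, y, rcond=None)[0] / scale


def _lar_irls(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Least-absolute-residual fit by iteratively reweighted least squares."""
    beta = _lstsq(A, y)
    for it in range(1, _IRLS_MAX + 1):
        r = np.abs(y - A @ beta)
        w = 1.0 / np.sqrt(np.maximum(r, _RMIN))  # sqrt of 1/|r| row weights
        beta_new = _lstsq(A * w[:, None], y * w)
        if np.max(np.abs(beta_new - beta)) < _IRLS_TOL:
            return beta_new, it
        beta = beta_new
    return beta, _IRLS_MAX


def _fit_branch(z: np.ndarray, y: np.ndarray, active: Sequence[int], robust: bool):
    A = _root_design(z, active)
    if robust:
        beta, its = _lar_irls(A, y)
    else:
        beta, its = _lstsq(A, y), 0
    full = np.zeros(5)
    full[list(active)] = beta
    return full, its


def fit_root(
    pairs, variant: str = "root4", robust: bool = False
) -> tuple[RootModel, FitReport]:
    """Fit a root-family model, positive and negative branches separately."""
    x, y = _xy(pairs)
    active = ROOT_VARIANTS[variant]
    pos, neg = x >= 0, x < 0
    k = len(active)
    if pos.sum() < 2 * k or neg.sum() < 2 * k:
        raise ValueError(
            f"variant {variant} needs at least {2 * k} samples on each sign branch"
        )
    pos_c, it_p = _fit_branch(x[pos], y[pos], active, robust)
    neg_c, it_n = _fit_branch(-x[neg], y[neg], active, robust)
    model = RootModel(variant=variant, pos_coeffs=pos_c, neg_coeffs=neg_c)
    return model, FitReport(
        model=model,
        rmse_gof=gof_rmse(model, (x, y)),
        n_samples=int(x.size),
        robust_iterations=max(it_p, it_n),
    )


def fit_poly(pairs, degree: int = 5, robust: bool = False) -> tuple[PolyModel, FitReport]:
    """Fit a single signed-range polynomial, constant coefficient first."""
    x, y = _xy(pairs)
    if not 2 <= degree <= 5:
        raise ValueError("polynomial degree must be between 2 and 5")
    if np.unique(x).size < degree + 2:
        raise ValueError(f"degree {degree} needs at least {degree + 2} distinct x values")
    A = np.column_stack([x**j for j in range(degree + 1)])
    if robust:
        beta, its = _lar_irls(A, y)
    else:
        beta, its = _lstsq(A, y), 0
    model = PolyModel(coeffs=beta, degree=degree)
    return model, FitReport(
        model=model, rmse_gof=gof_rmse(model, (x, y)), n_samples=int(x.size),
        robust_iterations=its,
    )


# ---------------------------------------------------------------------------
# neural network


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass
class MlpModel:
    """1-N-1 network: sigmoid hidden layer, linear output, standardized I/O."""

    hidden_units: int
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    x_mean: float
    x_std: float
    y_mean: float
    y_std: float
    warning: str = ""

    def _forward_std(self, xs: np.ndarray) -> np.ndarray:
        h = _sigmoid(np.outer(xs, self.w1) + self.b1)
        return h @ self.w2 + self.b2

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, dtype=float) - self.x_mean) / self.x_std
        return self._forward_std(xs) * self.y_std + self.y_mean


def _mlp_jacobian(xs, w1, b1, w2):
    h = _sigmoid(np.outer(xs, w1) + b1)  # (n, N)
    dh = h * (1.0 - h)
    J = np.concatenate(
        [w2 * dh * xs[:, None], w2 * dh, h, np.ones((xs.size, 1))], axis=1
    )
    return h, J


def fit_mlp(
    pairs,
    hidden_units: int = 7,
    seed: int = 0,
    patience: int = 6,
    max_iter: int = 1000,
    lambda0: float = 1e-3,
    init_scale: float = 0.5,
) -> tuple[MlpModel, FitReport]:
    """Train the 1-N-1 network with damped Gauss-Newton (Levenberg-Marquardt)
    steps on full-batch residuals.

    Inputs and targets are standardized; the data are split 70/15/15 into
    train/validation/test by a seeded shuffle; training stops when the
    validation MSE fails to improve for ``patience`` accepted steps (or at
    ``max_iter``); the best-validation weights are returned.  Deterministic
    for fixed (data, hidden_units, seed).
    """
    x, y = _xy(pairs)
    n = x.size
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    if n < 10:
        raise ValueError("need at least 10 samples for a 70/15/15 split")
    rng = np.random.default_rng(seed)
    x_mean, x_std = float(x.mean()), float(x.std()) or 1.0
    y_mean, y_std = float(y.mean()), float(y.std()) or 1.0
    xs, ys = (x - x_mean) / x_std, (y - y_mean) / y_std

    perm = rng.permutation(n)
    n_tr = int(round(0.70 * n))
    n_va = int(round(0.15 * n))
    idx_tr, idx_va, idx_te = perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:]

    N = hidden_units
    p = rng.uniform(-init_scale, init_scale, size=3 * N + 1)

    def unpack(p):
        return p[:N], p[N:2 * N], p[2 * N:3 * N], p[3 * N]

    def sse(p, idx):
        w1, b1, w2, b2 = unpack(p)
        pred = _sigmoid(np.outer(xs[idx], w1) + b1) @ w2 + b2
        return float(np.sum((ys[idx] - pred) ** 2))

    lam = lambda0
    warning = ""
    best_val = sse(p, idx_va) / max(idx_va.size, 1)
    best_p = p.copy()
    stall = 0
    val_history = [best_val]
    current = sse(p, idx_tr)
    for _ in range(max_iter):
        w1, b1, w2, b2 = unpack(p)
        h, J = _mlp_jacobian(xs[idx_tr], w1, b1, w2)
        r = ys[idx_tr] - (h @ w2 + b2)
        JtJ, Jtr = J.T @ J, J.T @ r
        accepted = False
        while lam < 1e10:
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), Jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = p + step
            trial_sse = sse(trial, idx_tr)
            if trial_sse < current:
                p, current, lam = trial, trial_sse, max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            warning = "damping overflow: returning best-validation weights"
            break
        val = sse(p, idx_va) / max(idx_va.size, 1)
        val_history.append(val)
        if val < best_val - 1e-15:
            best_val, best_p, stall = val, p.copy(), 0
        else:
            stall += 1
            if stall >= patience:
                break

    w1, b1, w2, b2 = unpack(best_p)
    model = MlpModel(
        hidden_units=N, w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(b2),
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std, warning=warning,
    )
    report = FitReport(
        model=model,
        rmse_gof=gof_rmse(model, (x, y)),
        n_samples=int(n),
        extras={
            "split": {"train": idx_tr.tolist(), "val": idx_va.tolist(), "test": idx_te.tolist()},
            "val_mse_history": val_history,
            "test_rmse": float(
                np.sqrt(np.mean((y[idx_te] - model.predict(x[idx_te])) ** 2))
            ) if idx_te.size else float("nan"),
        },
    )
    return model, report


# ---------------------------------------------------------------------------
# shared surface


def fit_by_name(pairs, name: str, robust: bool = False, seed: int = 0):
    """Dispatch on a model id: root2only..root4, poly2..poly5, ann1/3/5/7."""
    if name in ROOT_VARIANTS:
        return fit_root(pairs, variant=name, robust=robust)
    if name.startswith("poly"):
        return fit_poly(pairs, degree=int(name[4:]), robust=robust)
    if name.startswith("ann"):
        return fit_mlp(pairs, hidden_units=int(name[3:]), seed=seed)
    raise ValueError(f"unknown model id {name!r}")


def predict(model, dp: np.ndarray) -> np.ndarray:
    """Vectorized flow prediction (L/s) from differential pressure (Pa)."""
    dp = np.asarray(dp, dtype=float)
    if not np.all(np.isfinite(dp)):
        raise ValueError("differential pressure must be finite")
    if dp.size == 0:
        return np.empty(0)
    return model.predict(dp)


def gof_rmse(model, pairs) -> float:
    """Goodness of fit: RMSE between the reference flow and the model's
    prediction over the given samples."""
    x, y = _xy(pairs)
    if x.size == 0:
        raise ValueError("cannot evaluate goodness of fit on empty data")
    return float(np.sqrt(np.mean((y - model.predict(x)) ** 2)))


def is_monotone(model, lo: float, hi: float, n: int = 2001, tol: float = 1e-9) -> bool:
    """Diagnostic: is the fitted curve nondecreasing on [lo, hi]?  Polynomial
    fits in particular can lose monotonicity near the range edges."""
    grid = np.linspace(lo, hi, n)
    return bool(np.all(np.diff(model.predict(grid)) >= -tol))


def model_to_dict(model) -> dict:
    if isinstance(model, RootModel):
        return {
            "family": "root", "variant": model.variant,
            "pos_coeffs": model.pos_coeffs.tolist(), "neg_coeffs": model.neg_coeffs.tolist(),
        }
    if isinstance(model, PolyModel):
        return {"family": "poly", "degree": model.degree, "coeffs": model.coeffs.tolist()}
    if isinstance(model, MlpModel):
        return {
            "family": "mlp", "hidden_units": model.hidden_units,
            "w1": model.w1.tolist(), "b1": model.b1.tolist(),
            "w2": model.w2.tolist(), "b2": model.b2,
            "x_mean": model.x_mean, "x_std": model.x_std,
            "y_mean": model.y_mean, "y_std": model.y_std,
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(d: dict):
    fam = d["family"]
    if fam == "root":
        return RootModel(d["variant"], np.array(d["pos_coeffs"]), np.array(d["neg_coeffs"]))
    if fam == "poly":
        return PolyModel(np.array(d["coeffs"]), d["degree"])
    if fam == "mlp":
        return MlpModel(
            hidden_units=d["hidden_units"], w1=np.array(d["w1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=d["b2"], x_mean=d["x_mean"], x_std=d["x_std"],
            y_mean=d["y_mean"], y_std=d["y_std"],
        )
    raise ValueError(f"unknown model family {fam!r}")
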