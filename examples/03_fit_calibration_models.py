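"""Fit all three calibration families on one pooled cohort and compare
goodness of fit (RMSE between reference flow and prediction, L/s).

Expect the nested root variants to improve monotonically, polynomials and
the small networks to land in the same region once moderately complex —
beyond that, extra complexity buys little.
"""
import numpy as np

from barospiro.evaluation import prepare_sessions
from barospiro.models import fit_by_name, is_monotone
from barospiro.synth import SensorSpec, make_cohort, simulate_session

sessions = simulate_session(make_cohort(3, seed=7), SensorSpec.grade_a(), seed=7)
prep = prepare_sessions(sessions)
x = np.concatenate([p.pair.dp for p in prep])
y = np.concatenate([p.pair.flow for p in prep])
print(f"pooled training samples: {x.size}")
print()
print("model      gof RMSE (L/s)   monotone on data range")
for name in ("root2only", "root2", "root3", "root4",
             "poly2", "poly3", "poly4", "poly5", "ann1", "ann3", "ann5", "ann7"):
    model, report = fit_by_name((x, y), name, seed=7)
    mono = is_monotone(model, float(x.min()), float(x.max()))
    print(f"{name:10s} {report.rmse_gof:12.4f}     {mono}")
print()
print("A smaller RMSE means the curve tracks the pressure-flow cloud better;")
print("polynomials may lose monotonicity near the edges of the data range.")
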