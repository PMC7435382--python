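"""Extract per-maneuver FVC vitals and a flow-volume loop from predicted flow.

Flow is predicted from the conditioned differential pressure with a
subject-specific root4 calibration; breath segmentation then finds the
maneuvers and the clinical vitals are read off each one.
"""
import numpy as np

from barospiro.analytics import compute_fvc_vitals, flow_volume_loop, segment_breaths
from barospiro.evaluation import prepare_sessions
from barospiro.models import fit_root, predict
from barospiro.synth import SensorSpec, make_cohort, simulate_session
from barospiro.traces import FlowTrace

sessions = simulate_session(make_cohort(1, seed=9), SensorSpec.grade_a(), seed=9)
[prep] = prepare_sessions(sessions)
model, _ = fit_root(prep.pair, variant="root4")
flow = FlowTrace(times=prep.pair.grid_times, values=predict(model, prep.pair.dp))

segments = [s for s in segment_breaths(flow) if s.kind == "fvc"]
print(f"maneuvers found: {len(segments)}")
print()
print("maneuver   FVC (L)  FEV1 (L)  PEF (L/s)  FEF25 (L/s)  FIF25 (L/s)")
for i, seg in enumerate(segments):
    v = compute_fvc_vitals(flow, seg)
    print(f"{i:8d} {v.fvc:9.2f} {v.fev1:9.2f} {v.pef:10.2f} {v.fef25:12.2f} {v.fif25:12.2f}")

loop = flow_volume_loop(flow, segments[0])
np.savetxt("scratch_loop.csv", np.column_stack([loop.volume, loop.flow]),
           delimiter=",", header="volume_L,flow_Lps", comments="")
print()
print("first maneuver's flow-volume loop written to scratch_loop.csv")
print("(volume on x, flow on y: the clinical spirometry plot)")
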