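"""Derive IRV, ERV and IC from the respiration volume chart (documented
recipe, not a tested operation).

Combining forced maneuvers with tidal breathing lets further lung volumes
be read off the cumulative volume chart by selecting regions:

  IC  (inspiratory capacity)       = deep-inspiration depth below the
                                     tidal end-expiratory level;
  IRV (inspiratory reserve volume) = IC − tidal volume;
  ERV (expiratory reserve volume)  = FVC − IC.

Residual volume and total lung capacity are not measurable from flow alone.
"""
import numpy as np

from barospiro.analytics import cumulative_volume, segment_breaths
from barospiro.synth import SensorSpec, make_cohort, simulate_session

[session] = simulate_session(make_cohort(1, seed=21), SensorSpec.ideal(), seed=21,
                             reference_noise_sd=0.0, reference_offset=0.0)
flow = session.truth_flow
segs = segment_breaths(flow)
fvc_segs = [s for s in segs if s.kind == "fvc"]
tidal_segs = [s for s in segs if s.kind == "tidal"]

# mean tidal volume from the per-breath cumulative charts
tv = float(np.mean([cumulative_volume(flow, s).values.max() for s in tidal_segs]))

print("maneuver    FVC (L)   IC (L)   IRV (L)   ERV (L)")
for i, seg in enumerate(fvc_segs[:5]):
    vol = cumulative_volume(flow, seg)  # from expiratory onset
    fvc = float(vol.values.max())  # chart peak; the segment tail already re-inhales
    # the deep inspiration preceding the blast: volume excursion below the
    # tidal end-expiratory baseline
    sel = (flow.times >= seg.start_time) & (flow.times < seg.expiratory_onset)
    ic = float(-np.trapezoid(np.clip(flow.values[sel], None, 0.0), flow.times[sel]))
    print(f"{i:8d} {fvc:10.2f} {ic:8.2f} {ic - tv:9.2f} {fvc - ic:9.2f}")

print()
print(f"mean tidal volume: {tv:.2f} L")
print("IRV + TV + ERV reassembles the vital capacity, as on a volume chart.")
print("(The simulator's maneuvers are volume-balanced — the wearer inhales")
print("exactly what they exhale — so ERV is ~0 by construction here.)")
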