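"""Ideal-orifice pressure-to-flow model of the mask chamber.

Evaluates the frictionless closed form at a few chamber pressures.  The
'standard' variant uses the published coefficient 2.9 (L/s per sqrt(Pa));
the SI variant derives the flow from the stated air density and vent area.
Both illustrate the square-root shape that the regression calibration
assumes — neither is used for measurement.
"""
import numpy as np

from barospiro import ideal_flow_from_pressure, standard_flow_lps
from barospiro.orifice import ATMOSPHERIC_PRESSURE_PA

print("chamber P (Pa)   dP (Pa)   standard form (L/s)   SI model (L/s)")
for dp in (-400.0, -100.0, -1.0, 0.0, 1.0, 100.0, 400.0):
    p = ATMOSPHERIC_PRESSURE_PA + dp
    print(f"{p:14.0f} {dp:9.0f} {standard_flow_lps(p):15.3f} "
          f"{1000.0 * ideal_flow_from_pressure(p):17.3f}")

print()
print("The two columns differ by a constant factor: the printed coefficient")
print("2.9 understates the one re-derived from the stated area and density")
print(f"({2.826e-3 * np.sqrt(2 / 1.225) * 1000:.3f}); the discrepancy is kept as published, since the")
print("closed form only illustrates the shape that calibration later fits.")
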