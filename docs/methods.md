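# Methods

## The measurement model

A face mask with a vent is treated as a chamber with an orifice of area
S.  Bernoulli's relation for frictionless flow through the vent gives
ΔP = ½ρu² for the air speed u, hence a volumetric flow

    F = sign(ΔP) · S · √(2|ΔP|/ρ),    ΔP = P_inside − P_atmos.

With ρ = 1.225 kg/m³, P_atmos = 101,325 Pa and S = 2.826×10⁻³ m² the
litres-per-second closed form carries the coefficient 2.9.  That printed
coefficient is *not* what S and ρ re-derive to (S·√(2/ρ)·1000 ≈ 3.611);
`standard_flow_lps` keeps 2.9 verbatim (configurable) and the package
documents rather than resolves the discrepancy, because the closed form is
only an illustration of the square-root shape.  The piecewise form is
undefined at ΔP = 0; the implementation returns 0 there by continuity.

Real masks violate the ideal assumptions (friction, non-uniform chamber
pressure), so flow is measured by regression calibration: conditioned
differential pressure x (Pa) against reference spirometer flow y (L/s).

## Calibration families

* **Root models.** Separate fits for x > 0 and x < 0 on the basis
  {x, 1, x^1/2, x^1/3, x^1/4} (in −x on the negative branch); variants
  activate nested subsets (`root2only` = square-root term only, up to
  `root4` = all five).  x = 0 is assigned to the positive branch; the two
  branches are allowed to disagree at 0 (each may carry an intercept), as
  in the asymmetric formulation the design follows.
* **Polynomials.** One signed-range polynomial of degree 2–5, coefficients
  stored constant-first (p1 = constant).  Monotonicity is *not* enforced —
  polynomial calibrations genuinely lose it near the data-range edges — but
  an `is_monotone` diagnostic is provided.
* **Neural network.** A 1-N-1 feed-forward net (sigmoid hidden layer,
  linear output) on standardized inputs/targets, trained with
  Levenberg–Marquardt (damping λ₀ = 10⁻³, ×10 on a rejected step, ÷10 on an
  accepted one), a seeded 70/15/15 train/validation/test split, early
  stopping after 6 non-improving validation checks, at most 1000
  iterations, weights initialized uniform(−0.5, 0.5).  These training
  details are conventional choices, all exposed as parameters; the trainer
  is deterministic given (data, N, seed).

Least squares is solved by `numpy.linalg.lstsq` after exact column
rescaling (the basis spans many orders of magnitude over thousands of
pascals).  The robust option is the least-absolute-residual criterion via
iteratively reweighted least squares with weights 1/max(|r|, 10⁻⁶),
iterated to a 10⁻⁸ coefficient change or 50 rounds.

Units are fixed as x in Pa, y in L/s throughout.  Coefficient sets quoted
for masks of this kind are ambiguous about the underlying pressure unit;
the package fixes Pa and treats such sets as layout examples (and
generating truths for tests), not as reproduction targets.

## Signal conditioning

Order of operations: inside − outside (linear interpolation of the outside
trace onto the inside timestamps) → subtract the offset estimated as the
mean of the last 0.5 s (the protocol ends with the mask off, so true flow
is zero there) → zero-phase smoothing → two-sample-average downsampling
100 → 50 Hz → linear interpolation of pressure and offset-corrected
reference flow onto a shared 10 ms grid.  The reference flow receives
offset removal only (smoothing it as well is available but off by default).

"Zero-phase averaging with kernel 10" is implemented as a forward-backward
boxcar (`scipy.signal.filtfilt`, reflect padding of one kernel length): an
even-length single-pass boxcar cannot be zero-phase on its own grid, while
the forward-backward composition has an exactly symmetric impulse response
and unit DC gain.  The 10 ms grid is adopted as specified for the 50 Hz
instruments; the package follows it without endorsing the sampling-theorem
argument sometimes offered for it.

## FVC analytics

Breath boundaries are negative-to-positive flow reversals with a ±0.05 L/s
hysteresis band.  A segment is a forced maneuver when its peak expiratory
flow exceeds 3× the session's median segment peak; such segments are
widened backwards to the onset of the preceding maximal inspiration so the
flow-volume loop has both limbs.  Vitals: FVC = total expired volume
(trapezoid); PEF = maximum expiratory flow; FEV1 = volume at one second
after the back-extrapolated time zero (tangent at the steepest volume
slope — the standard spirometry convention); FEF25/FIF25 = expiratory/inspiratory flow magnitude, linearly
interpolated in volume, where 25% of the FVC has been exhaled/inhaled.
Maneuvers with under one second of expiration yield FEV1 = NaN rather than
a fabricated value.

Volume is reported two ways: a per-breath cumulative integral, and a
trailing sliding-window integral (0.5 s window, 10 ms step) that bounds
drift from long integration of a slightly biased flow signal.  The
window semantics (trailing, not centered) are a design choice; the δ
evaluation of tidal volume uses the sliding-window form.

## The δ metric and division schemes

δ = rmse(ref − pred) / max(range(ref), range(pred)).  The denominator range
is taken over the whole evaluated cohort by default (`range_scope =
"global"`), which is the published definition of the metric; a
fold/subject-local range is available as an option.  When a scheme yields
several models (per subject, or per held-out fold), per-model δ values are
aggregated by root mean square.  Exclusive folds come from a seeded shuffle
of subject ids into sizes as equal as possible; subjects, never samples,
are partitioned.

## The synthetic generator

The generator's purpose is to reproduce the statistical structure the
calibration assumes, with known ground truth:

* **Pressure truth.** Each subject's ΔP↔flow law is a root-family curve
  y = a·x + c·√x per sign branch (not the ideal orifice model — the
  empirically fitted gains are an order of magnitude below the theoretical
  coefficient, reflecting friction and non-uniformity).  Restricting the
  truth to the {linear, √} terms keeps a closed-form inverse, so sensor
  traces are generated exactly.  Per-subject gains vary by only a few
  percent around c⁺ ≈ 0.174 / c⁻ ≈ −0.137: the law is chiefly a property
  of the shared mask hardware, and a large spread would contradict the
  observation that pooled calibration performs close to individual
  calibration.
* **Waveforms.** Tidal breaths are paired half-sines moving exactly the
  tidal volume in each direction.  The forced maneuver is a maximal
  inspiratory half-sine followed by forced expiration.  Two expiration
  templates exist: an instant-rise exponential PEF·e^(−t/τ), whose vitals
  have closed forms (FVC = PEF·τ·(1−e^(−T/τ)), FEV1 = PEF·τ·(1−e^(−1/τ)),
  FEF25 = PEF − 0.25·FVC/τ, FIF25 = PIF·sin(π/3)) and which anchors the
  analytic tests; and the session default, a C¹ double-exponential
  A·(e^(−t/τ) − e^(−t/τr)) normalized to PEF (τr = 0.1 s, time-to-peak
  ≈ 0.2 s), whose ground-truth vitals are computed numerically at 1 kHz.
  The default is the smooth template because an instant-rise peak is a
  measure-zero spike that the zero-phase smoother annihilates, whereas
  real flow peaks are rounded on the ~0.2 s scale and survive kernel-10
  smoothing; per-maneuver effort jitters PEF and τ by ±10%.
* **Sensors.** Two presets mirror the two barometer datasheet grades:
  grade A (noise 0.2 Pa, resolution 0.18 Pa) and grade B (0.03 Pa,
  0.016 Pa), both at 100 Hz.  Corruption order: law-inverted pressure +
  constant per-sensor offset (uniform within ±50 Pa; inter-sensor
  manufacturing offsets are a known phenomenon of these barometers, but
  their magnitude is an assumed scale here) + Gaussian noise, then
  quantization by rounding to the resolution step.  The reference
  spirometer runs at 50 Hz with Gaussian noise of 0.02 L/s and a constant
  offset of 0.01 L/s (assumed values: reference spirometers do exhibit a
  constant zero-flow offset, of unstated size).
* **Sessions.** Ten maneuvers separated by five tidal cycles (both
  configurable), a closing tidal block, and a 1 s zero-flow mask-off tail.
  All randomness flows from a single seed through spawned generators;
  identical inputs give identical outputs.

What the generator does **not** emulate: airway mechanics (no
compliance/resistance dynamics, so maneuver shapes are templates rather
than effort-dependent physiology), clock drift between instruments,
temperature-driven sensor drift, motion artifacts, coughing or speech.
Passing tests therefore demonstrate that the processing chain is correct
and noise-robust under the assumed signal structure — not that the
hardware would achieve these margins on human subjects.

## Problem sizes and numerical choices

The validation cohorts use 6 subjects × 10 maneuvers (≈ 5 minutes of
100 Hz signal per subject), and the scheme-ordering property is averaged
over 20 seeded cohorts — sizes chosen so each property is measured well
away from its decision boundary while the whole suite stays quick.  The
end-to-end noise test asserts δ ≤ 0.05 for every vital and δ ≤ 0.03 for
sliding-window volume under grade-A noise with individual root4
calibration; these are suite thresholds for the generator's conditions,
in the same few-percent regime that differential-barometer spirometry
achieves against clinical references on human data.  Exactness tests
disable smoothing/downsampling and use noise-free sensors so the chain is
algebraically exact; the least-squares oracle is an explicit
normal-equations solve in extended precision.  Degenerate inputs (empty
series, all-zero flow, rank-deficient bases, zero δ ranges, too-short
traces) raise informative errors rather than returning numbers.

## Known limitations

* The breath segmenter assumes the session structure of the calibration
  protocol (clear tidal/forced contrast); free-living data with coughs or
  speech would need artifact rejection first.
* Polynomial calibrations extrapolate badly outside the fitted pressure
  range; use the root family when extrapolation is possible.
* The MLP trainer is full-batch and intended for the small 1-N-1
  architecture; it is not a general-purpose network trainer.
* δ is range-normalized and therefore cohort-dependent: comparing δ across
  differently composed cohorts is not meaningful.
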