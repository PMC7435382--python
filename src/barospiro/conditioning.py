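"""Preprocessing chain: differential pressure, offset removal, zero-phase
smoothing and rate alignment.

The raw measurand is the inside-minus-outside mask pressure.  Each sensor
carries a constant manufacturing offset, so the differential trace is
re-zeroed on the mask-off tail of the session (the last half second, when
true flow is exactly zero).  Smoothing uses a forward-backward boxcar —
a single even-length boxcar pass cannot be zero-phase on the same grid,
while the forward-backward composition has an exactly symmetric impulse
response and unit DC gain.  Pressure and reference flow finally meet on a
common uniform grid (10 ms by default) via linear interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy.signal import filtfilt

from .traces import ConditionedPair, FlowTrace, PressureTrace, Trace

__all__ = [
    "ConditioningConfig",
    "differential_pressure",
    "estimate_tail_offset",
    "zero_phase_smooth",
    "downsample_two_average",
    "make_conditioned_pair",
]


@dataclass(frozen=True)
class ConditioningConfig:
    tail_s: float = 0.5  # offset-estimation window at the end of the session
    kernel: int = 10  # boxcar length (samples); 1 disables smoothing
    grid_ms: float = 10.0  # common grid spacing for the (dp, flow) pairing
    downsample: bool = True  # two-sample-average 100 Hz -> 50 Hz before pairing
    smooth_flow: bool = False  # reference flow gets offset removal only by default


def differential_pressure(inside: PressureTrace, outside: PressureTrace) -> PressureTrace:
    """inside − outside, sample-wise on the inside trace's timestamps.

    The outside trace is linearly interpolated onto the inside timestamps
    (exact when both sensors share a clock, second-order otherwise); the
    result is restricted to the temporal overlap of the two traces.
    """
    t0 = max(inside.times[0], outside.times[0])
    t1 = min(inside.times[-1], outside.times[-1])
    if t0 >= t1:
        raise ValueError("inside and outside traces have no temporal overlap")
    sel = (inside.times >= t0 - 1e-12) & (inside.times <= t1 + 1e-12)
    times = inside.times[sel]
    diff = inside.values[sel] - np.interp(times, outside.times, outside.values)
    return PressureTrace(
        times=times,
        values=diff,
        sample_rate=inside.sample_rate,
        label=f"{inside.label or 'inside'}-{outside.label or 'outside'}",
    )


def estimate_tail_offset(trace: Trace, tail_duration: float = 0.5) -> float:
    """Mean of the samples in the trailing ``tail_duration`` seconds.

    The session protocol ends with the mask off, so the tail mean estimates
    the sensor's constant offset.
    """
    if trace.duration <= tail_duration:
        raise ValueError(
            f"trace duration {trace.duration:.3f}s must exceed the {tail_duration}s tail"
        )
    sel = trace.times > trace.times[-1] - tail_duration
    return float(trace.values[sel].mean())


def zero_phase_smooth(trace: Trace, kernel: int = 10) -> Trace:
    """Forward-backward boxcar of width ``kernel`` samples (zero phase,
    unit DC gain, reflect padding of one kernel length at the edges)."""
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if kernel == 1:
        return trace.with_values(trace.values.copy())
    if len(trace) <= 3 * kernel:
        raise ValueError(f"trace of {len(trace)} samples too short for kernel {kernel}")
    b = np.ones(kernel) / kernel
    smoothed = filtfilt(b, [1.0], trace.values, padtype="even", padlen=kernel)
    return trace.with_values(smoothed)


def downsample_two_average(trace: Trace) -> Trace:
    """Halve the rate by averaging non-overlapping sample pairs; output
    timestamps are the pair midpoints.  A trailing odd sample is dropped."""
    n = len(trace)
    if n % 2:
        warnings.warn("odd sample count: dropping the trailing sample", stacklevel=2)
        n -= 1
    t = trace.times[:n].reshape(-1, 2).mean(axis=1)
    v = trace.values[:n].reshape(-1, 2).mean(axis=1)
    rate = trace.sample_rate / 2.0 if trace.sample_rate else None
    return replace(trace, times=t, values=v, sample_rate=rate)


def make_conditioned_pair(
    inside: PressureTrace,
    outside: PressureTrace,
    reference_flow: FlowTrace,
    config: ConditioningConfig = ConditioningConfig(),
) -> ConditionedPair:
    """Full conditioning pipeline.

    Pressure path: difference -> subtract tail offset -> zero-phase smooth ->
    (optionally) two-sample-average downsample.  Flow path: subtract its own
    tail offset.  Both are then linearly interpolated onto a shared uniform
    grid covering the overlap of all inputs.
    """
    dp = differential_pressure(inside, outside)
    dp_offset = estimate_tail_offset(dp, config.tail_s)
    dp = dp.with_values(dp.values - dp_offset)
    dp = zero_phase_smooth(dp, config.kernel)
    if config.downsample:
        dp = downsample_two_average(dp)

    flow_offset = estimate_tail_offset(reference_flow, config.tail_s)
    flow = reference_flow.with_values(reference_flow.values - flow_offset)
    if config.smooth_flow:
        flow = zero_phase_smooth(flow, config.kernel)

    step = config.grid_ms / 1000.0
    t0 = max(dp.times[0], flow.times[0])
    t1 = min(dp.times[-1], flow.times[-1])
    if t0 >= t1:
        raise ValueError("pressure and flow traces have no temporal overlap")
    grid = np.arange(np.ceil(t0 / step - 1e-9), np.floor(t1 / step + 1e-9) + 0.5) * step
    return ConditionedPair(
        grid_times=grid,
        dp=np.interp(grid, dp.times, dp.values),
        flow=np.interp(grid, flow.times, flow.values),
        meta={"dp_offset": dp_offset, "flow_offset": flow_offset},
    )
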