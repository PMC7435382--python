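"""Breath segmentation, flow-volume loops and spirometry vitals.

Works on a signed flow signal (L/s, expiration positive).  A *breath
segment* spans one expiration and the inspiration that follows it; a
forced-vital-capacity (FVC) maneuver is recognised by its outsized peak
expiratory flow and is widened to include the maximal inspiration that
precedes the blast, so that both limbs of the flow-volume loop are
available.

Vitals follow the clinical definitions: FVC is the total expired volume,
PEF the maximum expiratory flow, FEV1 the volume expired within one second
of the back-extrapolated time zero (tangent at the steepest volume slope,
the standard spirometry convention), and FEF25/FIF25 the expiratory/
inspiratory flow magnitude at the instant 25% of the FVC has been
exhaled/inhaled.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .traces import FlowTrace

__all__ = [
    "BreathSegment",
    "FvcVitals",
    "FlowVolumeLoop",
    "VolumeTrace",
    "segment_breaths",
    "cumulative_volume",
    "sliding_window_volume",
    "flow_volume_loop",
    "compute_fvc_vitals",
]

#: Hysteresis half-band (L/s) around zero used when locating flow reversals.
HYSTERESIS_LPS = 0.05

VITAL_NAMES = ("fvc", "fev1", "pef", "fef25", "fif25")


@dataclass
class BreathSegment:
    kind: str  # "tidal" | "fvc"
    start_time: float
    end_time: float
    expiratory_onset: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("tidal", "fvc"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.start_time < self.end_time:
            raise ValueError("segment start must precede end")


@dataclass
class FvcVitals:
    fvc: float  # L
    fev1: float  # L (nan when < 1 s of expiration was recorded)
    pef: float  # L/s
    fef25: float  # L/s
    fif25: float  # L/s

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in VITAL_NAMES}


@dataclass
class FlowVolumeLoop:
    volume: np.ndarray  # L, cumulative expired volume from expiratory onset
    flow: np.ndarray  # L/s
    maneuver: BreathSegment


@dataclass
class VolumeTrace:
    times: np.ndarray
    values: np.ndarray  # L
    method: str  # "sliding_window" | "cumulative"


def _slice(flow: FlowTrace, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
    i0, i1 = np.searchsorted(flow.times, [t0, t1 + 1e-12])
    return flow.times[i0:i1], flow.values[i0:i1]


def _hysteresis_crossings(values: np.ndarray, band: float) -> tuple[list[int], list[int]]:
    """Indices where the signal leaves the -band state upward (neg->pos)
    and the +band state downward (pos->neg)."""
    up: list[int] = []
    down: list[int] = []
    state = 0  # -1 below -band, +1 above +band, 0 undecided
    for i, v in enumerate(values):
        if v > band:
            if state == -1:
                up.append(i)
            state = 1
        elif v < -band:
            if state == 1:
                down.append(i)
            state = -1
    return up, down


def segment_breaths(flow: FlowTrace, fvc_pef_threshold_factor: float = 3.0) -> list[BreathSegment]:
    """Split a session into breath segments and flag FVC maneuvers.

    Breath boundaries are negative-to-positive flow reversals (with a
    ±0.05 L/s hysteresis band); a segment is an FVC maneuver when its peak
    expiratory flow exceeds ``fvc_pef_threshold_factor`` times the session's
    median segment peak.  FVC segments are widened backwards to the onset of
    the preceding maximal inspiration (last positive-to-negative reversal),
    and the preceding segment is trimmed accordingly.
    """
    t, v = flow.times, flow.values
    up, down = _hysteresis_crossings(v, HYSTERESIS_LPS)
    if not up:
        return []

    bounds = up + [len(v) - 1]
    raw: list[tuple[int, int]] = [(bounds[i], bounds[i + 1]) for i in range(len(up))]
    peaks = np.array([v[i0:i1].max() for i0, i1 in raw])  # half-open: [onset_k, onset_{k+1})
    median_peak = float(np.median(peaks))
    is_fvc = peaks > fvc_pef_threshold_factor * median_peak

    segments: list[BreathSegment] = []
    down_arr = np.asarray(down)
    for k, (i0, i1) in enumerate(raw):
        if not is_fvc[k]:
            segments.append(BreathSegment("tidal", float(t[i0]), float(t[i1])))
            continue
        # expiratory onset: the reversal into positive flow opening the segment
        # (the last zero crossing before the segment's flow maximum)
        onset = float(t[i0])
        # widen to the start of the preceding deep inspiration
        prior_down = down_arr[down_arr < i0]
        start = float(t[prior_down[-1]]) if prior_down.size else float(t[i0])
        if segments and segments[-1].end_time > start:
            segments[-1].end_time = start
        segments.append(BreathSegment("fvc", start, float(t[i1]), expiratory_onset=onset))
    # drop any segment squeezed to nothing by the trimming
    return [s for s in segments if s.start_time < s.end_time]


def cumulative_volume(flow: FlowTrace, segment: BreathSegment) -> VolumeTrace:
    """Trapezoidal running integral (L) of flow from the segment's
    expiratory onset (or its start, for tidal segments)."""
    t0 = segment.expiratory_onset if segment.expiratory_onset is not None else segment.start_time
    t, v = _slice(flow, t0, segment.end_time)
    if t.size < 2:
        raise ValueError("segment contains fewer than two flow samples")
    vol = cumulative_trapezoid(v, t, initial=0.0)
    return VolumeTrace(times=t, values=vol, method="cumulative")


def sliding_window_volume(flow: FlowTrace, window: float = 0.5, step: float = 0.010) -> VolumeTrace:
    """Volume moved within the trailing ``window`` seconds, every ``step``.

    A short trailing-window integral avoids the drift that plagues
    open-ended integration of a slightly biased flow signal.
    """
    if flow.duration < window:
        raise ValueError("flow trace shorter than the integration window")
    grid = np.arange(np.ceil(flow.times[0] / step), np.floor(flow.times[-1] / step) + 0.5) * step
    grid = grid[grid - window >= flow.times[0] - 1e-12]
    # trailing-window trapezoid via the cumulative integral; linear
    # interpolation at off-grid endpoints is exact when the window is a
    # multiple of the sample spacing and second-order accurate otherwise
    cum = cumulative_trapezoid(flow.values, flow.times, initial=0.0)
    c_hi = np.interp(grid, flow.times, cum)
    c_lo = np.interp(grid - window, flow.times, cum)
    return VolumeTrace(times=grid, values=c_hi - c_lo, method="sliding_window")


def flow_volume_loop(flow: FlowTrace, segment: BreathSegment) -> FlowVolumeLoop:
    """Pair cumulative expired volume with instantaneous flow over a maneuver."""
    if segment.kind != "fvc":
        raise ValueError("flow-volume loops are defined for FVC maneuvers only")
    t, v = _slice(flow, segment.start_time, segment.end_time)
    if t.size < 2 or np.ptp(v) == 0.0:
        raise ValueError("degenerate maneuver: no flow excursion in segment")
    onset = segment.expiratory_onset if segment.expiratory_onset is not None else segment.start_time
    vol = cumulative_trapezoid(v, t, initial=0.0)
    vol -= np.interp(onset, t, vol)  # volume zero at expiratory onset
    return FlowVolumeLoop(volume=vol, flow=v, maneuver=segment)


def _crossing_flow(volume: np.ndarray, flow: np.ndarray, target: float) -> float:
    """Flow, linearly interpolated in volume, where cumulative volume first
    reaches ``target``."""
    idx = np.nonzero(volume >= target)[0]
    if idx.size == 0:
        return float("nan")
    i = int(idx[0])
    if i == 0 or volume[i] == volume[i - 1]:
        return float(flow[i])
    w = (target - volume[i - 1]) / (volume[i] - volume[i - 1])
    return float(flow[i - 1] + w * (flow[i] - flow[i - 1]))


def compute_fvc_vitals(flow: FlowTrace, segment: BreathSegment) -> FvcVitals:
    """Extract FVC, FEV1, PEF, FEF25 and FIF25 from one maneuver.

    The segment must contain the inspiratory limb (before the expiratory
    onset) and the expiratory blast.  FEV1 uses the back-extrapolated time
    zero: the tangent at the steepest volume slope (the PEF instant) is
    extended to the zero-volume axis.
    """
    if segment.kind != "fvc":
        raise ValueError("vitals are defined for FVC maneuvers only")
    onset = segment.expiratory_onset if segment.expiratory_onset is not None else segment.start_time
    t, v = _slice(flow, segment.start_time, segment.end_time)
    if t.size < 3:
        raise ValueError("maneuver segment too short")
    i_on = int(np.searchsorted(t, onset - 1e-12))

    # --- expiratory limb: from onset until flow reverses negative again
    # (searched after the peak, so a noisy near-zero onset cannot truncate it)
    te, ve = t[i_on:], v[i_on:]
    if te.size < 2:
        raise ValueError("no expiratory flow in maneuver segment")
    pk = int(np.argmax(ve))
    neg = np.nonzero(ve[pk:] < -HYSTERESIS_LPS)[0]
    if neg.size:
        te, ve = te[: pk + neg[0]], ve[: pk + neg[0]]
    vol = cumulative_trapezoid(ve, te, initial=0.0)
    fvc = float(vol[-1])
    ipk = int(np.argmax(ve))
    pef = float(ve[ipk])
    # back-extrapolated time zero
    t0 = te[ipk] - vol[ipk] / pef if pef > 0 else te[0]
    if te[-1] - t0 >= 1.0:
        fev1 = float(np.interp(t0 + 1.0, te, vol))
    else:
        fev1 = float("nan")  # expiration shorter than one second
    fef25 = _crossing_flow(vol, ve, 0.25 * fvc)

    # --- inspiratory limb: deep inhalation preceding the onset
    ti, vi = t[: i_on + 1], v[: i_on + 1]
    insp = vi < 0
    if np.any(insp):
        vol_in = cumulative_trapezoid(np.clip(-vi, 0.0, None), ti, initial=0.0)
        fif25 = _crossing_flow(vol_in, -vi, 0.25 * fvc)
    else:
        fif25 = float("nan")
    return FvcVitals(fvc=fvc, fev1=fev1, pef=pef, fef25=fef25, fif25=fif25)
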