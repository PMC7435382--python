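"""Synthetic breathing sessions with paired barometer and spirometer signals.

The generator emulates the statistical structure the calibration pipeline
assumes: a subject alternates blocks of tidal breathing with forced
vital-capacity (FVC) maneuvers, the mask's differential pressure follows a
monotone root-family law of the flow (the empirical shape of the
pressure-flow cloud, not the ideal orifice coefficient), each barometer
carries a constant per-sensor offset plus Gaussian noise and datasheet-grade
quantization, and the session ends with a mask-off stretch of exactly zero
flow from which offsets are later estimated.

Two sensor grades mirror the two barometer datasheets: grade A
(noise 0.2 Pa, resolution 0.18 Pa) and grade B (noise 0.03 Pa, resolution
0.016 Pa), both read out at 100 Hz.  The reference spirometer runs at 50 Hz
with its own small noise and constant offset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .analytics import BreathSegment, FvcVitals
from .orifice import ATMOSPHERIC_PRESSURE_PA
from .traces import FlowTrace, PressureTrace

__all__ = [
    "RootLaw",
    "SensorSpec",
    "SubjectProfile",
    "SessionDataset",
    "make_cohort",
    "simulate_tidal_flow",
    "simulate_fvc_flow",
    "exponential_template_vitals",
    "flow_to_sensor_traces",
    "simulate_session",
]


@dataclass(frozen=True)
class RootLaw:
    """Ground-truth differential-pressure -> flow law, y = a·x + c·√x on the
    positive branch and y = a_neg·(−x) + c_neg·√(−x) on the negative one.

    Restricting the truth to the {linear, square-root} terms keeps the law
    inside the family the calibration assumes while allowing a closed-form
    inverse (quadratic in √|x|), so sensor traces can be generated exactly.
    """

    a_pos: float = 0.0
    c_pos: float = 0.1744
    a_neg: float = 0.0
    c_neg: float = -0.1373

    def __post_init__(self) -> None:
        if self.c_pos <= 0 or self.a_pos < 0:
            raise ValueError("positive branch must be strictly increasing (c_pos>0, a_pos>=0)")
        if self.c_neg >= 0 or self.a_neg > 0:
            raise ValueError("negative branch must be strictly increasing (c_neg<0, a_neg<=0)")

    def flow_from_dp(self, dp: np.ndarray) -> np.ndarray:
        dp = np.asarray(dp, dtype=float)
        out = np.zeros_like(dp)
        pos, neg = dp > 0, dp < 0
        out[pos] = self.a_pos * dp[pos] + self.c_pos * np.sqrt(dp[pos])
        m = -dp[neg]
        out[neg] = self.a_neg * m + self.c_neg * np.sqrt(m)
        return out

    def dp_from_flow(self, flow: np.ndarray) -> np.ndarray:
        """Exact inverse (quadratic formula in √|dp|)."""
        flow = np.asarray(flow, dtype=float)
        out = np.zeros_like(flow)
        for sign, a, c in ((1.0, self.a_pos, self.c_pos), (-1.0, abs(self.a_neg), abs(self.c_neg))):
            sel = flow > 0 if sign > 0 else flow < 0
            y = np.abs(flow[sel])
            if a > 0:
                s = (-c + np.sqrt(c * c + 4.0 * a * y)) / (2.0 * a)
            else:
                s = y / c
            out[sel] = sign * s * s
        return out

    def as_dict(self) -> dict[str, float]:
        return {"a_pos": self.a_pos, "c_pos": self.c_pos, "a_neg": self.a_neg, "c_neg": self.c_neg}


@dataclass(frozen=True)
class SensorSpec:
    noise_sd: float  # Pa, Gaussian, per sample
    resolution: float  # Pa, quantization step (0 disables)
    offset_range: float = 50.0  # Pa, per-sensor constant offset ~ U(−r, +r)
    sample_rate: float = 100.0  # Hz

    @classmethod
    def grade_a(cls) -> "SensorSpec":
        """Older-generation barometer: noise 0.2 Pa, resolution 0.18 Pa."""
        return cls(noise_sd=0.2, resolution=0.18)

    @classmethod
    def grade_b(cls) -> "SensorSpec":
        """Newer-generation barometer: noise 0.03 Pa, resolution 0.016 Pa."""
        return cls(noise_sd=0.03, resolution=0.016)

    @classmethod
    def ideal(cls) -> "SensorSpec":
        """Noise-free, offset-free, unquantized sensor for exactness tests."""
        return cls(noise_sd=0.0, resolution=0.0, offset_range=0.0)


PRESETS = {"gradeA": SensorSpec.grade_a, "gradeB": SensorSpec.grade_b, "ideal": SensorSpec.ideal}


@dataclass(frozen=True)
class SubjectProfile:
    """Breathing parameters and calibration ground truth of one synthetic subject."""

    tidal_volume: float = 0.5  # L per tidal breath
    respiratory_rate: float = 14.0  # breaths/min
    fvc_total: float = 4.0  # L, nominal forced vital capacity
    peak_expiratory_flow: float = 8.0  # L/s
    peak_inspiratory_flow: float = 4.5  # L/s
    expiratory_decay_tau: float = 0.5  # s
    pressure_gain: RootLaw = field(default_factory=RootLaw)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tidal_volume < self.fvc_total):
            raise ValueError("need 0 < tidal_volume < fvc_total")
        if min(self.respiratory_rate, self.peak_inspiratory_flow, self.expiratory_decay_tau) <= 0:
            raise ValueError("rates, flows and time constants must be positive")
        if not (1.0 <= self.peak_expiratory_flow <= 12.0):
            raise ValueError("peak_expiratory_flow outside the plausible 1-12 L/s range")


def make_cohort(n: int, seed: int) -> list[SubjectProfile]:
    """Draw ``n`` heterogeneous subjects: breathing parameters and per-subject
    pressure-gain laws vary, mimicking a cohort of different body sizes."""
    ss = np.random.SeedSequence(seed)
    profiles = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        pef = float(rng.uniform(6.0, 11.0))
        tau = float(rng.uniform(0.45, 0.75))
        # The pressure-flow law is mostly a property of the shared mask
        # hardware; subjects perturb it only mildly (fit, face geometry),
        # which is what lets pooled calibration work at all.
        law = RootLaw(
            a_pos=0.003 * float(rng.uniform(0.7, 1.3)),
            c_pos=0.1744 * float(rng.uniform(0.95, 1.05)),
            a_neg=-0.002 * float(rng.uniform(0.7, 1.3)),
            c_neg=-0.1373 * float(rng.uniform(0.95, 1.05)),
        )
        profiles.append(
            SubjectProfile(
                tidal_volume=float(rng.uniform(0.4, 0.7)),
                respiratory_rate=float(rng.uniform(11.0, 17.0)),
                fvc_total=pef * tau,  # consistent with the expiratory template
                peak_expiratory_flow=pef,
                peak_inspiratory_flow=float(rng.uniform(3.0, 6.0)),
                expiratory_decay_tau=tau,
                pressure_gain=law,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# waveform templates


def _half_sine(volume: float, duration: float, fs: float, sign: float) -> np.ndarray:
    """Sampled half-sine flow pulse moving ``volume`` litres in ``duration`` s."""
    n = max(1, round(duration * fs))
    dur = n / fs
    amp = math.pi * volume / (2.0 * dur)
    t = np.arange(n) / fs
    return sign * amp * np.sin(math.pi * t / dur)


def simulate_tidal_flow(
    profile: SubjectProfile,
    n_cycles: int,
    fs: float = 100.0,
    tidal_volume: float | None = None,
) -> FlowTrace:
    """Quiet breathing: per cycle, an inspiratory then an expiratory half-sine,
    each moving exactly the tidal volume (zero net volume per cycle)."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    tv = profile.tidal_volume if tidal_volume is None else tidal_volume
    half = 30.0 / profile.respiratory_rate  # s, half cycle
    insp = _half_sine(tv, half, fs, sign=-1.0)
    exp_ = _half_sine(tv, half, fs, sign=+1.0)
    values = np.concatenate([np.concatenate([insp, exp_]) for _ in range(n_cycles)])
    times = np.arange(values.size) / fs
    return FlowTrace(times=times, values=values, sample_rate=fs, label="tidal")


def exponential_template_vitals(
    pef: float, tau: float, duration: float, pif: float
) -> FvcVitals:
    """Closed-form vitals of the instant-rise exponential expiration
    F(t) = PEF·e^(−t/τ) truncated at ``duration``, preceded by an inspiratory
    half-sine of matching volume with peak ``pif``."""
    fvc = pef * tau * (1.0 - math.exp(-duration / tau))
    fev1 = pef * tau * (1.0 - math.exp(-1.0 / tau)) if duration >= 1.0 else float("nan")
    fef25 = pef - 0.25 * fvc / tau
    # inspired volume fraction ¼ of a half-sine: (1−cosθ)/2 = ¼ ⇒ θ = π/3
    fif25 = pif * math.sin(math.pi / 3.0)
    return FvcVitals(fvc=fvc, fev1=fev1, pef=pef, fef25=fef25, fif25=fif25)


def _fvc_waveform(
    pef: float,
    tau: float,
    pif: float,
    duration: float,
    rise_time: float,
    fs: float,
) -> tuple[np.ndarray, int]:
    """Sampled maneuver (deep inspiration + forced expiration) and the index
    of the expiratory onset."""
    if tau <= 0:
        raise ValueError("expiratory decay tau must be positive")
    if rise_time < 0 or rise_time >= duration:
        raise ValueError("rise_time must lie in [0, duration)")
    n_exp = max(2, round(duration * fs))
    t = np.arange(n_exp) / fs
    if rise_time == 0.0:
        exp_flow = pef * np.exp(-t / tau)
    else:
        # smooth C¹ peak: difference of exponentials, normalized to PEF.
        # rise_time is the rising time constant; time-to-peak ≈ 2×rise_time.
        tr = min(rise_time, 0.8 * tau)
        tp = math.log(tau / tr) * tau * tr / (tau - tr)
        amp = pef / (math.exp(-tp / tau) - math.exp(-tp / tr))
        exp_flow = amp * (np.exp(-t / tau) - np.exp(-t / tr))
    expired = float(np.trapezoid(np.append(exp_flow, 0.0), dx=1.0 / fs))
    t_insp = math.pi * expired / (2.0 * pif)  # half-sine moving the same volume
    insp = _half_sine(expired, t_insp, fs, sign=-1.0)
    return np.concatenate([insp, exp_flow]), insp.size


def simulate_fvc_flow(
    profile: SubjectProfile,
    fs: float = 100.0,
    duration: float = 6.0,
    rise_time: float = 0.0,
) -> tuple[FlowTrace, FvcVitals]:
    """One FVC maneuver: maximal inspiration (half-sine) then forced
    expiration.  With ``rise_time`` 0 the expiration is the instant-rise
    exponential whose vitals have closed forms; a positive rise time selects
    the smooth double-exponential template (rounded peak, as real forced
    expirations have) and the returned ground-truth vitals are then computed
    numerically from a 1 kHz sampling.
    """
    values, i_on = _fvc_waveform(
        profile.peak_expiratory_flow,
        profile.expiratory_decay_tau,
        profile.peak_inspiratory_flow,
        duration,
        rise_time,
        fs,
    )
    times = np.arange(values.size) / fs
    trace = FlowTrace(times=times, values=values, sample_rate=fs, label="fvc")
    if rise_time == 0.0:
        vitals = exponential_template_vitals(
            profile.peak_expiratory_flow,
            profile.expiratory_decay_tau,
            duration,
            profile.peak_inspiratory_flow,
        )
    else:
        vitals = _numeric_template_vitals(profile, duration, rise_time)
    return trace, vitals


def _numeric_template_vitals(
    profile: SubjectProfile, duration: float, rise_time: float, fs: float = 1000.0
) -> FvcVitals:
    """Ground-truth vitals of the smooth-rise template from a dense sampling."""
    values, i_on = _fvc_waveform(
        profile.peak_expiratory_flow,
        profile.expiratory_decay_tau,
        profile.peak_inspiratory_flow,
        duration,
        rise_time,
        fs,
    )
    t = np.arange(values.size) / fs
    ve, te = values[i_on:], t[i_on:]
    vol = np.concatenate([[0.0], np.cumsum((ve[1:] + ve[:-1]) / 2.0)]) / fs
    fvc = float(vol[-1])
    ipk = int(np.argmax(ve))
    pef = float(ve[ipk])
    t0 = te[ipk] - vol[ipk] / pef
    fev1 = float(np.interp(t0 + 1.0, te, vol)) if te[-1] - t0 >= 1.0 else float("nan")
    fef25 = float(np.interp(0.25 * fvc, vol, ve))
    fif25 = profile.peak_inspiratory_flow * math.sin(math.pi / 3.0)
    return FvcVitals(fvc=fvc, fev1=fev1, pef=pef, fef25=fef25, fif25=fif25)


# ---------------------------------------------------------------------------
# sensors and sessions


def _quantize(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(values / step) * step if step > 0 else values


def flow_to_sensor_traces(
    truth_flow: FlowTrace,
    profile: SubjectProfile,
    spec: SensorSpec,
    seed: int,
    atmos: float = ATMOSPHERIC_PRESSURE_PA,
) -> tuple[PressureTrace, PressureTrace]:
    """Corrupt a true flow signal into inside/outside barometer traces.

    inside = atmos + law⁻¹(flow) + offset_in + noise, then quantized;
    outside = atmos + offset_out + noise, then quantized.  Deterministic
    for a given seed.
    """
    dt = np.diff(truth_flow.times)
    if dt.size and not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("truth flow must be uniformly sampled")
    rate = truth_flow.sample_rate or (1.0 / dt[0] if dt.size else spec.sample_rate)
    if abs(rate - spec.sample_rate) > 1e-9:
        times = np.arange(0.0, truth_flow.times[-1] + 0.5 / spec.sample_rate, 1.0 / spec.sample_rate)
        flow = np.interp(times + truth_flow.times[0], truth_flow.times, truth_flow.values)
        times = times + truth_flow.times[0]
    else:
        times, flow = truth_flow.times, truth_flow.values
    dp = profile.pressure_gain.dp_from_flow(flow)

    rng = np.random.default_rng(seed)
    off_in, off_out = rng.uniform(-spec.offset_range, spec.offset_range, size=2)
    inside = atmos + dp + off_in
    outside = atmos + np.full_like(dp, off_out)
    if spec.noise_sd > 0:
        inside = inside + rng.normal(0.0, spec.noise_sd, size=dp.size)
        outside = outside + rng.normal(0.0, spec.noise_sd, size=dp.size)
    inside = _quantize(inside, spec.resolution)
    outside = _quantize(outside, spec.resolution)
    mk = lambda v, lab: PressureTrace(
        times=times, values=v, sample_rate=spec.sample_rate, label=lab
    )
    return mk(inside, "inside"), mk(outside, "outside")


@dataclass
class SessionDataset:
    """One subject's paired recording: raw sensor traces, reference flow,
    noise-free truth, and ground-truth maneuver labels."""

    subject_id: int
    profile: SubjectProfile
    inside: PressureTrace
    outside: PressureTrace
    reference_flow: FlowTrace
    truth_flow: FlowTrace
    truth_vitals: list[FvcVitals]
    segment_labels: list[BreathSegment]


def simulate_session(
    profiles: list[SubjectProfile],
    spec: SensorSpec,
    seed: int,
    n_maneuvers: int = 10,
    tidal_cycles: int = 5,
    fvc_duration: float = 6.0,
    rise_time: float = 0.1,
    tail_s: float = 1.0,
    reference_rate: float = 50.0,
    reference_noise_sd: float = 0.02,
    reference_offset: float = 0.01,
    maneuver_jitter: float = 0.1,
    fs: float = 100.0,
) -> list[SessionDataset]:
    """Generate one session per subject.

    Each session interleaves ``n_maneuvers`` FVC maneuvers with blocks of
    ``tidal_cycles`` quiet breaths (tidal blocks open and close the session)
    and ends with ``tail_s`` seconds of exactly zero flow — the mask-off
    stretch used downstream for offset estimation.  Per-maneuver effort
    varies by ±``maneuver_jitter`` (uniform) on PEF and τ.  All randomness
    derives from ``seed``; identical inputs give identical outputs.
    """
    if not profiles:
        raise ValueError("need at least one subject profile")
    if n_maneuvers < 1 or tidal_cycles < 1:
        raise ValueError("n_maneuvers and tidal_cycles must be >= 1")
    ss = np.random.SeedSequence(seed)
    sessions = []
    for sid, (profile, child) in enumerate(zip(profiles, ss.spawn(len(profiles)))):
        rng = np.random.default_rng(child)
        chunks: list[np.ndarray] = []
        labels: list[BreathSegment] = []
        vitals: list[FvcVitals] = []
        t_cursor = 0.0

        def _append(arr: np.ndarray) -> float:
            nonlocal t_cursor
            start = t_cursor
            chunks.append(arr)
            t_cursor += arr.size / fs
            return start

        for m in range(n_maneuvers):
            tv = profile.tidal_volume * float(rng.uniform(0.95, 1.05))
            tidal = simulate_tidal_flow(profile, tidal_cycles, fs=fs, tidal_volume=tv)
            start = _append(tidal.values)
            half = (tidal.values.size / tidal_cycles / 2.0) / fs
            for c in range(tidal_cycles):
                labels.append(
                    BreathSegment("tidal", start + 2 * c * half, start + 2 * (c + 1) * half)
                )
            jit = lambda: float(rng.uniform(1.0 - maneuver_jitter, 1.0 + maneuver_jitter))
            p_m = replace(
                profile,
                peak_expiratory_flow=min(12.0, profile.peak_expiratory_flow * jit()),
                expiratory_decay_tau=profile.expiratory_decay_tau * jit(),
            )
            fvc_trace, fvc_vitals = simulate_fvc_flow(
                p_m, fs=fs, duration=fvc_duration, rise_time=rise_time
            )
            start = _append(fvc_trace.values)
            # expiratory onset: first sample of the expiration part
            n_insp = int(np.nonzero(fvc_trace.values > 0)[0][0])
            labels.append(
                BreathSegment(
                    "fvc",
                    start,
                    start + fvc_trace.values.size / fs,
                    expiratory_onset=start + n_insp / fs,
                )
            )
            vitals.append(fvc_vitals)
        tidal = simulate_tidal_flow(profile, tidal_cycles, fs=fs)
        _append(tidal.values)
        _append(np.zeros(round(tail_s * fs)))

        values = np.concatenate(chunks)
        times = np.arange(values.size) / fs
        truth = FlowTrace(times=times, values=values, sample_rate=fs, label="truth")

        inside, outside = flow_to_sensor_traces(
            truth, profile, spec, seed=int(rng.integers(0, 2**31 - 1))
        )

        step = fs / reference_rate
        if abs(step - round(step)) < 1e-9:
            idx = np.arange(0, values.size, int(round(step)))
            ref_t, ref_v = times[idx], values[idx].copy()
        else:
            ref_t = np.arange(0.0, times[-1], 1.0 / reference_rate)
            ref_v = np.interp(ref_t, times, values)
        ref_v = ref_v + reference_offset
        if reference_noise_sd > 0:
            ref_v = ref_v + rng.normal(0.0, reference_noise_sd, size=ref_v.size)
        reference = FlowTrace(
            times=ref_t, values=ref_v, sample_rate=reference_rate, label="spirometer"
        )
        sessions.append(
            SessionDataset(
                subject_id=sid,
                profile=profile,
                inside=inside,
                outside=outside,
                reference_flow=reference,
                truth_flow=truth,
                truth_vitals=vitals,
                segment_labels=labels,
            )
        )
    return sessions
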