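import math
from dataclasses import replace

import numpy as np
import pytest

from barospiro.analytics import (
    BreathSegment,
    compute_fvc_vitals,
    cumulative_volume,
    flow_volume_loop,
    segment_breaths,
    sliding_window_volume,
)
from barospiro.synth import (
    exponential_template_vitals,
    simulate_fvc_flow,
    simulate_session,
    simulate_tidal_flow,
    SensorSpec,
    SubjectProfile,
    make_cohort,
)
from barospiro.traces import FlowTrace


def _flow(values, rate=100.0):
    values = np.asarray(values, dtype=float)
    return FlowTrace(times=np.arange(values.size) / rate, values=values, sample_rate=rate)


class TestSegmentation:
    def test_labeled_session_maneuvers_found(self, noisy_sessions):
        for s in noisy_sessions:
            segs = segment_breaths(s.truth_flow)
            fvc = [g for g in segs if g.kind == "fvc"]
            truth = [g for g in s.segment_labels if g.kind == "fvc"]
            assert len(fvc) == len(truth) == 10
            for got, want in zip(fvc, truth):
                assert got.expiratory_onset == pytest.approx(want.expiratory_onset, abs=0.03)

    def test_maneuver_count_agrees_across_many_seeded_sessions(self):
        """Full maneuver-count agreement with the generator's labels over 50
        seeded single-subject sessions."""
        for seed in range(50):
            [s] = simulate_session(
                make_cohort(1, seed), SensorSpec.grade_a(), seed=seed,
                n_maneuvers=4, tidal_cycles=5,
            )
            got = sum(g.kind == "fvc" for g in segment_breaths(s.truth_flow))
            assert got == 4, seed

    def test_pure_tidal_session_has_no_fvc(self, profile):
        trace = simulate_tidal_flow(profile, n_cycles=8)
        segs = segment_breaths(trace)
        assert segs and all(s.kind == "tidal" for s in segs)

    def test_hysteresis_robust_to_small_noise(self, profile, rng):
        trace = simulate_tidal_flow(profile, n_cycles=8)
        clean = len(segment_breaths(trace))
        noisy = trace.with_values(trace.values + rng.uniform(-0.02, 0.02, len(trace)))
        assert len(segment_breaths(noisy)) == clean

    def test_all_zero_flow_gives_empty_list(self):
        assert segment_breaths(_flow(np.zeros(500))) == []


class TestVolume:
    def test_constant_flow_cumulative(self):
        seg = BreathSegment("tidal", 0.0, 2.0)
        vol = cumulative_volume(_flow(np.ones(201)), seg)
        assert vol.values[-1] == pytest.approx(2.0)

    def test_tidal_cycle_conserves_volume(self, profile):
        prof = replace(profile, respiratory_rate=12.0)
        trace = simulate_tidal_flow(prof, n_cycles=1)
        closed = trace.with_values(np.append(trace.values, 0.0)[:-1])  # same length
        seg = BreathSegment("tidal", 0.0, trace.times[-1])
        vol = cumulative_volume(trace, seg)
        assert abs(vol.values[-1]) < 1e-4

    def test_exponential_template_volume(self, profile):
        prof = replace(profile, peak_expiratory_flow=8.0, expiratory_decay_tau=0.5)
        trace, vitals = simulate_fvc_flow(prof, fs=1000.0, rise_time=0.0)
        onset = trace.times[int(np.argmax(trace.values))]
        seg = BreathSegment("fvc", 0.0, trace.times[-1], expiratory_onset=onset)
        vol = cumulative_volume(trace, seg)
        assert vol.values[-1] == pytest.approx(4.0, rel=1e-3)

    def test_sliding_window_constant_flow_exact(self):
        vol = sliding_window_volume(_flow(np.ones(500)), window=0.5)
        assert np.allclose(vol.values[vol.times >= 0.5], 0.5, atol=1e-12)

    def test_sliding_window_zero_flow(self):
        vol = sliding_window_volume(_flow(np.zeros(300)))
        assert np.allclose(vol.values, 0.0)

    def test_sliding_window_sinusoid_closed_form(self):
        t = np.arange(0, 10, 0.001)
        trace = FlowTrace(times=t, values=np.sin(2 * np.pi * t), sample_rate=1000.0)
        vol = sliding_window_volume(trace, window=0.5)
        expected = (np.cos(2 * np.pi * (vol.times - 0.5)) - np.cos(2 * np.pi * vol.times)) / (
            2 * np.pi
        )
        assert np.allclose(vol.values, expected, atol=1e-5)
        assert vol.values.max() == pytest.approx(1 / np.pi, rel=1e-3)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_volume(_flow(np.ones(10)), window=0.5)


class TestLoopAndVitals:
    @pytest.fixture()
    def template(self, profile):
        prof = replace(
            profile,
            peak_expiratory_flow=8.0,
            expiratory_decay_tau=0.5,
            peak_inspiratory_flow=4.0,
        )
        trace, vitals = simulate_fvc_flow(prof, fs=1000.0, rise_time=0.0)
        onset = trace.times[int(np.argmax(trace.values))]
        seg = BreathSegment("fvc", 0.0, trace.times[-1], expiratory_onset=onset)
        return trace, seg, vitals

    def test_loop_peak_flow_at_zero_volume(self, template):
        trace, seg, _ = template
        loop = flow_volume_loop(trace, seg)
        i = int(np.argmax(loop.flow))
        assert loop.flow[i] == pytest.approx(8.0)
        assert loop.volume[i] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_segment_rejected(self):
        seg = BreathSegment("fvc", 0.0, 1.0, expiratory_onset=0.0)
        with pytest.raises(ValueError):
            flow_volume_loop(_flow(np.zeros(200)), seg)

    def test_non_fvc_segment_rejected(self):
        with pytest.raises(ValueError):
            flow_volume_loop(_flow(np.ones(100)), BreathSegment("tidal", 0.0, 0.5))

    @pytest.mark.parametrize("fs, rel_tol", [(1000.0, 1e-3), (100.0, 1e-2)])
    def test_vitals_match_closed_forms(self, profile, fs, rel_tol):
        prof = replace(
            profile,
            peak_expiratory_flow=8.0,
            expiratory_decay_tau=0.5,
            peak_inspiratory_flow=4.0,
        )
        trace, _ = simulate_fvc_flow(prof, fs=fs, rise_time=0.0)
        onset = trace.times[int(np.argmax(trace.values))]
        seg = BreathSegment("fvc", 0.0, trace.times[-1], expiratory_onset=onset)
        got = compute_fvc_vitals(trace, seg)
        want = exponential_template_vitals(8.0, 0.5, 6.0, 4.0)
        assert got.fvc == pytest.approx(want.fvc, rel=rel_tol)
        assert got.fev1 == pytest.approx(want.fev1, rel=rel_tol)
        assert got.pef == pytest.approx(want.pef, rel=rel_tol)
        assert got.fef25 == pytest.approx(want.fef25, rel=rel_tol)
        assert got.fif25 == pytest.approx(want.fif25, rel=rel_tol)

    def test_vitals_scale_linearly(self, template):
        trace, seg, _ = template
        v1 = compute_fvc_vitals(trace, seg)
        v2 = compute_fvc_vitals(trace.with_values(2.0 * trace.values), seg)
        for name in ("fvc", "fev1", "pef", "fef25", "fif25"):
            assert getattr(v2, name) == pytest.approx(2.0 * getattr(v1, name), rel=1e-9)

    def test_constant_plateau_fev1_is_pef(self):
        """In the tau -> infinity limit (flat plateau) FEV1 = PEF * 1 s."""
        v = np.concatenate([-np.ones(100), np.full(400, 3.0)])
        trace = _flow(v)
        seg = BreathSegment("fvc", 0.0, trace.times[-1], expiratory_onset=1.0)
        got = compute_fvc_vitals(trace, seg)
        assert got.fev1 == pytest.approx(3.0, rel=1e-6)

    def test_short_expiration_flags_fev1(self):
        v = np.concatenate([-np.ones(100), np.full(50, 3.0)])
        trace = _flow(v)
        seg = BreathSegment("fvc", 0.0, trace.times[-1], expiratory_onset=1.0)
        assert math.isnan(compute_fvc_vitals(trace, seg).fev1)
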