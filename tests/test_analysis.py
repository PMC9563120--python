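import math

import numpy as np
import pytest

from myoforge import (TraceModel, ViabilityCheck, build_schedule,
                      detect_peaks, fatigue_analysis, peak_stats,
                      quadrant_frequency, response_rate, simulate_sham,
                      simulate_trace, viability_precheck, viability_trend)
from myoforge.analysis import (InsufficientDataError, Peak, extract_datapad,
                               fit_fatigue_rate, time_to_peak)
from myoforge.protocol import StimulusSchedule
from _oracles import oracle_top_two
from myoforge.synthetic import ForceTrace, TwitchKernel, twitch_peak_time


def _peak(t, h, kind="major", k=0):
    return Peak(time=t, height=h, kind=kind, train_index=k)


class TestDetectPeaks:
    def test_noiseless_sham_has_no_peaks(self):
        tr = simulate_sham(30.0, noise_sd=0.0)
        sched = build_schedule(1.0, 30.0)
        assert detect_peaks(tr, sched, min_height=0.1) == []

    def test_noisy_sham_has_no_peaks(self):
        tr = simulate_sham(300.0, noise_sd=0.05, seed=5)
        sched = build_schedule(1.2097, 300.0)
        assert detect_peaks(tr, sched) == []

    def test_alternating_quadrant_counts(self, quadrant_trace, quadrant_schedule):
        peaks = detect_peaks(quadrant_trace, quadrant_schedule)
        assert sum(p.kind == "major" for p in peaks) == 248
        assert sum(p.kind == "minor" for p in peaks) == 248

    def test_single_twitch_height_and_kind(self):
        sched = build_schedule(5.0, 4.0)  # one onset at 0
        m = TraceModel(major_amp_mean=10.0, major_amp_sd=0.0, noise_sd=0.0,
                       minor_ratio=0.5)
        tr = simulate_trace(sched, m)
        peaks = detect_peaks(tr, sched, min_height=1.0)
        majors = [p for p in peaks if p.kind == "major"]
        assert len(majors) == 1
        assert majors[0].height == pytest.approx(10.0, abs=10.0 / (100 * 0.02) ** 2)

    def test_major_is_taller_than_minor_within_each_train(self, quadrant_trace,
                                                          quadrant_schedule):
        peaks = detect_peaks(quadrant_trace, quadrant_schedule)
        by_train = {}
        for p in peaks:
            by_train.setdefault(p.train_index, {})[p.kind] = p.height
        for kinds in by_train.values():
            if "minor" in kinds:
                assert kinds["major"] >= kinds["minor"]

    def test_scaling_invariance_of_counts_and_kinds(self, quadrant_trace,
                                                    quadrant_schedule):
        """Multiplying the force by any c > 0 changes no peak kinds/counts."""
        base = detect_peaks(quadrant_trace, quadrant_schedule)
        for c in (0.2, 5.0):
            scaled = ForceTrace(time=quadrant_trace.time,
                                force=c * quadrant_trace.force,
                                sampling_rate=quadrant_trace.sampling_rate)
            got = detect_peaks(scaled, quadrant_schedule)
            assert [(p.kind, p.train_index) for p in got] == \
                   [(p.kind, p.train_index) for p in base]

    def test_matches_brute_force_window_oracle(self):
        """Detection equals per-window top-two local maxima on short
        noiseless traces over random parameter draws."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            period = rng.uniform(1.0, 2.0)
            amp = rng.uniform(2.0, 20.0)
            ratio = rng.uniform(0.3, 0.8)
            sched = build_schedule(period, 60.0)
            m = TraceModel(major_amp_mean=amp, major_amp_sd=0.0, noise_sd=0.0,
                           minor_ratio=ratio)
            tr = simulate_trace(sched, m)
            got = detect_peaks(tr, sched, min_height=amp * 0.05)
            expected = oracle_top_two(tr, sched, amp * 0.05)
            assert [(p.train_index, p.kind) for p in got] == expected

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            ForceTrace(time=np.array([]), force=np.array([]),
                       sampling_rate=100.0)


class TestQuadrantFrequency:
    def test_full_quadrant_counts(self, quadrant_trace, quadrant_schedule):
        peaks = detect_peaks(quadrant_trace, quadrant_schedule)
        q = quadrant_frequency(peaks)
        assert (q.n_major, q.n_minor) == (248, 248)

    def test_empty_peaks(self):
        q = quadrant_frequency([])
        assert (q.n_major, q.n_minor) == (0, 0)

    def test_half_open_window_boundary(self):
        peaks = [_peak(299.9, 5.0), _peak(300.0, 5.0, k=1)]
        q = quadrant_frequency(peaks, window=300.0, start=0.0)
        assert q.n_major == 1

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            quadrant_frequency([], window=0.0)


class TestResponseRate:
    @pytest.mark.parametrize("resp,prog,expected", [
        (248, 248, 100.0), (0, 248, 0.0), (124, 248, 50.0), (1, 3, 33.3),
    ])
    def test_examples(self, resp, prog, expected):
        assert response_rate(resp, prog) == expected

    def test_zero_programmed_rejected(self):
        with pytest.raises(ValueError):
            response_rate(0, 0)


class TestPeakStats:
    def test_constant_heights(self):
        mean, sd, med = peak_stats([_peak(0, 8.5), _peak(1, 8.5)])
        assert (mean, sd, med) == (8.5, 0.0, 8.5)

    def test_simple_heights(self):
        mean, sd, med = peak_stats([_peak(0, 1), _peak(1, 2), _peak(2, 3)])
        assert (mean, sd, med) == (2.0, 1.0, 2.0)

    def test_kind_filter(self):
        peaks = [_peak(0, 10.0), _peak(0.5, 5.0, "minor")]
        assert peak_stats(peaks, "minor")[0] == 5.0

    def test_empty_after_filter_signals(self):
        with pytest.raises(InsufficientDataError):
            peak_stats([_peak(0, 1.0)], "minor")


class TestTimeToPeak:
    def test_noiseless_twitch_latency_is_kernel_peak_time(self):
        sched = build_schedule(5.0, 4.0)
        kernel = TwitchKernel(rise_tau=0.02, decay_tau=0.08)
        m = TraceModel(major_amp_mean=10.0, major_amp_sd=0.0, noise_sd=0.0,
                       kernel=kernel)
        tr = simulate_trace(sched, m, sampling_rate=1000.0)
        peaks = detect_peaks(tr, sched, min_height=1.0)
        major = next(p for p in peaks if p.kind == "major")
        assert time_to_peak(sched, major) == pytest.approx(0.0370, abs=2e-3)
        assert time_to_peak(sched, major) == pytest.approx(
            twitch_peak_time(kernel), abs=2e-3)

    def test_measured_from_assigned_onset(self):
        sched = build_schedule(2.0, 4.0)
        p = _peak(2.1, 5.0, k=1)
        assert time_to_peak(sched, p) == pytest.approx(0.1)

    def test_peak_before_onset_rejected(self):
        sched = build_schedule(2.0, 4.0)
        with pytest.raises(ValueError):
            time_to_peak(sched, _peak(1.0, 5.0, k=1))


class TestFatigueAnalysis:
    def test_constant_amplitude_gives_zero_fatigue(self):
        peaks = [_peak(t, 10.0, k=i) for i, t in
                 enumerate(np.arange(0, 600, 1.2))]
        res = fatigue_analysis(peaks, total_runtime_min=10.0)
        assert res.half_time_force == pytest.approx(10.0)
        assert res.fatigue_percent == pytest.approx(0.0)
        assert res.half_time == 5.0

    def test_exponential_envelope_half_time_force(self):
        """Envelope calibrated to hit 8.23 mN at 22.5 min from 20.5 mN."""
        rate = math.log(20.5 / 8.23) / 1350.0
        sched = build_schedule(1.2097, 2700.0)
        m = TraceModel(major_amp_mean=20.5, major_amp_sd=0.0, noise_sd=0.0,
                       fatigue="exponential", fatigue_rate=rate)
        tr = simulate_trace(sched, m)
        peaks = detect_peaks(tr, sched, min_height=0.5)
        res = fatigue_analysis(peaks, total_runtime_min=45.0)
        assert res.half_time == 22.5
        assert res.half_time_force == pytest.approx(8.23, abs=0.15)
        assert res.fatigue_percent > 0

    def test_total_drop_is_100_percent(self):
        peaks = ([_peak(t, 10.0, k=i) for i, t in enumerate(np.arange(0, 60, 2))]
                 + [_peak(1350.0, 1e-12, k=999)])
        res = fatigue_analysis(peaks, total_runtime_min=45.0)
        assert res.fatigue_percent == pytest.approx(100.0)

    def test_missing_window_signals(self):
        with pytest.raises(InsufficientDataError):
            fatigue_analysis([_peak(0.0, 10.0)], total_runtime_min=45.0)

    def test_fatigue_rate_recovery(self):
        truth = 5e-4
        sched = build_schedule(1.2097, 300.0)
        ests = []
        for seed in range(8):
            m = TraceModel(seed=seed, fatigue="exponential", fatigue_rate=truth)
            tr = simulate_trace(sched, m)
            peaks = detect_peaks(tr, sched)
            rate, _ = fit_fatigue_rate(peaks)
            ests.append(rate)
        ests = np.array(ests)
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 3 * se + 1e-6


class TestViabilityTrend:
    def test_flat_baseline_not_flagged(self):
        tr = simulate_sham(120.0, noise_sd=0.0)
        slope, flagged = viability_trend(tr)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert not flagged

    def test_injected_drift_recovered_and_flagged(self, quadrant_schedule):
        m = TraceModel(seed=3, drift_slope=0.01)
        tr = simulate_trace(quadrant_schedule, m)
        slope, flagged = viability_trend(tr)
        assert slope == pytest.approx(0.01, abs=0.003)
        assert flagged

    def test_negative_drift_not_flagged(self, quadrant_schedule):
        m = TraceModel(seed=3, drift_slope=-0.01)
        tr = simulate_trace(quadrant_schedule, m)
        slope, flagged = viability_trend(tr)
        assert slope < 0
        assert not flagged

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            viability_trend(simulate_sham(30.0))


class TestViabilityPrecheck:
    def _check_trace(self, n_respond):
        onsets = np.arange(3) * 40.0
        sched = StimulusSchedule(onsets=onsets, train_period=40.0, duration=121.0)
        m = TraceModel(major_amp_mean=10.0, major_amp_sd=0.0, noise_sd=0.0)
        tr = simulate_trace(sched, m)
        if n_respond < 3:  # flatten the response to the last stimuli
            cut = int(onsets[n_respond] * tr.sampling_rate)
            tr.force[cut:] = 0.0
        return tr

    def test_three_of_three_passes(self):
        assert viability_precheck(self._check_trace(3), ViabilityCheck())

    def test_two_of_three_fails(self):
        assert not viability_precheck(self._check_trace(2), ViabilityCheck())

    def test_sham_fails(self):
        tr = simulate_sham(130.0, noise_sd=0.05, seed=2)
        assert not viability_precheck(tr, ViabilityCheck())


class TestExtractDatapad:
    def test_constant_amplitude_never_crosses(self):
        peaks = [_peak(t, 10.0, k=i) for i, t in enumerate(range(0, 100, 2))]
        df = extract_datapad(peaks, initial_force=10.0, fraction=0.5)
        assert df.attrs["crossing_time_s"] is None
        assert not df["below_fraction"].any()

    def test_linear_decline_crossing_near_midpoint(self):
        peaks = [_peak(t, 10.0 * (1 - t / 100.0) + 1e-9, k=i)
                 for i, t in enumerate(range(0, 100, 2))]
        df = extract_datapad(peaks, initial_force=10.0, fraction=0.5)
        assert df.attrs["crossing_time_s"] == pytest.approx(50.0, abs=2.0)

    def test_empty_peaks_empty_table(self):
        df = extract_datapad([], initial_force=10.0)
        assert len(df) == 0
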