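import numpy as np
import pytest

from spkrecon.metrics import (average_waveform, detect_spikes, match_trains,
                              mean_time_delay, waveform_nrmse)
from spkrecon.synthio import TemplateParams, make_templates

FS = 25_000.0


def brute_force_max_tp(gt, rec, tol):
    """Maximum one-to-one matching cardinality by exhaustive enumeration."""
    gt, rec = list(gt), list(rec)
    best = 0
    compat = [[abs(g - r) <= tol for r in rec] for g in gt]

    def rec_fn(i, used):
        nonlocal best
        if i == len(gt):
            best = max(best, len(used))
            return
        if len(gt) - i + len(used) <= best:
            return
        rec_fn(i + 1, used)
        for j in range(len(rec)):
            if j not in used and compat[i][j]:
                rec_fn(i + 1, used | {j})

    rec_fn(0, frozenset())
    return best


class TestDetectSpikes:
    def test_subthreshold_signal_yields_nothing(self, rng):
        x = rng.uniform(-5.9, 100.0, size=10_000)
        assert len(detect_spikes(x, 1.0, fs=FS)) == 0

    def test_injected_templates_detected_at_minima(self):
        tpl = make_templates([TemplateParams(-10.0, 1.0, 0.3)], FS)[0]
        x = np.zeros(25_000)
        times = [5_000, 12_000, 20_000]
        for t in times:
            x[t - tpl["peak"] : t - tpl["peak"] + len(tpl["waveform"])] += tpl["waveform"]
        det = detect_spikes(x, 1.0, fs=FS)   # threshold -6, spikes at -10
        assert np.array_equal(det, times)

    def test_default_threshold_is_minus_six_sigma(self):
        x = np.zeros(10_000)
        x[5_000] = -6.5
        x[7_000] = -5.5
        det = detect_spikes(x, 1.0, fs=FS)
        assert np.array_equal(det, [5_000])

    def test_close_crossings_merged_within_dead_time(self):
        x = np.zeros(10_000)
        x[5_000] = -8.0
        x[5_010] = -10.0   # 0.4 ms later: same event, deeper minimum
        det = detect_spikes(x, 1.0, fs=FS)
        assert np.array_equal(det, [5_010])

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(100), 0.0)

    def test_timestamps_strictly_increasing(self, rng):
        x = rng.normal(0, 1, size=100_000)
        det = detect_spikes(x, 0.5, fs=FS)
        assert np.all(np.diff(det) > 0)


class TestMatchTrains:
    def test_identical_trains_match_perfectly(self):
        t = np.array([100, 500, 900])
        m = match_trains(t, t, FS)
        assert m.hit_rate == 1.0
        assert m.precision == 1.0
        assert np.allclose(m.delays_us, 0)

    def test_small_worked_example(self):
        # gt at sample 2500; rec at 2510 (+400 us, matched) and 3750 (FP)
        m = match_trains(np.array([2500]), np.array([2510, 3750]), FS)
        assert m.n_tp == 1
        assert m.delays_us[0] == pytest.approx(400.0)
        assert m.hit_rate == 1.0
        assert m.precision == 0.5

    def test_default_tolerance_is_500_us(self):
        # ±500 us at 25 kHz is 12.5 samples: 12 matches, 13 does not
        assert match_trains(np.array([1000]), np.array([1012]), FS).n_tp == 1
        assert match_trains(np.array([1000]), np.array([1013]), FS).n_tp == 0

    def test_greedy_counterexample_handled_optimally(self):
        # earliest-deadline matching finds both pairs where nearest-first
        # greedy would find only one
        m = match_trains(np.array([0, 6]), np.array([4, 10]), fs=1.0,
                         tolerance_us=5e6)
        assert m.n_tp == 2

    def test_matches_brute_force_on_random_instances(self, rng):
        tol = 12
        for _ in range(1000):
            gt = np.sort(rng.integers(0, 120, size=rng.integers(0, 9)))
            rec = np.sort(rng.integers(0, 120, size=rng.integers(0, 9)))
            m = match_trains(gt, rec, fs=1.0, tolerance_us=tol * 1e6)
            assert m.n_tp == brute_force_max_tp(gt, rec, tol)
            assert m.n_tp + len(m.fn_times) == len(gt)
            assert m.n_tp + len(m.fp_times) == len(rec)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            match_trains(np.array([5, 1]), np.array([1]), FS)

    def test_removing_detection_cannot_raise_hit_rate(self, rng):
        gt = np.sort(rng.integers(0, 10_000, size=20))
        rec = np.sort(rng.integers(0, 10_000, size=20))
        full = match_trains(gt, rec, FS)
        reduced = match_trains(gt, rec[:-1], FS)
        assert reduced.hit_rate <= full.hit_rate + 1e-12
        assert 0 <= reduced.precision <= 1


class TestDelaysAndWaveforms:
    def test_identical_trains_have_zero_mean_delay(self):
        t = np.array([100, 200])
        assert mean_time_delay(match_trains(t, t, FS)) == 0.0

    def test_one_sample_shift_is_40_us(self):
        gt = np.array([1000, 2000])
        m = match_trains(gt, gt + 1, FS)
        assert mean_time_delay(m) == pytest.approx(40.0)

    def test_symmetric_delays_average_to_zero(self):
        gt = np.array([1000, 2000, 3000])
        rec = np.array([1001, 1999, 3000])
        assert mean_time_delay(match_trains(gt, rec, FS)) == pytest.approx(0.0)

    def test_no_matches_is_an_error(self):
        m = match_trains(np.array([0]), np.array([], dtype=int), FS)
        with pytest.raises(ValueError):
            mean_time_delay(m)

    def test_nrmse_zero_for_perfect_reconstruction(self, rng):
        trace = rng.normal(size=10_000)
        _, mean = waveform_nrmse(trace, trace, np.array([5_000]), fs=FS)
        assert mean == 0.0

    def test_nrmse_constant_offset_closed_form(self):
        # rec = gt + 5 with gt peak-to-peak 100 -> NRMSE exactly 0.05
        trace = np.zeros(10_000)
        trace[5_000] = -60.0
        trace[5_010] = 40.0
        _, mean = waveform_nrmse(trace, trace + 5.0, np.array([5_000]), fs=FS)
        assert mean == pytest.approx(0.05)

    def test_nrmse_amplitude_scaling_closed_form(self):
        # rec = (1+eps) gt -> NRMSE = eps * RMS(gt) / ptp(gt)
        rng = np.random.default_rng(0)
        trace = rng.normal(size=10_000)
        eps = 0.1
        vals, _ = waveform_nrmse(trace, (1 + eps) * trace, np.array([5_000]), fs=FS)
        w = trace[5_000 - 25 : 5_000 + 50]
        expected = eps * np.sqrt(np.mean(w**2)) / np.ptp(w)
        assert vals[0] == pytest.approx(expected)

    def test_nrmse_scales_inversely_with_gt_amplitude(self):
        rng = np.random.default_rng(1)
        gt = rng.normal(size=10_000)
        rec = gt + rng.normal(0, 0.1, size=10_000)
        v1, _ = waveform_nrmse(gt, rec, np.array([5_000]), fs=FS)
        v2, _ = waveform_nrmse(3 * gt, rec + 2 * gt, np.array([5_000]), fs=FS)
        assert v2[0] == pytest.approx(v1[0] / 3)

    def test_flat_window_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            vals, mean = waveform_nrmse(np.zeros(10_000), np.ones(10_000),
                                        np.array([5_000]), fs=FS)
        assert len(vals) == 0
        assert np.isnan(mean)

    def test_average_of_single_spike_is_its_window(self, rng):
        trace = rng.normal(size=10_000)
        avg = average_waveform(trace, np.array([5_000]), fs=FS)
        assert np.array_equal(avg, trace[5_000 - 25 : 5_000 + 50])

    def test_average_converges_at_clt_rate(self, rng):
        # n aligned copies of a template in noise: RMSE(avg, template)
        # approaches sigma/sqrt(n)
        tpl = make_templates([TemplateParams(-50.0, 1.0, 0.3)], FS)[0]
        n, sigma = 100, 2.0
        spacing = 200
        trace = rng.normal(0, sigma, size=n * spacing + 1000)
        times = []
        for i in range(n):
            t = 500 + i * spacing
            trace[t - tpl["peak"] : t - tpl["peak"] + len(tpl["waveform"])] += tpl["waveform"]
            times.append(t)
        avg = average_waveform(trace, np.array(times), fs=FS)
        clean = np.zeros_like(trace)
        for t in times:
            clean[t - tpl["peak"] : t - tpl["peak"] + len(tpl["waveform"])] += tpl["waveform"]
        template_window = clean[times[0] - 25 : times[0] + 50]
        rmse = np.sqrt(np.mean((avg - template_window) ** 2))
        assert abs(rmse - sigma / np.sqrt(n)) < 0.3 * sigma / np.sqrt(n)

    def test_no_support_rejected(self):
        with pytest.raises(ValueError):
            average_waveform(np.zeros(10), np.array([5]), fs=FS)
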