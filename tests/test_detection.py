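import numpy as np
import pytest

from seizurepca import (FeatureSignal, aggregate_ranks, calibrate,
                        detect_onset, evaluate_at_scales,
                        false_positive_rate, normalize_against_threshold,
                        rank_features, stable_range, threshold_for_fp,
                        threshold_for_latency)


def make_sig(values, window_len=2.0, hop=1.0, name="u"):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * hop
    return FeatureSignal(values, starts, window_len, name)


class TestDetectOnset:
    def test_no_crossing_is_fn(self):
        res = detect_onset(make_sig([1, 1, 1]), threshold=5, onset_s=0)
        assert not res.detected and res.is_fn and res.latency_s is None

    def test_crossing_before_onset_clamps_latency_to_zero(self):
        # scanning from the record start, the first crossing ends at 1 s,
        # before the 1.5 s onset: latency clamps at 0
        sig = make_sig([10, 0, 0], window_len=1.0)
        res = detect_onset(sig, threshold=5, onset_s=1.5, search_start_s=0.0)
        assert res.detected and res.latency_s == 0.0 and not res.is_fn

    def test_first_crossing_scan(self):
        # windows end at 1, 2, 3, 4 s
        sig = make_sig([0, 0, 3, 0], window_len=1.0)
        res = detect_onset(sig, threshold=2, onset_s=0)
        assert res.detect_time_s == pytest.approx(3.0)
        assert res.latency_s == pytest.approx(3.0)
        assert not res.is_fn

    def test_late_crossing_is_fn(self):
        sig = make_sig([0, 0, 0, 0, 0, 0, 9], window_len=1.0)  # ends 1..7 s
        res = detect_onset(sig, threshold=2, onset_s=0)
        assert res.detected and res.latency_s == pytest.approx(7.0) and res.is_fn

    def test_empty_signal_errors(self):
        with pytest.raises(ValueError):
            detect_onset(make_sig([]), threshold=1, onset_s=0)


class TestFalsePositiveRate:
    def test_threshold_above_max_is_zero(self):
        assert false_positive_rate(make_sig([1, 2, 3]), 10) == 0.0

    def test_all_above_is_hundred(self):
        sig = make_sig([1, 2, 3])
        assert false_positive_rate(sig, 0) == 100.0

    def test_matches_counting_loop(self, rng):
        u = rng.lognormal(size=300)
        th = float(np.median(u))
        got = false_positive_rate(make_sig(u), th)
        want = 100.0 * sum(1 for v in u if v > th) / len(u)
        assert got == pytest.approx(want)


def brute_force_th_fp(values, target):
    best = None
    for cand in sorted(set(values)):
        fp = np.count_nonzero(values > cand) / values.size
        if fp <= target:
            best = cand
            break
    return best


def brute_force_th_lat(sig, onset, target):
    best = None
    for cand in sorted(set(sig.values)):
        if cand <= 0:
            continue
        res = detect_onset(sig, cand, onset, fn_cutoff_s=np.inf)
        if res.detected and res.latency_s <= target:
            best = cand  # keep the largest passing candidate
    return best


class TestThresholdForFP:
    def test_distinct_values_order_statistic(self):
        sig = make_sig(np.arange(1.0, 101.0))
        assert threshold_for_fp(sig, 0.05) == 95.0

    def test_constant_signal_returns_constant(self):
        assert threshold_for_fp(make_sig(np.full(50, 7.0)), 0.05) == 7.0

    def test_result_satisfies_own_constraint_and_matches_scan(self, rng):
        for _ in range(50):
            u = rng.lognormal(size=rng.integers(20, 200))
            sig = make_sig(u)
            th = threshold_for_fp(sig, 0.05)
            assert false_positive_rate(sig, th) <= 5.0
            assert th == pytest.approx(brute_force_th_fp(u, 0.05))

    def test_bad_target_errors(self):
        with pytest.raises(ValueError):
            threshold_for_fp(make_sig([1.0]), 1.5)


class TestThresholdForLatency:
    def test_single_eligible_window(self):
        sig = make_sig([7.0], window_len=1.0)  # ends at 1 s
        assert threshold_for_latency(sig, onset_s=0, target_lat_s=2) == 7.0

    def test_max_of_eligible_windows(self):
        sig = make_sig([3.0, 9.0, 100.0], window_len=1.0)  # ends 1, 2, 3 s
        assert threshold_for_latency(sig, 0, 2) == 9.0

    def test_no_eligible_window_errors(self):
        sig = make_sig([1.0, 1.0], window_len=1.0)
        with pytest.raises(ValueError):
            threshold_for_latency(sig, onset_s=10, target_lat_s=2)

    def test_matches_scan_oracle_and_one_step_higher_fails(self, rng):
        for _ in range(50):
            u = rng.lognormal(mean=1.0, size=30)
            sig = make_sig(u, window_len=1.0)
            onset = float(rng.integers(0, 20))
            th = threshold_for_latency(sig, onset, 2.0)
            assert th == pytest.approx(brute_force_th_lat(sig, onset, 2.0))
            res = detect_onset(sig, th, onset, fn_cutoff_s=np.inf)
            assert res.latency_s <= 2.0
            res_hi = detect_onset(sig, th * (1 + 1e-9), onset, fn_cutoff_s=np.inf)
            assert (not res_hi.detected) or res_hi.latency_s > 2.0


class TestCalibrate:
    def seizure_sig(self, early_max):
        # windows end 1..6 s; onset 0; eligible windows (ends 1, 2 s)
        return make_sig([early_max / 2, early_max, 100, 100, 100, 100],
                        window_len=1.0)

    def test_single_seizure_candidate_is_th1(self):
        nonseiz = make_sig(np.full(100, 2.0))
        calib = calibrate([(self.seizure_sig(8.0), 0.0)], nonseiz)
        # th_fp = 2, th_lat = 8 → candidate (2+8)/2 = 5
        assert calib.th1 == pytest.approx(5.0)
        assert calib.per_seizure[0] == pytest.approx((2.0, 8.0, 5.0))

    def test_odd_count_median(self):
        nonseiz = make_sig(np.full(100, 0.0) + 1e-9)
        sigs = [(self.seizure_sig(2 * c), 0.0) for c in (1, 2, 9)]
        calib = calibrate(sigs, nonseiz)
        assert calib.th1 == pytest.approx(2.0, rel=1e-6)

    def test_even_count_median_is_mean_of_central_two(self):
        nonseiz = make_sig(np.full(100, 0.0) + 1e-9)
        sigs = [(self.seizure_sig(2 * c), 0.0) for c in (1, 3, 5, 7)]
        assert calibrate(sigs, nonseiz).th1 == pytest.approx(4.0, rel=1e-6)

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            calibrate([], make_sig([1.0]))


class TestEvaluateAndStableRange:
    def test_monotone_fp_and_fn_across_scales(self, rng):
        seiz = [(make_sig(np.concatenate([rng.lognormal(2, 1, 5),
                                          rng.lognormal(4, 1, 20)]),
                          window_len=1.0), 5.0) for _ in range(10)]
        nonseiz = make_sig(rng.lognormal(0, 1, 500))
        out = evaluate_at_scales(seiz, nonseiz, th1=np.exp(3))
        scales = sorted(out)
        fps = [out[s].fp_pct for s in scales]
        fns = [out[s].fn_pct for s in scales]
        assert all(a >= b for a, b in zip(fps, fps[1:]))
        assert all(a <= b for a, b in zip(fns, fns[1:]))

    def test_stable_range_width(self):
        seiz = make_sig([1, 50, 1, 1], window_len=1.0)
        wide = stable_range(seiz, 0.0, make_sig(np.full(100, 3.0)))
        assert wide.low == 3.0 and wide.high == 50.0 and wide.width == 47.0

    def test_inverted_range_clamps_to_zero(self):
        seiz = make_sig([1, 2, 1, 1], window_len=1.0)
        inv = stable_range(seiz, 0.0, make_sig(np.full(100, 30.0)))
        assert inv.width == 0.0


class TestRanks:
    def test_simple_ranking(self):
        np.testing.assert_array_equal(rank_features([3, 2, 1]), [1, 2, 3])

    def test_tie_gets_mean_rank(self):
        np.testing.assert_array_equal(rank_features([2, 2, 1]), [1.5, 1.5, 3])

    def test_aggregate_matches_sort_oracle(self, rng):
        widths = rng.uniform(size=(50, 7))
        mean_ranks, sds, firsts = aggregate_ranks(widths)
        oracle = np.zeros((50, 7))
        for i in range(50):
            order = np.argsort(-widths[i])
            for pos, j in enumerate(order):
                oracle[i, j] = pos + 1
        np.testing.assert_allclose(mean_ranks, oracle.mean(axis=0))
        np.testing.assert_allclose(sds, oracle.std(axis=0))
        np.testing.assert_array_equal(
            firsts, (oracle == 1).sum(axis=0))

    def test_tied_first_ranks_each_count(self):
        _, _, firsts = aggregate_ranks(np.array([[5.0, 5.0, 1.0]]))
        np.testing.assert_array_equal(firsts, [1, 1, 0])


class TestNormalizeAgainstThreshold:
    def test_at_threshold_maps_to_one(self):
        sig = make_sig(np.full(10, 4.0))
        np.testing.assert_allclose(
            normalize_against_threshold(sig, 4.0).values, 1.0)

    def test_zero_signal(self):
        np.testing.assert_array_equal(
            normalize_against_threshold(make_sig(np.zeros(5)), 2.0).values,
            np.zeros(5))

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            normalize_against_threshold(make_sig([1.0]), 0.0)

    def test_fp_count_equivalence(self, rng):
        u = rng.lognormal(size=200)
        sig = make_sig(u)
        th = float(np.median(u))
        norm = normalize_against_threshold(sig, th)
        assert (np.count_nonzero(norm.values > 1.0)
                == false_positive_rate(sig, th) * u.size / 100.0)
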