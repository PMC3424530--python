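"""Event-driven pairing and plasticity simulators: exact brute-force checks
for lag collection, hand-simulated update examples, and Monte-Carlo bridges
to the closed forms."""

import math

import numpy as np
import pytest

from stdpsync import (
    ALL_TO_ALL,
    NEAREST_NEIGHBOR,
    ProtocolSpec,
    SpikeTrain,
    SyncSpec,
    TripletParams,
    classify_coupling,
    collect_lags,
    doublet_kernel,
    estimate_dw_surface,
    expected_dw_sync,
    generate_one_spike_per_cycle,
    generate_pair,
    get_preset,
    lag_histogram,
    run_doublet,
    run_triplet_nn,
)
from stdpsync.kernels import powerlaw_amplitudes


def train(times, duration=None):
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = (times[-1] + 1.0) if times.size else 1.0
    return SpikeTrain(times=times, duration=duration)


def brute_force_aa(pre, post, d, max_lag):
    out = []
    for p in pre.times:
        for q in post.times:
            lag = q - p - d
            if abs(lag) <= max_lag:
                out.append(lag)
    return sorted(out)


def brute_force_nn(pre, post, d):
    out = []
    for p in pre.times:
        ps = p + d
        before = [q for q in post.times if q < ps]
        after = [q for q in post.times if q >= ps]
        if before:
            out.append(max(before) - ps)
        if after:
            out.append(min(after) - ps)
    return sorted(out)


class TestCollectLags:
    def test_single_pair_all_to_all(self):
        lags = collect_lags(train([10.0]), train([12.0]), 1.0, mode=ALL_TO_ALL)
        assert list(lags) == [1.0]

    def test_nearest_neighbor_hand_example(self):
        lags = collect_lags(train([10.0]), train([5.0, 12.0, 30.0], duration=31),
                            0.0, mode=NEAREST_NEIGHBOR)
        assert sorted(lags) == [-5.0, 2.0]  # 30 is not a nearest partner

    def test_identical_trains_symmetric_multiset(self, rng):
        t = train(np.sort(rng.uniform(0, 1000, 40)), duration=1001)
        lags = collect_lags(t, t, 0.0, mode=ALL_TO_ALL, max_lag=500)
        assert np.allclose(np.sort(lags), -np.sort(lags)[::-1])

    @pytest.mark.parametrize("d", [0.0, 1.0, -2.5])
    def test_all_to_all_equals_brute_force(self, rng, d):
        for _ in range(10):
            pre = train(np.sort(rng.uniform(0, 500, rng.integers(0, 50))), duration=501)
            post = train(np.sort(rng.uniform(0, 500, rng.integers(0, 50))), duration=501)
            got = sorted(collect_lags(pre, post, d, mode=ALL_TO_ALL, max_lag=80.0))
            assert got == pytest.approx(brute_force_aa(pre, post, d, 80.0))

    @pytest.mark.parametrize("d", [0.0, 1.0, -2.5])
    def test_nearest_neighbor_equals_brute_force(self, rng, d):
        for _ in range(10):
            pre = train(np.sort(rng.uniform(0, 500, rng.integers(0, 50))), duration=501)
            post = train(np.sort(rng.uniform(0, 500, rng.integers(0, 50))), duration=501)
            got = sorted(collect_lags(pre, post, d, mode=NEAREST_NEIGHBOR))
            assert got == pytest.approx(brute_force_nn(pre, post, d))

    def test_empty_trains_give_empty_multiset(self):
        assert collect_lags(train([]), train([5.0]), 0.0, mode=ALL_TO_ALL).size == 0
        assert collect_lags(train([5.0]), train([]), 0.0, mode=NEAREST_NEIGHBOR).size == 0


class TestLagHistogram:
    def test_single_lag_fills_one_bin(self):
        hist = lag_histogram([3.2], bin_width=1.0, lag_range=(-5, 5))
        assert hist.values.sum() == pytest.approx(1.0)
        assert hist.values.max() == pytest.approx(1.0)
        assert not hist.empty

    def test_uniform_lags_are_flat(self, rng):
        n = 50000
        lags = rng.uniform(-5, 5, n)
        hist = lag_histogram(lags, bin_width=1.0, lag_range=(-5, 5))
        p = 1.0 / 10
        se = math.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(hist.values - p) < 3 * se)

    def test_uncorrelated_poisson_all_to_all_is_flat(self):
        # rate coding: the all-to-all lag distribution is flat
        spec = ProtocolSpec(kind="rate", rate_mean=20.0, duration=100.0, seed=55)
        pre, post = generate_pair(spec)
        lags = collect_lags(pre, post, 0.0, mode=ALL_TO_ALL, max_lag=50.0)
        hist = lag_histogram(lags, bin_width=10.0, lag_range=(-50, 50))
        p = 1.0 / 10
        se = math.sqrt(p * (1 - p) / lags.size)
        assert np.all(np.abs(hist.values - p) < 4 * se)

    def test_empty_input_flagged(self):
        hist = lag_histogram([], bin_width=1.0, lag_range=(-5, 5))
        assert hist.empty
        assert np.all(hist.values == 0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            lag_histogram([1.0], bin_width=0.0, lag_range=(-5, 5))


class TestRunDoublet:
    def test_single_pair_total(self, vc_doublet):
        # one pre at 10, one post at 12, d=1: a single pairing at lag +1
        traj = run_doublet(train([10.0]), train([12.0]), 1.0, vc_doublet,
                           mode=ALL_TO_ALL)
        assert traj.total_dw == pytest.approx(1.3611627856e-2, rel=1e-9)

    def test_nearest_neighbor_hand_total(self, vc_doublet):
        # lags +2 and -5 contribute; F(2) + F(-5) from the kernel oracle
        traj = run_doublet(train([10.0]), train([5.0, 12.0, 30.0], duration=31),
                           0.0, vc_doublet, mode=NEAREST_NEIGHBOR)
        assert traj.total_dw == pytest.approx(6.30216227421e-3, rel=1e-9)

    def test_linear_total_is_order_invariant(self, vc_doublet, rng):
        pre = train(np.sort(rng.uniform(0, 2000, 60)), duration=2001)
        post = train(np.sort(rng.uniform(0, 2000, 60)), duration=2001)
        traj = run_doublet(pre, post, 1.0, vc_doublet, mode=ALL_TO_ALL)
        lags = collect_lags(pre, post, 1.0, mode=ALL_TO_ALL)
        shuffled = rng.permutation(lags)
        assert traj.total_dw == pytest.approx(float(np.sum(doublet_kernel(shuffled, vc_doublet))))

    def test_all_to_all_bridge_to_closed_form(self, vc_doublet):
        # one-spike-per-cycle at 5 Hz: same-cycle lags are exactly the
        # uniform window of the closed form; max_lag below the period
        # excludes cross-cycle pairs
        pre, post = generate_one_spike_per_cycle(5.0, 10.0, 50000, seed=77)
        lags = collect_lags(pre, post, 1.0, mode=ALL_TO_ALL, max_lag=90.0)
        dw = doublet_kernel(lags, vc_doublet)
        se = dw.std(ddof=1) / math.sqrt(dw.size)
        cf = expected_dw_sync(SyncSpec(10.0, 1.0), vc_doublet)
        assert abs(dw.mean() - cf) <= 3 * se

    def test_weight_dependent_amplitudes_recomputed(self):
        # nearest-neighbor pairs in update order: +5 (at 15), -85 (at 100),
        # +5 (at 105); each update must use the weight left by the previous
        # one (hand-tracked power-law amplitudes)
        p = get_preset("powerlaw_original")
        pre = train([10.0, 100.0], duration=200)
        post = train([15.0, 105.0], duration=200)
        traj = run_doublet(pre, post, 0.0, None, mode=NEAREST_NEIGHBOR,
                           weight_model=p, w_init=1.0)
        w = 1.0
        for lag in (5.0, -85.0, 5.0):
            ap, am = powerlaw_amplitudes(w, p)
            w += ap * math.exp(-lag / p.tau_plus) if lag > 0 else -am * math.exp(lag / p.tau_minus)
        assert traj.weights[-1] == pytest.approx(w)

    def test_interp_weights_stay_in_unit_interval(self, rng):
        p = get_preset("interp_multiplicative")
        spec = ProtocolSpec(kind="rate", rate_mean=30.0, duration=20.0, seed=9)
        pre, post = generate_pair(spec)
        traj = run_doublet(pre, post, 1.0, None, mode=NEAREST_NEIGHBOR,
                           weight_model=p, w_init=0.5)
        assert np.all((traj.weights >= 0) & (traj.weights <= 1))

    def test_clip_bounds_respected(self, vc_doublet):
        pre = train(np.arange(10.0, 500.0, 10.0), duration=500)
        post = train(np.arange(11.0, 500.0, 10.0), duration=500)
        traj = run_doublet(pre, post, 0.0, vc_doublet, mode=NEAREST_NEIGHBOR,
                           w_init=0.0, clip_bounds=(0.0, 0.05))
        assert np.all((traj.weights >= 0) & (traj.weights <= 0.05))

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError):
            run_doublet(train([1.0]), train([2.0]), 0.0, None)


class TestRunTripletNN:
    def test_no_presynaptic_spikes_zero_trajectory(self):
        traj = run_triplet_nn(train([]), train([10.0, 20.0], duration=30), 0.0,
                              get_preset("hippocampus_triplet"))
        assert traj.total_dw == 0.0

    def test_single_pair_hand_simulation(self):
        # pre at 10, post at 20: one LTP event with dt1=10 and undefined dt2
        # (triplet term zero); the pre spike has no preceding post, so no LTD
        p = get_preset("hippocampus_triplet")
        traj = run_triplet_nn(train([10.0]), train([20.0], duration=30), 0.0, p)
        assert traj.times.size == 1
        assert traj.total_dw == pytest.approx(2.53658378257e-3, rel=1e-9)

    def test_post_then_pre_gives_single_ltd(self):
        p = get_preset("hippocampus_triplet")
        traj = run_triplet_nn(train([20.0]), train([10.0], duration=30), 0.0, p)
        assert traj.times.size == 1
        assert traj.total_dw == pytest.approx(-p.a2_minus * math.exp(-10.0 / p.tau_minus))

    def test_triplet_term_uses_previous_postsynaptic_interval(self):
        # two posts after one pre: the second LTP event gains the triplet term
        p = get_preset("hippocampus_triplet")
        traj = run_triplet_nn(train([10.0]), train([20.0, 60.0], duration=100), 0.0, p)
        first = p.a2_plus * math.exp(-10.0 / p.tau_plus)
        second = math.exp(-50.0 / p.tau_plus) * (
            p.a2_plus + p.a3_plus * math.exp(-40.0 / p.tau_y)
        )
        assert traj.deltas == pytest.approx([first, second])

    def test_clip_bounds_respected(self):
        p = get_preset("visual_cortex_triplet")
        pre, post = generate_one_spike_per_cycle(20.0, 10.0, 2000, seed=5)
        traj = run_triplet_nn(pre, post, 1.0, p, w_init=0.01, clip_bounds=(0.0, 0.02))
        assert np.all((traj.weights >= 0.0) & (traj.weights <= 0.02))


class TestEstimateDwSurface:
    def test_zero_amplitude_model_gives_zero_surface(self):
        template = ProtocolSpec(kind="nonoscillatory", rate_mean=4.0, event_rate=2.0,
                                window_T=10.0, duration=5.0, seed=0)
        zero = TripletParams(0, 0, 0, 0, 16.8, 33.7, 575, 48)
        surface = estimate_dw_surface(template, zero, [5.0, 10.0], [0.0, 1.0],
                                      repeats=2, seed=1)
        assert np.all(surface.values == 0)
        assert surface.stderr.shape == surface.values.shape

    def test_standard_error_shrinks_with_repeats(self, vc_doublet):
        template = ProtocolSpec(kind="nonoscillatory", rate_mean=8.0, event_rate=4.0,
                                window_T=10.0, duration=5.0, seed=0)
        few = estimate_dw_surface(template, vc_doublet, [10.0], [1.0],
                                  repeats=8, seed=2)
        many = estimate_dw_surface(template, vc_doublet, [10.0], [1.0],
                                   repeats=32, seed=2)
        ratio = few.stderr[0, 0] / many.stderr[0, 0]
        assert 1.2 < ratio < 3.5  # expected factor 2, wide stochastic band

    def test_raw_totals_retained_on_request(self, vc_doublet):
        template = ProtocolSpec(kind="rate", rate_mean=10.0, duration=5.0, seed=0)
        per_post = estimate_dw_surface(template, vc_doublet, [10.0], [1.0],
                                       repeats=3, seed=4)
        raw = estimate_dw_surface(template, vc_doublet, [10.0], [1.0],
                                  repeats=3, seed=4, per_post_spike=False)
        assert raw.meta["quantity"] == "mean_total_dw"
        assert abs(raw.values[0, 0]) > abs(per_post.values[0, 0])

    def test_trajectory_text_round_trip(self, vc_doublet, tmp_path):
        pre = train([10.0, 30.0, 55.0], duration=100)
        post = train([12.0, 40.0], duration=100)
        traj = run_doublet(pre, post, 1.0, vc_doublet, mode=NEAREST_NEIGHBOR,
                           w_init=0.5)
        path = tmp_path / "traj.txt"
        traj.save(path)
        loaded = type(traj).load(path)
        assert np.array_equal(loaded.times, traj.times)
        assert np.array_equal(loaded.weights, traj.weights)
        assert loaded.w_init == traj.w_init

    def test_coupling_decoupling_signs(self, vc_doublet):
        # coarse synchronization potentiates, precise synchronization
        # depresses for positive delay (nonoscillatory protocol)
        template = ProtocolSpec(kind="nonoscillatory", rate_mean=4.0, event_rate=2.0,
                                window_T=10.0, duration=50.0, seed=0)
        surface = estimate_dw_surface(template, vc_doublet, [1.0, 10.0], [1.0],
                                      repeats=12, seed=3)
        assert surface.values[0, 0] < -3 * surface.stderr[0, 0]
        assert surface.values[1, 0] > 3 * surface.stderr[1, 0]


class TestClassifyCoupling:
    @pytest.mark.parametrize(
        "dw, se, expected",
        [
            (0.01, 0.001, "coupling"),
            (-0.01, 0.001, "decoupling"),
            (0.001, 0.01, "indeterminate"),
        ],
    )
    def test_three_way_classification(self, dw, se, expected):
        assert classify_coupling(dw, se) == expected

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            classify_coupling(0.0, -1.0)
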