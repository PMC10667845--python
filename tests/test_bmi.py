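"""Center-out metrics, comparison statistics, decoder and closed loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexephys.bmi import (
    accuracy,
    bh_fdr,
    compare_modes,
    decode_velocity,
    load_cursor_trials,
    path_efficiency,
    save_cursor_trials,
    simulate_closed_loop,
    task_metrics,
    time_cost,
    train_velocity_decoder,
    training_data_for_decoder,
)
from flexephys.session import CursorTrial
from flexephys.synthetic import gen_cursor_trials


def make_trial(points, direction=0.0, dt=0.05, success=True, mode="hand",
               distance=7.5, radius=1.85):
    pts = np.asarray(points, dtype=float)
    return CursorTrial(
        times=np.arange(pts.shape[0]) * dt,
        positions=pts,
        target_direction_deg=direction,
        target_distance_cm=distance,
        target_radius_cm=radius,
        mode=mode,
        success=success,
    )


class TestPathEfficiency:
    def test_straight_path_exactly_one(self):
        t = make_trial([[0, 0], [3, 0], [6, 0]], direction=0.0)
        assert path_efficiency(t) == 1.0

    def test_right_angle_path(self):
        # two equal legs to a target on the hypotenuse end: sqrt(2)/2
        t = make_trial([[0, 0], [7.5 / np.sqrt(2), 0],
                        [7.5 / np.sqrt(2), 7.5 / np.sqrt(2)]], direction=45.0)
        assert path_efficiency(t) == pytest.approx(np.sqrt(2) / 2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_never_exceeds_one(self, seed):
        r = np.random.default_rng(seed)
        steps = r.normal(0, 1.0, (20, 2))
        pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        target = pts[-1]
        d = np.hypot(*target)
        t = make_trial(pts, direction=np.degrees(np.arctan2(target[1], target[0])),
                       distance=d, radius=0.2)
        try:
            pe = path_efficiency(t)
        except ValueError:
            return  # path never enters the disk before the end
        if np.isnan(pe):
            return  # start already inside the disk: zero traveled distance
        assert pe <= 1.0 + 1e-12

    def test_rigid_motion_invariance(self, rng):
        pts = np.vstack([[0, 0], np.cumsum(rng.normal(0, 1, (15, 2)), axis=0)])
        target = pts[-1]
        ang = np.degrees(np.arctan2(target[1], target[0]))
        t1 = make_trial(pts, direction=ang, distance=np.hypot(*target), radius=0.5)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        pts2 = pts @ R.T + np.array([3.0, -1.0])
        tgt2 = pts2[-1] - pts2[0]
        t2 = CursorTrial(times=t1.times, positions=pts2,
                         target_direction_deg=np.degrees(np.arctan2(tgt2[1], tgt2[0])),
                         target_distance_cm=np.hypot(*tgt2), target_radius_cm=0.5,
                         mode="hand", success=True)
        t2.positions -= pts2[0]  # same start so geometry matches
        assert path_efficiency(t2) == pytest.approx(path_efficiency(t1), rel=1e-9)


class TestTimeCostAccuracy:
    def test_acquisition_time(self):
        pts = [[0, 0]] + [[7.5 * k / 25, 0] for k in range(1, 26)]
        t = make_trial(pts, direction=0.0)
        # enters the 1.85 cm disk at x >= 5.65 -> sample 19 -> 0.95 s
        assert time_cost(t) == pytest.approx(0.95)

    def test_failed_trials_excluded_from_metrics(self):
        good = make_trial([[0, 0], [7.5, 0]], success=True)
        bad = make_trial([[0, 0], [0.5, 0]], success=False)
        m = task_metrics([good, bad])
        assert m.time_cost_s.size == 1

    def test_accuracy_fraction(self):
        trials = [make_trial([[0, 0], [7.5, 0]], success=(i < 8)) for i in range(10)]
        assert accuracy(trials)[0.0] == pytest.approx(0.8)

    def test_pooled_accuracy_is_weighted_mean(self):
        trials = (
            [make_trial([[0, 0], [7.5, 0]], direction=0.0, success=s)
             for s in (True, True, False)]
            + [make_trial([[0, 0], [0, 7.5]], direction=90.0, success=s)
               for s in (True, False)]
        )
        acc = accuracy(trials)
        pooled = np.mean([t.success for t in trials])
        weights = {0.0: 3, 90.0: 2}
        weighted = sum(acc[d] * w for d, w in weights.items()) / 5
        assert pooled == pytest.approx(weighted)


class TestBHFDR:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == 0.2

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_matches_statsmodels(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        from statsmodels.stats.multitest import multipletests

        _, ref, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(adj, ref, atol=1e-12)


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumeration over rank assignments."""
    pooled = np.r_[x, y]
    n1 = len(x)
    obs_u = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )
        us.append(u)
    us = np.asarray(us)
    mu = len(x) * len(y) / 2
    return np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-12)


class TestMannWhitney:
    def test_textbook_case_exact_p(self):
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(0.1)
        assert mwu_exact_oracle(np.array([1., 2, 3]), np.array([4., 5, 6])) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_scipy_matches_enumeration_oracle(self, seed):
        from scipy.stats import mannwhitneyu

        r = np.random.default_rng(seed)
        x = r.normal(0, 1, int(r.integers(3, 8)))
        y = r.normal(0.5, 1, int(r.integers(3, 8)))
        p = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(mwu_exact_oracle(x, y), abs=1e-9)


class TestCompareModes:
    def _trials(self, successes, direction=0.0, mode="hand", time_scale=1.0, seed=0):
        r = np.random.default_rng(seed)
        out = []
        for s in successes:
            n = int(r.integers(10, 20))
            pts = np.vstack([np.linspace(0, 7.5, n), np.zeros(n)]).T
            jitterdt = time_scale * 0.05
            t = CursorTrial(times=np.arange(n) * jitterdt + r.uniform(0, 0.01),
                            positions=pts, target_direction_deg=direction,
                            mode=mode, success=bool(s))
            out.append(t)
        return out

    def test_identical_success_vectors_p_near_one(self):
        h = self._trials([1] * 10 + [0] * 5, mode="hand", seed=1)
        b = self._trials([1] * 10 + [0] * 5, mode="brain", seed=2)
        df = compare_modes(h, b, seed=0)
        assert df["accuracy_p"].iloc[0] > 0.5

    def test_extreme_difference_significant_after_fdr(self):
        h = self._trials([1] * 20, mode="hand", seed=3)
        b = self._trials([0] * 20 + [1], mode="brain", seed=4)  # one success for stats
        df = compare_modes(h, b, seed=0)
        assert df["accuracy_p_adj"].iloc[0] < 0.01

    def test_type_one_error_controlled(self):
        # identical generating distributions: rejection rate <= alpha
        r = np.random.default_rng(0)
        rejections = {"accuracy": 0, "time_cost": 0}
        n_rep = 200
        for rep in range(n_rep):
            succ_h = r.uniform(size=15) < 0.7
            succ_b = r.uniform(size=15) < 0.7
            h = self._trials(succ_h, mode="hand", time_scale=1.0, seed=rep)
            b = self._trials(succ_b, mode="brain", time_scale=1.0, seed=10_000 + rep)
            df = compare_modes(h, b, n_boot=300, seed=rep)
            if df["accuracy_p"].iloc[0] < 0.05:
                rejections["accuracy"] += 1
            p = df["time_cost_p"].iloc[0]
            if np.isfinite(p) and p < 0.05:
                rejections["time_cost"] += 1
        for metric, k in rejections.items():
            assert k / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep), metric


class TestDecoder:
    def test_exact_linear_map_recovered(self, rng):
        X = rng.normal(0, 1, (500, 6))
        W_true = rng.normal(0, 1, (6, 2))
        Y = X @ W_true + 0.5
        W = train_velocity_decoder(X, Y, ridge_lambda=0.0)
        np.testing.assert_allclose(W[:-1], W_true, atol=1e-8)
        np.testing.assert_allclose(decode_velocity(W, X), Y, atol=1e-8)

    def test_heavy_ridge_shrinks_weights(self, rng):
        X = rng.normal(0, 1, (200, 4))
        Y = rng.normal(0, 1, (200, 2))
        W = train_velocity_decoder(X, Y, ridge_lambda=1e9)
        assert np.abs(W[:-1]).max() < 1e-4

    def test_cosine_population_decodes_direction(self):
        pds = np.arange(0, 360, 30.0)
        X, V = training_data_for_decoder(pds, n_samples=4000, seed=1)
        W = train_velocity_decoder(X, V, ridge_lambda=1.0)
        Xt, Vt = training_data_for_decoder(pds, n_samples=500, seed=2)
        pred = decode_velocity(W, Xt)
        ang_err = np.degrees(np.abs(np.angle(
            (pred[:, 0] + 1j * pred[:, 1]) / (Vt[:, 0] + 1j * Vt[:, 1])
        )))
        assert np.median(ang_err) < 30.0


class TestClosedLoop:
    def _decoder(self, pds, noise=True):
        X, V = training_data_for_decoder(pds, n_samples=4000, noise=noise, seed=11)
        return train_velocity_decoder(X, V, ridge_lambda=1.0)

    def test_noiseless_perfect_control(self):
        pds = np.arange(0, 360, 30.0)
        W = self._decoder(pds, noise=False)
        trials = simulate_closed_loop(W, pds, n_trials=8, noise=False, seed=0)
        m = task_metrics(trials)
        assert all(t.success for t in trials)
        assert np.all(m.path_efficiency > 0.95)

    def test_shuffled_weights_fail_on_average(self):
        # a shuffled readout is a random linear map; closed-loop feedback can
        # rescue individual shuffles, so chance behavior is tested in the mean
        pds = np.arange(0, 360, 30.0)
        W = self._decoder(pds)
        accs = []
        for s in range(10):
            r = np.random.default_rng(s)
            W_shuf = W.copy()
            r.shuffle(W_shuf[:-1])
            trials = simulate_closed_loop(W_shuf, pds, n_trials=16, seed=1)
            accs.append(np.mean([t.success for t in trials]))
        assert np.mean(accs) < 0.5

    def test_fixed_seed_reproducible(self):
        pds = np.arange(0, 360, 45.0)
        W = self._decoder(pds)
        a = simulate_closed_loop(W, pds, n_trials=4, seed=3)
        b = simulate_closed_loop(W, pds, n_trials=4, seed=3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)


class TestCursorCSV:
    def test_round_trip(self, tmp_path):
        trials = gen_cursor_trials(n_trials=6, noise_level=0.3, seed=2)
        save_cursor_trials(trials, tmp_path / "t.csv")
        loaded = load_cursor_trials(tmp_path / "t.csv")
        assert len(loaded) == 6
        for t0, t1 in zip(trials, loaded):
            np.testing.assert_allclose(t0.positions, t1.positions)
            assert t0.success == t1.success and t0.mode == t1.mode
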