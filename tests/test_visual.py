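"""Orientation tuning, OSI, receptive-field mapping and the depth model."""

import numpy as np
import pandas as pd
import pytest

from flexephys.synthetic import gen_orientation_session
from flexephys.visual import (
    orientation_curve,
    osi,
    preferred_orientation,
    rf_depth_model,
    rf_fit,
    rf_map,
    trial_rates,
)


def curve_from(rates, orientations):
    return orientation_curve(np.asarray(rates, float), np.asarray(orientations, float))


GRID8 = np.arange(0, 180, 22.5)


class TestTrialRates:
    def test_five_spikes_in_half_second(self):
        trials = pd.DataFrame({"trial_id": [0], "onset_s": [1.0], "offset_s": [1.5]})
        t = np.array([1.05, 1.1, 1.2, 1.3, 1.45])
        assert trial_rates(t, trials)[0] == pytest.approx(10.0)

    def test_empty_train_zero(self):
        trials = pd.DataFrame({"trial_id": [0], "onset_s": [0.0], "offset_s": [1.0]})
        assert trial_rates(np.array([]), trials)[0] == 0.0

    def test_disjoint_windows_sum_to_union_count(self, rng):
        t = np.sort(rng.uniform(0, 10, 200))
        trials = pd.DataFrame({"trial_id": [0, 1], "onset_s": [1.0, 2.0],
                               "offset_s": [2.0, 3.0]})
        r = trial_rates(t, trials)
        union = np.sum((t >= 1.0) & (t < 3.0))
        assert r.sum() == pytest.approx(union)


class TestOrientationCurve:
    def test_flat_curve_normalizes_to_one(self):
        c = curve_from([5, 5, 5, 5], [0, 45, 90, 135])
        np.testing.assert_allclose(c.normalized, 1.0)

    def test_max_condition_is_exactly_one(self, rng):
        rates = rng.uniform(1, 20, 40)
        oris = np.tile([0.0, 45.0, 90.0, 135.0], 10)
        c = orientation_curve(rates, oris)
        assert c.normalized.max() == 1.0

    def test_single_trial_sem_zero_with_warning(self):
        with pytest.warns(UserWarning):
            c = curve_from([3, 8], [0, 90])
        np.testing.assert_array_equal(c.sem_hz, 0.0)

    def test_sem_formula(self, rng):
        rates = np.array([1.0, 3.0, 1.0, 3.0])
        oris = np.array([0.0, 0.0, 90.0, 90.0])
        c = orientation_curve(rates, oris)
        assert c.sem_hz[0] == pytest.approx(np.std([1, 3], ddof=1) / np.sqrt(2))


class TestOSI:
    def test_orth_zero_gives_one(self):
        c = curve_from([10, 0, 0, 0], [0, 45, 90, 135])
        assert osi(c) == 1.0

    def test_flat_curve_zero(self):
        c = curve_from([4, 4, 4, 4], [0, 45, 90, 135])
        assert osi(c) == 0.0

    def test_boundary_value_fails_strict_selectivity_gate(self):
        c = curve_from([6.5, 5, 3.5, 5], [0, 45, 90, 135])
        assert osi(c) == pytest.approx(0.3)
        assert not osi(c) > 0.3

    def test_range_bounded(self, rng):
        for _ in range(20):
            c = curve_from(rng.uniform(0, 30, 8), GRID8)
            assert 0.0 <= osi(c) <= 1.0

    def test_circular_variance_variant_limits(self):
        c = curve_from([4, 4, 4, 4], [0, 45, 90, 135])
        assert osi(c, method="circular_variance") == pytest.approx(0.0)


class TestPreferredOrientation:
    def test_single_nonzero_condition(self):
        c = curve_from([0, 0, 7, 0], [0, 30, 60, 90])
        assert preferred_orientation(c) == pytest.approx(60.0)

    def test_symmetric_peaks_undefined(self):
        c = curve_from([5, 0, 5, 0], [0, 45, 90, 135])
        assert np.isnan(preferred_orientation(c))

    def test_rotation_equivariance(self, rng):
        rates = rng.uniform(0, 10, 8)
        base = preferred_orientation(curve_from(rates, GRID8))
        for delta in (22.5, 45.0, 67.5):
            rolled = preferred_orientation(curve_from(np.roll(rates, 1), GRID8))
        assert rolled == pytest.approx((base + 22.5) % 180.0, abs=1e-6)

    def test_von_mises_unit_recovered_within_half_grid(self):
        s, truth = gen_orientation_session(
            n_units=3, n_trials_per_orientation=30, seed=21,
            tuning_params={"kappa": 2.0},
        )
        for u in s.units:
            rates = trial_rates(u.spike_times, s.trials)
            c = orientation_curve(rates, s.trials["orientation_deg"].to_numpy())
            est = preferred_orientation(c)
            true = truth.units[u.unit_id]["pref_orientation_deg"]
            d = abs(est - true) % 180
            assert min(d, 180 - d) <= 11.25


def gaussian_grid(center=(3.0, -2.0), sigma=0.8, amp=20.0, extent=8, step=1.0):
    xs = np.arange(-extent, extent + step, step)
    pts = [(x, y) for x in xs for y in xs]
    df = pd.DataFrame(pts, columns=["x_deg", "y_deg"])
    df["rate_hz"] = amp * np.exp(
        -((df.x_deg - center[0]) ** 2 + (df.y_deg - center[1]) ** 2) / (2 * sigma**2)
    )
    return df


class TestRF:
    def _trials_grid(self, rng, locations, n_rep=4, dur=0.5, gap=0.5):
        rows = []
        t = gap
        tid = 0
        for _ in range(n_rep):
            for (x, y) in locations:
                rows.append({"trial_id": tid, "onset_s": t, "offset_s": t + dur,
                             "grid_x_deg": x, "grid_y_deg": y})
                tid += 1
                t += dur + gap
        return pd.DataFrame(rows)

    def test_one_hot_response_grid(self, rng):
        locs = [(0, 0), (2, 0), (0, 2)]
        trials = self._trials_grid(rng, locs)
        spikes = []
        for row in trials.itertuples():
            if (row.grid_x_deg, row.grid_y_deg) == (2, 0):
                spikes.extend(np.linspace(row.onset_s + 0.01, row.offset_s - 0.01, 10))
        grid = rf_map(np.array(sorted(spikes)), trials)
        hot = grid[(grid.x_deg == 2) & (grid.y_deg == 0)]["rate_hz"].iloc[0]
        cold = grid[(grid.x_deg != 2) | (grid.y_deg != 0)]["rate_hz"]
        assert hot > 0 and np.allclose(cold, 0.0)

    def test_unresponsive_unit_flat_grid(self, rng):
        locs = [(0, 0), (2, 0)]
        trials = self._trials_grid(rng, locs, n_rep=10)
        t = np.sort(rng.uniform(0, trials.offset_s.max() + 0.5, 400))
        grid = rf_map(t, trials)
        assert np.abs(grid["rate_hz"]).max() < 3.0

    def test_gaussian_response_correlates_with_truth(self, rng):
        locs = [(x, y) for x in range(-3, 4) for y in range(-3, 4)]
        trials = self._trials_grid(rng, locs, n_rep=3)
        spikes = []
        for row in trials.itertuples():
            lam = 30 * np.exp(-((row.grid_x_deg - 1) ** 2 + (row.grid_y_deg + 1) ** 2) / 2)
            n = rng.poisson(lam * 0.5)
            spikes.extend(rng.uniform(row.onset_s, row.offset_s, n))
        grid = rf_map(np.array(sorted(spikes)), trials)
        truth = 30 * np.exp(-((grid.x_deg - 1) ** 2 + (grid.y_deg + 1) ** 2) / 2)
        assert np.corrcoef(grid["rate_hz"], truth)[0, 1] > 0.9

    def test_fit_recovers_noiseless_gaussian(self):
        rf = rf_fit(gaussian_grid())
        assert rf.fit_ok
        assert rf.center_deg[0] == pytest.approx(3.0, abs=0.1)
        assert rf.center_deg[1] == pytest.approx(-2.0, abs=0.1)
        assert rf.size_deg == pytest.approx(1.6, abs=0.05)
        assert rf.eccentricity_deg == pytest.approx(np.sqrt(13), abs=0.1)

    def test_flat_grid_fit_fails(self):
        df = gaussian_grid()
        df["rate_hz"] = 0.0
        assert not rf_fit(df).fit_ok

    def test_isotropic_scaling_scales_size(self):
        a = rf_fit(gaussian_grid(sigma=0.8))
        b = rf_fit(gaussian_grid(center=(6.0, -4.0), sigma=1.6, extent=16, step=2.0))
        assert b.size_deg == pytest.approx(2 * a.size_deg, rel=0.05)


def make_depth_data(rng, slope_per_mm=0.3, n_shanks=6, n_per=20, noise=0.2,
                    shank_slope_sd=0.05, shank_intercept_sd=0.2):
    depths = np.tile(np.linspace(100, 1400, n_per), n_shanks)
    shanks = np.repeat([f"s{i}" for i in range(n_shanks)], n_per)
    slopes = slope_per_mm + rng.normal(0, shank_slope_sd, n_shanks)
    inter = 1.0 + rng.normal(0, shank_intercept_sd, n_shanks)
    sizes = (np.repeat(inter, n_per) + np.repeat(slopes, n_per) * depths / 1000.0
             + rng.normal(0, noise, depths.size))
    return sizes, depths, shanks


class TestDepthModel:
    def test_recovers_known_slope(self, rng):
        sizes, depths, shanks = make_depth_data(rng)
        res = rf_depth_model(sizes, depths, shanks)
        lo, hi = res["ci95"]
        assert lo < 0.3 < hi
        assert res["p"] < 0.05

    def test_degenerate_common_slope_recovered(self):
        rng = np.random.default_rng(0)
        sizes, depths, shanks = make_depth_data(rng, noise=1e-9, shank_slope_sd=0.0,
                                                shank_intercept_sd=0.0)
        res = rf_depth_model(sizes, depths, shanks)
        assert res["slope"] == pytest.approx(0.3, abs=1e-4)

    def test_requires_multiple_shanks(self, rng):
        with pytest.raises(ValueError):
            rf_depth_model([1, 2, 3], [100, 200, 300], ["a", "a", "a"])
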