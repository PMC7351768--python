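"""Instantaneous MSD, D_inst, the rod reference diffusivity, and maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecsnano.diffusivity import (BOLTZMANN_J_PER_K, MsdCurve,
                                 ReferenceMedium, d_reference,
                                 exploration_area, fit_d_inst, make_map,
                                 msd_instantaneous, relative_diffusivity)
from ecsnano.tracking import Trajectory

from conftest import walker_trajectory


def traj_from_xy(xy, dt=0.030):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(0, np.arange(len(xy)), xy, np.zeros(len(xy)), dt_s=dt)


class TestMsdInstantaneous:
    def test_stationary_points_zero_msd(self):
        curves = msd_instantaneous(traj_from_xy(np.zeros((30, 2))))
        assert len(curves) == 30 - 15 + 1
        for c in curves:
            assert np.allclose(c.msd_nm2, 0.0)

    def test_ballistic_motion_quadratic_msd(self):
        v = 100.0  # nm/s
        t = np.arange(40) * 0.030
        xy = np.column_stack([v * t, np.zeros(40)])
        for c in msd_instantaneous(traj_from_xy(xy)):
            assert np.allclose(c.msd_nm2, (v * c.lags_s) ** 2, rtol=1e-9)

    def test_brownian_windowed_msd_matches_4dt(self):
        d_true = 1e6
        msd_sum = {}
        n_windows = 0
        for seed in range(4):
            traj = walker_trajectory(None, d_true, 260, seed=seed)
            for c in msd_instantaneous(traj):
                n_windows += 1
                for lag, v in zip(np.round(c.lags_s / 0.030).astype(int),
                                  c.msd_nm2):
                    msd_sum.setdefault(lag, []).append(v)
        assert n_windows >= 200
        for lag in (1, 2, 3):
            pooled = np.mean(msd_sum[lag])
            assert pooled == pytest.approx(4 * d_true * lag * 0.030,
                                           rel=0.10)

    def test_short_trajectory_empty(self):
        assert msd_instantaneous(traj_from_xy(np.zeros((10, 2)))) == []


class TestFitDInst:
    @staticmethod
    def _curve(lags, msd):
        return MsdCurve(np.asarray(lags, float), np.asarray(msd, float),
                        0.0, np.zeros(2), np.ones(len(lags), int))

    def test_exact_line(self):
        lags = np.array([0.03, 0.06, 0.09])
        d, floored = fit_d_inst(self._curve(lags, 4.0 * lags))
        assert d == pytest.approx(1.0, rel=1e-12)
        assert not floored

    def test_intercept_absorbs_static_offset(self):
        lags = np.array([0.03, 0.06, 0.09])
        d0, _ = fit_d_inst(self._curve(lags, 4.0 * lags))
        db, _ = fit_d_inst(self._curve(lags, 4.0 * lags + 900.0))
        assert db == pytest.approx(d0, rel=1e-9)

    def test_negative_slope_floored(self):
        lags = np.array([0.03, 0.06, 0.09])
        d, floored = fit_d_inst(self._curve(lags, [30.0, 20.0, 10.0]))
        assert d == 0.0 and floored

    def test_brownian_recovery_within_ten_percent(self):
        d_true = 0.5e6
        vals = []
        for seed in range(100):
            traj = walker_trajectory(None, d_true, 100, seed=1000 + seed)
            for c in msd_instantaneous(traj):
                vals.append(fit_d_inst(c)[0])
        assert np.median(vals) == pytest.approx(d_true, rel=0.10)


class TestDReference:
    def test_matches_arbitrary_precision_evaluation(self):
        # independent sympy re-derivation, 10 significant digits
        import sympy as sp

        kB = sp.Rational(1380649, 10**6) * sp.Integer(10) ** -23
        for L_nm in (200.0, 500.0, 1000.0):
            for T in (298.15, 310.15):
                for eta in (0.70e-3, 1.0e-3):
                    phi = sp.Float(L_nm, 30)  # diameter 1 nm
                    expr = (3 * kB * sp.Float(T, 30) * sp.log(2 * phi)) / (
                        8 * sp.pi * sp.Float(eta, 30)
                        * sp.Float(L_nm, 30) * sp.Integer(10) ** -9
                    ) * sp.Integer(10) ** 18
                    expected = float(expr.evalf(30))
                    got = d_reference(
                        L_nm, ReferenceMedium(T, eta, 1.0))
                    assert abs(got - expected) <= 1e-10 * abs(expected)

    def test_reference_value_500nm_rod(self):
        # L = 500 nm, phi = 500, T = 310.15 K, eta = 0.70 mPa s
        d = d_reference(500.0)
        assert d * 1e-18 == pytest.approx(1.01e-11, rel=0.005)

    def test_viscosity_doubling_halves_d(self):
        m1 = ReferenceMedium(viscosity_Pa_s=0.7e-3)
        m2 = ReferenceMedium(viscosity_Pa_s=1.4e-3)
        assert d_reference(500.0, m1) == pytest.approx(
            2 * d_reference(500.0, m2), rel=1e-12)

    def test_strictly_decreasing_in_length(self):
        # d/dL < 0 once ln(2 phi) > 1, i.e. L > e/2 nm for 1 nm diameter
        grid = np.linspace(5.0, 2000.0, 200)
        vals = [d_reference(L) for L in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            d_reference(0.0)


class TestRelativeDiffusivity:
    def test_hindered_walkers_recover_ratio(self):
        d_ref = d_reference(500.0)
        trajs = []
        for seed in range(40):
            t = walker_trajectory(None, 0.03 * d_ref, 120, seed=seed)
            t.length_nm, t.length_defined = 500.0, True
            trajs.append(t)
        est = relative_diffusivity(trajs)
        med = np.median([e.ratio for e in est])
        assert 0.024 <= med <= 0.036

    def test_unhindered_ratio_is_one(self):
        d_ref = d_reference(500.0)
        lags = np.arange(1, 4) * 0.030
        t = traj_from_xy(np.zeros((20, 2)))
        t.length_nm, t.length_defined = 500.0, True
        # construct an exact MSD = 4 D_ref tau trajectory via ballistic
        # check instead on the formula level:
        from ecsnano.diffusivity import MsdCurve, fit_d_inst
        c = MsdCurve(lags, 4 * d_ref * lags, 0.0, np.zeros(2),
                     np.ones(3, int))
        assert fit_d_inst(c)[0] / d_ref == pytest.approx(1.0, rel=1e-12)

    def test_all_immobile_empty(self):
        t = traj_from_xy(np.zeros((40, 2)))
        t.immobile = True
        assert relative_diffusivity([t]) == []

    def test_undefined_length_uses_cohort_median(self):
        rng = np.random.default_rng(3)
        trajs = []
        for k in range(3):
            xy = np.cumsum(rng.normal(0, 150.0, (40, 2)), axis=0)
            t = traj_from_xy(xy)
            t.id = k
            if k < 2:
                t.length_nm, t.length_defined = 400.0, True
            trajs.append(t)
        est = relative_diffusivity(trajs)
        flagged = [e for e in est if e.traj_id == 2]
        assert flagged and all(e.length_imputed for e in flagged)
        assert flagged[0].d_ref_nm2_s == pytest.approx(d_reference(400.0))


class TestMaps:
    def test_single_localization_density_peak_unit(self):
        m = make_map(np.array([[100.0, 100.0]]), mode="density")
        assert m.data.max() == pytest.approx(1.0, abs=1e-12)

    def test_constant_values_give_constant_map(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 2000, (50, 2))
        m = make_map(pts, np.full(50, 3.7), mode="mean_value")
        sup = ~np.isnan(m.data)
        assert np.allclose(m.data[sup], 3.7)

    def test_two_distant_clusters_keep_their_values(self):
        rng = np.random.default_rng(1)
        a = rng.normal([500.0, 500.0], 30.0, (200, 2))
        b = rng.normal([50_000.0, 500.0], 30.0, (200, 2))
        pts = np.vstack([a, b])
        vals = np.concatenate([np.full(200, 0.02), np.full(200, 0.2)])
        m = make_map(pts, vals, mode="mean_value")
        cols = (pts[:, 0] - m.origin_nm[0]) / m.pixel_size_nm
        left = m.data[:, : int(cols[:200].max()) + 1]
        right = m.data[:, int(cols[200:].min()):]
        assert np.nanmedian(left) == pytest.approx(0.02, rel=0.01)
        assert np.nanmedian(right) == pytest.approx(0.2, rel=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(1, 40))
    def test_mean_value_maps_are_convex_combinations(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1500, (n, 2))
        vals = rng.uniform(-5, 5, n)
        m = make_map(pts, vals, mode="mean_value")
        sup = ~np.isnan(m.data)
        assert np.all(m.data[sup] >= vals.min() - 1e-9)
        assert np.all(m.data[sup] <= vals.max() + 1e-9)


class TestExplorationArea:
    def test_single_localization_half_max_disc(self):
        # brute-force rasterization oracle: pixels of a 50 nm FWHM,
        # unit-amplitude Gaussian with value >= 0.5 on a 25 nm grid
        m = make_map(np.array([[100.0, 100.0]]), mode="density")
        sigma = 50.0 / (2 * np.sqrt(2 * np.log(2)))
        ys, xs = np.indices(m.data.shape)
        xc = m.origin_nm[0] + xs * 25.0
        yc = m.origin_nm[1] + ys * 25.0
        g = np.exp(-((xc - 100) ** 2 + (yc - 100) ** 2) / (2 * sigma**2))
        expected = (g >= 0.5).sum() * 625.0 / 1e6
        assert exploration_area(m) == pytest.approx(expected, abs=1e-12)

    def test_superset_covers_at_least_subset(self):
        rng = np.random.default_rng(2)
        sub = rng.uniform(0, 3000, (50, 2))
        sup = np.vstack([sub, rng.uniform(0, 3000, (50, 2))])
        a_sub = exploration_area(make_map(sub, mode="density"))
        a_sup = exploration_area(make_map(sup, mode="density"))
        assert a_sup >= a_sub

    def test_mean_value_map_rejected(self):
        m = make_map(np.zeros((1, 2)), np.ones(1), mode="mean_value")
        with pytest.raises(ValueError):
            exploration_area(m)
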