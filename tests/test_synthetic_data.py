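"""Ground-truth generators: geometry, walkers, rendering, masks, fractals."""

import numpy as np
import pytest
from scipy import ndimage, stats

from ecsnano.synthetic_data import (CameraModel, GeometryError, SceneGeometry,
                                    TruthTrack, generate_ecs_mask,
                                    generate_geometry,
                                    generate_reference_fractal, render_movie,
                                    simulate_walker)

from conftest import make_channel_geometry


class TestGeometry:
    def test_single_disc_inside_predicate(self):
        geom = SceneGeometry(np.array([[500.0, 500.0, 100.0]]),
                             np.empty((0, 5)), (1000.0, 1000.0))
        pts = np.array([
            [500.0, 500.0],   # centre
            [599.0, 500.0],   # just inside
            [601.0, 500.0],   # just outside
            [500.0, 401.0],
            [10.0, 10.0],
        ])
        assert list(geom.inside(pts)) == [True, True, False, True, False]

    def test_generated_geometry_is_connected(self):
        geom = generate_geometry(4, seed=3)
        mask = geom.rasterize(10.0)
        _labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        assert n == 1

    def test_channel_endpoints_inside_pools(self):
        geom = generate_geometry(5, seed=11)
        for x1, y1, x2, y2, _w in geom.channels:
            assert geom.inside(np.array([[x1, y1], [x2, y2]])).all()

    def test_seed_determinism(self):
        a = generate_geometry(3, seed=42)
        b = generate_geometry(3, seed=42)
        assert np.array_equal(a.pools, b.pools)
        assert np.array_equal(a.channels, b.channels)

    def test_nonpositive_ranges_rejected(self):
        with pytest.raises(ValueError):
            generate_geometry(2, pool_radius_range_nm=(0.0, 10.0))


class TestWalker:
    def test_unconfined_msd_slope_matches_theory(self):
        # free 2D Brownian motion: MSD(dt) = 4 D dt
        d_true = 1e6  # 1 um^2/s in nm^2/s
        track = simulate_walker(None, d_true, 100_000, 0.030, seed=2)
        steps = np.diff(track.positions, axis=0)
        d_est = (steps**2).sum(axis=1).mean() / (4 * 0.030)
        assert d_est == pytest.approx(d_true, rel=0.03)

    def test_zero_diffusivity_is_static(self):
        track = simulate_walker(None, 0.0, 100, 0.030, seed=1)
        assert np.allclose(track.positions, track.positions[0])

    def test_channel_confinement_bounds_transverse_variance(self):
        geom = make_channel_geometry(50.0)
        track = simulate_walker(geom, 1e6, 3000, 0.030, seed=3,
                                start_nm=[2200.0, 500.0])
        y = track.positions[:, 1]
        assert geom.inside(track.positions).all()
        assert y.var() <= 50.0**2 / 4  # hard reflection bound
        assert y.min() >= 475.0 - 1e-6 and y.max() <= 525.0 + 1e-6

    def test_start_outside_geometry_rejected(self):
        geom = make_channel_geometry(50.0)
        with pytest.raises(ValueError, match="outside"):
            simulate_walker(geom, 1e6, 10, 0.030, start_nm=[0.0, 0.0])

    def test_seed_determinism(self):
        a = simulate_walker(None, 1e5, 50, 0.030, seed=9)
        b = simulate_walker(None, 1e5, 50, 0.030, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_two_pool_occupancy_proportional_to_areas(self):
        # equilibrium occupancy of a two-pool dumbbell tracks pool areas
        geom = SceneGeometry(
            pools=np.array([[300.0, 300.0, 100.0], [800.0, 300.0, 150.0]]),
            channels=np.array([[300.0, 300.0, 800.0, 300.0, 60.0]]),
            domain_size=(1100.0, 600.0),
            resolution_nm=5.0,
        )
        track = simulate_walker(geom, 2e6, 30_000, 0.030, seed=4,
                                start_nm=[300.0, 300.0])
        pos = track.positions[::20]  # thin serially correlated samples
        in1 = ((pos - [300.0, 300.0]) ** 2).sum(1) <= 100.0**2
        in2 = ((pos - [800.0, 300.0]) ** 2).sum(1) <= 150.0**2
        counts = np.array([in1.sum(), in2.sum()])
        areas = np.array([100.0**2, 150.0**2])
        expected = counts.sum() * areas / areas.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=1)
        assert p > 1e-3


class TestRenderMovie:
    @staticmethod
    def _static_track(n, pos=(3200.0, 3200.0), length=500.0):
        return TruthTrack(
            positions=np.tile(pos, (n, 1)),
            dt_s=0.030,
            d_true=np.zeros(n),
            probe_length_nm=length,
            orientations=np.full(n, 0.4),
        )

    def test_noise_free_static_movie_constant(self):
        cam = CameraModel()
        movie, truth = render_movie(self._static_track(5), cam,
                                    np.zeros((5, 2)), noise=False)
        assert (movie == movie[0]).all()
        assert truth["visible"].all()

    def test_truth_table_reports_injected_drift(self):
        cam = CameraModel()
        drift = np.arange(10)[:, None] * np.array([0.05, 0.0])
        _movie, truth = render_movie(self._static_track(10), cam, drift,
                                     seed=0)
        assert np.array_equal(truth["drift_x_px"].to_numpy(), drift[:, 0])
        assert np.array_equal(truth["drift_y_px"].to_numpy(), drift[:, 1])

    def test_expected_intensity_conservation(self):
        # noise-free total = background*npx + amplitude * 2 pi smaj smin
        cam = CameraModel(pixel_size_nm=100.0, amplitude=200.0,
                          background=7.0)
        movie, _ = render_movie(self._static_track(1), cam,
                                np.zeros((1, 2)), noise=False,
                                psf_fwhm_nm=300.0)
        fwhm = 2 * np.sqrt(2 * np.log(2))
        smin = 300.0 / fwhm / 100.0
        smaj = np.sqrt(300.0**2 + 600.0**2) / fwhm / 100.0
        expected = 7.0 * 64 * 64 + 200.0 * 2 * np.pi * smaj * smin
        assert movie.sum() == pytest.approx(expected, rel=0.02)

    def test_emitter_outside_fov_flagged(self):
        track = self._static_track(3, pos=(-5000.0, -5000.0))
        cam = CameraModel()
        movie, truth = render_movie(track, cam, np.zeros((3, 2)),
                                    noise=False)
        assert not truth["visible"].any()
        assert np.allclose(movie, cam.background)

    def test_drift_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="drift length"):
            render_movie(self._static_track(5), CameraModel(),
                         np.zeros((4, 2)))

    def test_seed_determinism(self):
        cam = CameraModel()
        a, _ = render_movie(self._static_track(4), cam, np.zeros((4, 2)),
                            seed=5)
        b, _ = render_movie(self._static_track(4), cam, np.zeros((4, 2)),
                            seed=5)
        assert np.array_equal(a, b)


class TestEcsMask:
    def test_target_fraction_achieved(self):
        mask, truth = generate_ecs_mask(0.17, seed=1, shape=(128, 128))
        assert 0.165 <= mask.mean() <= 0.175
        assert truth.volume_fraction == mask.mean()

    def test_seed_determinism(self):
        a, _ = generate_ecs_mask(0.20, seed=3, shape=(96, 96))
        b, _ = generate_ecs_mask(0.20, seed=3, shape=(96, 96))
        assert np.array_equal(a, b)

    def test_unachievable_fraction_raises(self):
        with pytest.raises((GeometryError, ValueError)):
            generate_ecs_mask(1.5, seed=0)

    def test_voronoi_gap_width_matches_local_thickness(self):
        # uniform boundary gap: straight-boundary thickness ~ nominal width
        from ecsnano.em_morphometry import local_thickness

        mask, truth = generate_ecs_mask(
            0.10, {"mode": "voronoi", "n_sites": 2}, pixel_size_nm=1.0,
            seed=5, shape=(128, 128),
        )
        nominal = truth.width_field_nm[mask].max()
        _tmap, widths = local_thickness(mask, 1.0)
        # the gap is narrowest (= nominal) where the boundary is straight,
        # widening along the hyperbola branches and the border
        assert np.percentile(widths, 5) == pytest.approx(nominal, rel=0.15)

    def test_pools_mode_truth_recorded(self):
        mask, truth = generate_ecs_mask(
            0.15, {"mode": "pools", "n_pools": 3}, seed=2, shape=(128, 128)
        )
        assert 0.145 <= mask.mean() <= 0.155
        assert (truth.width_field_nm[mask] > 0).all()


class TestReferenceFractals:
    def test_known_rasters(self):
        line = generate_reference_fractal("line", 6)
        assert line.sum() == 64
        square = generate_reference_fractal("filled_square", 5)
        assert square.all()
        sierp = generate_reference_fractal("sierpinski", 6)
        assert sierp.sum() == 3**6  # self-similar count
        assert np.array_equal(sierp,
                              generate_reference_fractal("sierpinski", 6))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_reference_fractal("menger", 4)

    def test_sierpinski_needs_depth(self):
        with pytest.raises(ValueError):
            generate_reference_fractal("sierpinski", 2)
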