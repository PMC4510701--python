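import numpy as np
import pandas as pd
import pytest

from epigap.analysis import (
    area_decay,
    binned_mean_velocity,
    fit_velocity_curvature,
    isoperimetric_ratio,
    normal_displacement,
    pole_velocity,
    sample_edge_points,
    smoothed_normals,
)
from epigap.contours import Contour
from epigap.synthetic import ShapeSpec, make_gap_contour


def shrinking_circles(r0=50.0, speed=1.0, n=6, dt=1.0):
    out = []
    for i in range(n):
        out.append(
            (i * dt, make_gap_contour(ShapeSpec("circle", radius=r0 - speed * i * dt,
                                                resolution=0.5)))
        )
    return out


class TestSampling:
    def test_shrinking_circle_recovers_speed_and_curvature(self):
        contours = shrinking_circles()
        df, dropped = sample_edge_points(contours, n_points=8, arc_spacing=15.0, seed=0)
        assert dropped == 0
        assert np.abs(df.v_n_um_min - 1.0).max() < 0.01
        # kappa = -1/r(t) per frame
        for t, grp in df.groupby("t"):
            assert grp.kappa_per_um.mean() == pytest.approx(-1.0 / (50 - t), rel=1e-6)

    def test_static_contours_have_zero_velocity(self):
        c = make_gap_contour(ShapeSpec("circle", radius=30.0, resolution=0.5))
        contours = [(0.0, c), (1.0, c), (2.0, c)]
        df, _ = sample_edge_points(contours, n_points=6, arc_spacing=15.0, seed=1)
        assert np.abs(df.v_n_um_min).max() < 1e-9

    def test_sampler_is_deterministic_under_seed(self):
        contours = shrinking_circles()
        df1, _ = sample_edge_points(contours, seed=42)
        df2, _ = sample_edge_points(contours, seed=42)
        pd.testing.assert_frame_equal(df1, df2)

    def test_misses_are_dropped_and_counted(self):
        # second contour displaced far beyond the search window
        a = make_gap_contour(ShapeSpec("circle", radius=20.0, resolution=0.5))
        b = Contour(a.points + np.array([200.0, 0.0]))
        df, dropped = sample_edge_points([(0.0, a), (1.0, b)], n_points=6,
                                         arc_spacing=10.0, window=5.0, seed=0)
        assert dropped > 0

    def test_too_few_frames_rejected(self):
        c = make_gap_contour(ShapeSpec("circle", radius=20.0, resolution=0.5))
        with pytest.raises(ValueError):
            sample_edge_points([(0.0, c)])

    def test_normal_displacement_sign_convention(self):
        a = make_gap_contour(ShapeSpec("circle", radius=20.0, resolution=0.5))
        b = make_gap_contour(ShapeSpec("circle", radius=18.0, resolution=0.5))
        n = smoothed_normals(a, 5.0)
        d = normal_displacement(a.points[0], n[0], b, 10.0)
        assert d == pytest.approx(2.0, abs=0.01)  # edge advanced into the gap


class TestFits:
    def test_log_law_recovered_exactly(self):
        rng = np.random.default_rng(0)
        kappa = rng.uniform(-0.2, -0.01, 200)
        a, b, k0 = 1.0, 0.5, -0.3
        v = a - b * np.log(kappa - k0)
        df = pd.DataFrame({"kappa_per_um": kappa, "v_n_um_min": v})
        fit = fit_velocity_curvature(df, form="log")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients["a"] == pytest.approx(a, abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(b, abs=1e-6)
        assert fit.coefficients["kappa0"] == pytest.approx(k0, abs=1e-6)

    def test_linear_fit_and_window(self):
        kappa = np.linspace(-0.05, 0.05, 50)
        v = 0.8 - 12.0 * kappa
        df = pd.DataFrame({"kappa_per_um": kappa, "v_n_um_min": v})
        fit = fit_velocity_curvature(df, form="linear", window=(-0.02, 0.02))
        assert fit.coefficients["slope"] == pytest.approx(-12.0, rel=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(0.8, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"kappa_per_um": np.full(10, -0.02),
                           "v_n_um_min": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError, match="degenerate"):
            fit_velocity_curvature(df, form="linear")

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"kappa_per_um": [-0.1, -0.2], "v_n_um_min": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_velocity_curvature(df, form="linear")

    def test_binned_means_on_known_trend(self):
        kappa = np.linspace(-0.2, 0.02, 300)
        v = 1.0 - 10.0 * kappa
        df = pd.DataFrame({"kappa_per_um": kappa, "v_n_um_min": v})
        b = binned_mean_velocity(df, n_bins=5)
        assert len(b) == 5
        assert np.all(np.diff(b.v_n) < 0)


class TestLandmarksAndShape:
    def test_circle_pole_speeds(self):
        contours = shrinking_circles(speed=0.7)
        df = pole_velocity(contours, axis_x=0.0)
        assert np.abs(df.v_north.dropna() - 0.7).max() < 0.01
        assert np.abs(df.v_south.dropna() - 0.7).max() < 0.01

    def test_lost_axis_intersection_truncates(self):
        a = make_gap_contour(ShapeSpec("circle", radius=10.0, resolution=0.5))
        b = Contour(a.points + np.array([50.0, 0.0]))  # moved off the axis
        df = pole_velocity([(0.0, a), (1.0, b)], axis_x=0.0)
        assert len(df) == 1

    def test_area_decay_linear_series(self):
        t = np.linspace(0, 10, 20)
        A = 1000 - 30 * t
        series = area_decay(list(zip(t, A)))
        assert series.slope == pytest.approx(-30.0)
        assert series.r_squared == pytest.approx(1.0)

    def test_area_decay_needs_three_points(self):
        with pytest.raises(ValueError):
            area_decay([(0.0, 1.0), (1.0, 0.5)])

    def test_isoperimetric_ratio_circle_and_square(self):
        circ = make_gap_contour(ShapeSpec("circle", radius=30.0, resolution=0.2))
        assert isoperimetric_ratio(circ) == pytest.approx(1.0, abs=5e-3)
        sq = make_gap_contour(
            ShapeSpec("polygon", vertices=[(0, 0), (10, 0), (10, 10), (0, 10)], resolution=0.1)
        )
        assert isoperimetric_ratio(sq) == pytest.approx(np.pi / 4, abs=5e-3)
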