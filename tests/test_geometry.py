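import numpy as np
import pytest

from epigap.contours import Contour, contours_distance
from epigap.geometry import (
    CFLError,
    Grid,
    LevelSetField,
    advect,
    curvature_levelset,
    extract_contours,
    gap_area,
    normals,
    polygon_gap_area,
    reinitialize,
    signed_distance,
    three_point_curvature,
)
from epigap.synthetic import ShapeSpec, make_gap_contour, moon_area


def circle_field(R=20.0, h=0.5, margin=10.0, resolution=None):
    c = make_gap_contour(ShapeSpec("circle", radius=R, resolution=resolution or h / 8))
    grid = Grid.around(c, h, margin)
    return signed_distance(c, grid), c


class TestSignedDistance:
    def test_circle_values(self):
        field, _ = circle_field(R=20.0, h=0.5)
        phi = field.sample(np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 20.0]]))
        assert phi[0] == pytest.approx(20.0, abs=0.02)
        assert phi[1] == pytest.approx(-10.0, abs=0.02)
        assert abs(phi[2]) < 0.02

    def test_square_interior_distance_is_to_nearest_edge(self):
        sq = make_gap_contour(
            ShapeSpec("polygon", vertices=[(0, 0), (20, 0), (20, 20), (0, 20)], resolution=0.5)
        )
        grid = Grid((-5.0, -5.0), 0.5, (61, 61))
        field = signed_distance(sq, grid)
        # on the diagonal, 4 um from the corner: nearest edge is 4 um away,
        # the corner itself is 4*sqrt(2)
        val = field.sample(np.array([[4.0, 4.0]]))[0]
        assert val == pytest.approx(4.0, abs=0.02)

    def test_contour_touching_border_rejected(self):
        c = make_gap_contour(ShapeSpec("circle", radius=10.0, resolution=0.5))
        grid = Grid((-10.2, -10.2), 0.5, (42, 42))
        with pytest.raises(ValueError):
            signed_distance(c, grid)

    def test_roundtrip_through_extraction(self):
        field, _ = circle_field(R=20.0, h=0.5)
        loops = extract_contours(field)
        field2 = signed_distance(loops[0].upsampled_smooth(0.5 / 8), field.grid)
        band = np.abs(field.values) <= 5 * 0.5
        assert np.abs(field.values - field2.values)[band].max() <= 0.5


class TestExtraction:
    def test_circle_vertices_at_radius(self):
        field, _ = circle_field(R=20.0, h=0.5)
        loops = extract_contours(field)
        assert len(loops) == 1
        r = np.linalg.norm(loops[0].points, axis=1)
        assert np.abs(r - 20.0).max() <= 0.25  # h/2

    def test_closed_gap_returns_empty(self):
        grid = Grid((0.0, 0.0), 1.0, (16, 16))
        field = LevelSetField(grid, -np.ones((16, 16)))
        assert extract_contours(field) == []

    def test_pinched_dumbbell_yields_two_loops_with_additive_area(self):
        # union of two disjoint discs: phi = max of the two signed distances
        grid = Grid((-40.0, -20.0), 0.5, (81, 161))
        X, Y = grid.meshgrid()
        phi1 = 8.0 - np.hypot(X + 15, Y)
        phi2 = 8.0 - np.hypot(X - 15, Y)
        field = LevelSetField(grid, np.maximum(phi1, phi2))
        loops = extract_contours(field)
        assert len(loops) == 2
        assert loops[0].area >= loops[1].area
        total = sum(lp.area for lp in loops)
        assert total == pytest.approx(gap_area(field), rel=0.01)


class TestCurvature:
    def test_levelset_circle_sign_and_magnitude(self):
        R, h = 50.0, 1.0
        field, c = circle_field(R=R, h=h)
        kappa = curvature_levelset(field).sample(c.points)
        assert np.all(kappa < 0)
        assert np.abs(kappa + 1.0 / R).max() * R < 0.02

    def test_levelset_flat_edge_zero(self):
        grid = Grid((0.0, 0.0), 0.5, (41, 41))
        X, Y = grid.meshgrid()
        field = LevelSetField(grid, Y - 10.0)  # gap above a straight edge
        cf = curvature_levelset(field)
        assert np.nanmax(np.abs(cf.values[cf.valid])) < 1e-6

    def test_levelset_convergence_on_fine_circle(self):
        R, h = 10.0, 0.25
        field, c = circle_field(R=R, h=h, resolution=h / 8)
        kappa = curvature_levelset(field).sample(c.points)
        assert np.abs(kappa + 1.0 / R).max() * R < 0.02

    def test_capping_at_mesh_scale(self):
        sq = make_gap_contour(
            ShapeSpec("polygon", vertices=[(0, 0), (20, 0), (20, 20), (0, 20)], resolution=0.25)
        )
        grid = Grid((-6.0, -6.0), 0.5, (65, 65))
        field = signed_distance(sq, grid)
        cf = curvature_levelset(field)
        assert np.nanmax(np.abs(cf.values[cf.valid])) <= 1.0 / (2 * 0.5) + 1e-12

    def test_three_point_circle_exact(self):
        c = make_gap_contour(ShapeSpec("circle", radius=50.0, resolution=0.5))
        kappa = three_point_curvature(c, 0, arc_spacing=15.0)
        assert kappa == pytest.approx(-0.02, abs=1e-12)

    def test_three_point_collinear_zero(self):
        pts = np.array([[x, 0.0] for x in np.linspace(0, 40, 41)] +
                       [[40 - x, 20.0] for x in np.linspace(0, 40, 41)])
        c = Contour(np.vstack([pts, [[0.0, 10.0]]]))
        i = 20  # mid of the straight lower edge
        assert abs(three_point_curvature(c, i, arc_spacing=5.0)) < 1e-12

    def test_three_point_spacing_exceeding_contour_rejected(self):
        c = make_gap_contour(ShapeSpec("circle", radius=4.0, resolution=0.5))
        with pytest.raises(ValueError):
            three_point_curvature(c, 0, arc_spacing=15.0)

    def test_normals_unit_and_gapward(self):
        field, c = circle_field(R=20.0, h=0.5)
        nf = normals(field)
        mag = np.hypot(nf.nx, nf.ny)[nf.valid]
        assert np.abs(mag - 1.0).max() < 1e-6
        # at the centre of the gap the normal field points away from tissue;
        # just inside the interface it should point radially inward (to gap)
        iy = np.searchsorted(field.grid.y, 0.0)
        ix = np.searchsorted(field.grid.x, -21.0)  # tissue side, left of gap
        assert nf.nx[iy, ix] > 0.9  # toward the gap centre


class TestTransport:
    def test_zero_velocity_is_bitwise_identity(self):
        field, _ = circle_field(R=10.0, h=0.5, margin=8.0)
        v = np.zeros(field.grid.shape)
        out = advect(field, v, v, dt=1.0)
        assert out.values.tobytes() == field.values.tobytes()

    def test_uniform_translation(self):
        field, _ = circle_field(R=20.0, h=2.0, margin=16.0)
        vx = np.ones(field.grid.shape)
        vy = np.zeros(field.grid.shape)
        out = advect(field, vx, vy, dt=1.0)
        shifted = extract_contours(out)[0]
        ref = Contour(extract_contours(field)[0].points + np.array([1.0, 0.0]))
        assert contours_distance(shifted, ref) <= 0.1 * 2.0

    def test_uniform_normal_shrinkage(self):
        field, _ = circle_field(R=20.0, h=0.5)
        nf = normals(field)
        s = 0.4  # um/min inward edge speed
        out = advect(field, s * nf.nx, s * nf.ny, dt=0.5)
        r = np.linalg.norm(extract_contours(out)[0].points, axis=1)
        assert r.mean() == pytest.approx(20.0 - s * 0.5, rel=0.01)

    def test_cfl_violation_reports_admissible_step(self):
        field, _ = circle_field(R=10.0, h=0.5, margin=8.0)
        v = np.ones(field.grid.shape)
        with pytest.raises(CFLError) as exc:
            advect(field, v, v, dt=1.0)
        assert exc.value.dt_admissible == pytest.approx(0.25)


class TestReinitialize:
    def test_fixed_point_on_signed_distance(self):
        field, _ = circle_field(R=10.0, h=0.25, resolution=0.25 / 8)
        before = extract_contours(field)[0]
        after = extract_contours(reinitialize(field))[0]
        assert contours_distance(after, before) <= 1e-3 * 0.25

    def test_restores_unit_gradient_after_scaling(self):
        field, _ = circle_field(R=20.0, h=0.5)
        scaled = LevelSetField(field.grid, 3.0 * field.values)
        out = reinitialize(scaled)
        gy, gx = np.gradient(out.values, 0.5)
        band = np.abs(out.values) <= 5 * 0.5
        mag = np.hypot(gx, gy)[band]
        assert mag.min() > 0.95 and mag.max() < 1.05
        assert contours_distance(
            extract_contours(out)[0], extract_contours(scaled)[0]
        ) < 0.1 * 0.5


class TestArea:
    def test_circle_area(self):
        field, _ = circle_field(R=50.0, h=1.0)
        assert gap_area(field) == pytest.approx(np.pi * 2500, rel=0.01)

    def test_all_negative_is_zero(self):
        grid = Grid((0.0, 0.0), 1.0, (8, 8))
        assert gap_area(LevelSetField(grid, -np.ones((8, 8)))) == 0.0

    def test_moon_area_closed_form(self):
        c = make_gap_contour(ShapeSpec("moon", radius=50.0, h=25.0, resolution=0.5))
        grid = Grid.around(c, 1.0, 10.0)
        field = signed_distance(c, grid)
        assert gap_area(field) == pytest.approx(moon_area(50.0, 25.0), rel=0.01)

    def test_grid_and_polygon_areas_agree(self):
        field, _ = circle_field(R=20.0, h=0.5)
        assert gap_area(field) == pytest.approx(polygon_gap_area(field), rel=0.01)


def test_resolution_convergence_of_geometry_errors():
    """Halving the grid spacing should at least halve the circle-family
    errors (area and extracted-radius deviations)."""
    errs = []
    for h in (1.0, 0.5):
        field, _ = circle_field(R=20.0, h=h)
        r = np.linalg.norm(extract_contours(field)[0].points, axis=1)
        errs.append(
            abs(gap_area(field) - np.pi * 400) / (np.pi * 400)
            + np.abs(r - 20.0).max() / 20.0
        )
    assert errs[1] <= errs[0] / 2.0
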