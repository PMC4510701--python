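import numpy as np
import pytest
from scipy import special

from epigap.geometry import Grid, signed_distance
from epigap.mechanics import (
    ModelParams,
    SingularSystemError,
    TissueDomain,
    analytic_circular_closure,
    analytic_radial_velocity,
    boundary_traction,
    radial_ode_residual,
    solve_flat_edge,
    solve_velocity,
)
from epigap.synthetic import ShapeSpec, make_gap_contour

BENCH = ModelParams(eta=1.0, c_f=0.04, f_l=1.0, gamma=5.0)


def annulus_solution(a, params, R_out, h):
    c = make_gap_contour(ShapeSpec("circle", radius=a, resolution=h / 2))
    n = int(np.ceil(2 * (R_out + 5 * h) / h)) + 1
    grid = Grid((-R_out - 5 * h, -R_out - 5 * h), h, (n, n))
    field = signed_distance(c.upsampled_smooth(h / 8), grid)
    return solve_velocity(
        TissueDomain(field=field, outer={"circle": (0.0, 0.0, R_out)}), params
    )


class TestBoundaryTraction:
    def test_flat_edge_is_pure_crawling(self):
        p = ModelParams(f_l=1.2, gamma=7.0, c_f=0.1)
        assert boundary_traction(0.0, p) == pytest.approx(1.2)

    def test_circular_gap_mechanisms_add_up(self):
        p = ModelParams(f_l=1.0, gamma=5.0, c_f=0.1)
        assert boundary_traction(-1.0 / 20.0, p) == pytest.approx(1.0 + 5.0 / 20.0)

    def test_purse_string_overcomes_crawling_at_high_positive_curvature(self):
        p = ModelParams(f_l=1.0, gamma=5.0, c_f=0.1)
        assert boundary_traction(0.5, p) < 0


class TestModelParams:
    def test_screening_length(self):
        p = ModelParams(eta=2.0, c_f=0.04)
        assert p.screening_length == pytest.approx(np.sqrt(2 * 2.0 / 0.04))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(eta=0.0)
        with pytest.raises(ValueError):
            ModelParams(f_l=-1.0)

    def test_zero_friction_names_the_null_space(self):
        c = make_gap_contour(ShapeSpec("circle", radius=10.0, resolution=0.5))
        grid = Grid.around(c, 1.0, 10.0)
        field = signed_distance(c, grid)
        with pytest.raises(SingularSystemError, match="null space"):
            solve_velocity(TissueDomain(field=field), ModelParams(c_f=1e-9).with_(c_f=0.0))


class TestRadialOracle:
    def test_zero_forces_zero_velocity(self):
        p = ModelParams(eta=1.0, c_f=0.04, f_l=0.0, gamma=0.0)
        r = np.linspace(20, 60, 10)
        assert np.abs(analytic_radial_velocity(r, 20.0, 80.0, p)).max() == 0.0

    def test_infinite_domain_is_pure_k1_and_closing(self):
        v_a = analytic_radial_velocity(20.0, 20.0, np.inf, BENCH)
        assert v_a < 0  # edge moves inward
        ell = BENCH.screening_length
        r = np.array([30.0, 40.0])
        v = analytic_radial_velocity(r, 20.0, np.inf, BENCH)
        ratio = v[0] / v[1]
        assert ratio == pytest.approx(
            special.kv(1, r[0] / ell) / special.kv(1, r[1] / ell), rel=1e-10
        )

    def test_linearity_in_forces(self):
        v1 = analytic_radial_velocity(25.0, 20.0, 80.0, BENCH)
        doubled = BENCH.with_(f_l=2 * BENCH.f_l, gamma=2 * BENCH.gamma)
        assert analytic_radial_velocity(25.0, 20.0, 80.0, doubled) == pytest.approx(2 * v1)

    def test_parameter_scale_invariance(self):
        lam = 3.7
        scaled = ModelParams(
            eta=lam * BENCH.eta, c_f=lam * BENCH.c_f,
            f_l=lam * BENCH.f_l, gamma=lam * BENCH.gamma,
        )
        r = np.linspace(21, 70, 7)
        assert np.allclose(
            analytic_radial_velocity(r, 20.0, 80.0, scaled),
            analytic_radial_velocity(r, 20.0, 80.0, BENCH),
        )

    def test_bessel_solution_satisfies_the_ode(self):
        R_out = 20.0 + 8 * BENCH.screening_length
        assert radial_ode_residual(20.0, R_out, BENCH) <= 1e-6

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            analytic_radial_velocity(25.0, 30.0, 20.0, BENCH)

    def test_screening_makes_outer_boundary_immaterial(self):
        ell = BENCH.screening_length
        v8 = analytic_radial_velocity(20.0, 20.0, 20 + 8 * ell, BENCH)
        v12 = analytic_radial_velocity(20.0, 20.0, 20 + 12 * ell, BENCH)
        assert abs(v12 - v8) / abs(v8) < 0.01


class TestClosureOracle:
    def test_purse_string_accelerates_near_closure(self):
        p = ModelParams(eta=1.0, c_f=0.08, f_l=0.0, gamma=10.0)
        a = np.array([8.0, 4.0, 2.0, 1.0])
        v = np.array([analytic_radial_velocity(x, x, 80.0, p) for x in a])
        assert np.all(np.diff(np.abs(v)) > 0)  # faster as the gap shrinks

    def test_crawling_speed_near_constant_for_large_gaps(self):
        p = ModelParams(eta=1.0, c_f=0.08, f_l=1.0, gamma=0.0)
        ell = p.screening_length
        v1 = analytic_radial_velocity(10 * ell, 10 * ell, 200.0, p)
        v2 = analytic_radial_velocity(5 * ell, 5 * ell, 200.0, p)
        assert abs(v1 - v2) / abs(v1) < 0.1

    def test_tiny_gap_closes_immediately(self):
        p = ModelParams(eta=1.0, c_f=0.08, f_l=0.0, gamma=10.0)
        curve = analytic_circular_closure(0.05, p, 50.0)
        assert curve.closing and curve.closure_time < 0.05

    def test_zero_forces_reported_non_closing(self):
        p = ModelParams(eta=1.0, c_f=0.08, f_l=0.0, gamma=0.0)
        curve = analytic_circular_closure(10.0, p, 50.0)
        assert not curve.closing
        assert curve.closure_time == np.inf


class TestVelocitySolve:
    def test_flat_edge_purse_string_only_is_exactly_null(self):
        p = ModelParams(eta=1.0, c_f=0.08, f_l=0.0, gamma=5.0)
        _, v, vn = solve_flat_edge(60.0, 40.0, p, h=1.0)
        assert np.abs(vn).max() == 0.0

    def test_flat_edge_crawling_profile_matches_1d_screening(self):
        p = ModelParams(eta=1.0, c_f=0.08, f_l=1.0, gamma=0.0)
        pts, v, vn = solve_flat_edge(60.0, 50.0, p, h=0.5)
        mid = vn[len(vn) // 4 : -len(vn) // 4]
        assert np.ptp(mid) / np.abs(mid).mean() < 0.01
        # 1D solution: v_y(0) = f_L * l / (2 eta)
        v_exact = p.f_l * p.screening_length / (2 * p.eta)
        assert mid.mean() == pytest.approx(v_exact, rel=0.02)

    def test_annulus_edge_speed_matches_bessel(self):
        R_out = 20.0 + 8 * BENCH.screening_length
        sol = annulus_solution(20.0, BENCH, R_out, h=1.0)
        v_exact = -analytic_radial_velocity(20.0, 20.0, R_out, BENCH)
        assert sol.normal_speed.mean() == pytest.approx(v_exact, rel=0.02)
        assert sol.residual <= 1e-8

    def test_velocity_decays_like_screened_flow(self):
        R_out = 20.0 + 10 * BENCH.screening_length
        sol = annulus_solution(20.0, BENCH, R_out, h=1.0)
        ell = BENCH.screening_length
        pts = np.array([[20.0 + ell, 0.0], [20.0 + 3 * ell, 0.0]])
        v = sol.sample(pts)
        measured = np.hypot(*v[0]) / np.hypot(*v[1])
        expected = special.kv(1, (20 + ell) / ell) / special.kv(1, (20 + 3 * ell) / ell)
        assert measured == pytest.approx(expected, rel=0.2)

    def test_superposition_of_load_cases(self):
        from epigap._fem import FactorizedOperator

        lobed = make_gap_contour(
            ShapeSpec("lobed", radius=15.0, lobe_amplitude=5.0, lobe_count=3, resolution=0.5)
        )
        p = ModelParams(eta=1.0, c_f=0.08, f_l=1.0, gamma=5.0)
        grid = Grid.around(lobed, 1.0, 8 * p.screening_length)
        field = signed_distance(lobed.upsampled_smooth(1 / 8), grid)
        dom = TissueDomain(field=field)
        full = solve_velocity(dom, p)
        op = FactorizedOperator(full.mesh, p.eta, p.c_f)
        crawl = solve_velocity(dom, p.with_(gamma=0.0), operator=op)
        ps = solve_velocity(dom, p.with_(f_l=0.0), operator=op)
        resid = np.abs(full.v - crawl.v - ps.v).max() / np.abs(full.v).max()
        assert resid <= 1e-8

    def test_force_scaling_scales_velocity(self):
        R_out = 20.0 + 8 * BENCH.screening_length
        sol1 = annulus_solution(20.0, BENCH, R_out, h=1.0)
        sol2 = annulus_solution(
            20.0, BENCH.with_(f_l=2 * BENCH.f_l, gamma=2 * BENCH.gamma), R_out, h=1.0
        )
        assert np.allclose(sol2.v, 2 * sol1.v, atol=1e-10 * np.abs(sol1.v).max())
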