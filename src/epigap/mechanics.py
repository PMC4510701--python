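"""Quasi-static momentum balance of the gap-closing tissue.

Model: the monolayer is a compressible 2D viscous sheet, sigma = 2 eta D(v),
balanced against substrate friction, -div(sigma) + C_f v = 0 in the tissue.
The free edge carries a traction t = (f_L - gamma*kappa) n, with n the unit
normal pointing into the gap: f_L is the lamellipodial (crawling) force per
unit edge length, always pulling into the gap, and gamma the purse-string
cable tension acting through the signed edge curvature kappa (negative
around a circular gap, so both mechanisms add up there; at strongly
positive curvature the cable overcomes crawling and the edge retracts).

Substrate friction screens the flow over the hydrodynamic length
l = sqrt(2 eta / C_f); the outer tissue boundary is traction-free and is
immaterial once it sits several l from the gap.

Units: um, min, nN throughout (eta: nN min / um, C_f: nN min / um^3,
f_L: nN / um, gamma: nN).  Nondimensional parameter sets are equally valid;
only ratios and l enter the solution shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import special
from scipy.integrate import solve_ivp
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from ._fem import FactorizedOperator, Mesh, SingularSystemError, build_mesh
from .contours import Contour
from .geometry import Grid, LevelSetField, curvature_levelset, signed_distance

__all__ = [
    "ModelParams",
    "TissueDomain",
    "VelocitySolution",
    "boundary_traction",
    "solve_velocity",
    "solve_flat_edge",
    "analytic_radial_velocity",
    "analytic_circular_closure",
    "radial_ode_residual",
    "SingularSystemError",
]


@dataclass(frozen=True)
class ModelParams:
    """Tissue material and edge-force parameters."""

    eta: float = 1.0
    c_f: float = 0.08
    f_l: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.c_f < 0 or self.f_l < 0 or self.gamma < 0:
            raise ValueError("C_f, f_L and gamma must be non-negative")

    @property
    def screening_length(self) -> float:
        """Hydrodynamic screening length l = sqrt(2 eta / C_f) (um)."""
        if self.c_f == 0:
            return np.inf
        return float(np.sqrt(2 * self.eta / self.c_f))

    def with_(self, **kw) -> "ModelParams":
        d = dict(eta=self.eta, c_f=self.c_f, f_l=self.f_l, gamma=self.gamma)
        d.update(kw)
        return ModelParams(**d)


def boundary_traction(kappa, params: ModelParams):
    """Scalar edge traction T = f_L - gamma*kappa (nN/um).

    The traction vector applied to the tissue edge is T n with n gap-ward:
    on a flat edge (kappa = 0) only crawling acts; around a circular gap of
    radius a (kappa = -1/a) the purse-string adds gamma/a; where
    gamma*kappa > f_L the net traction is negative and the edge is pulled
    back into the tissue.
    """
    return params.f_l - params.gamma * np.asarray(kappa)


@dataclass
class TissueDomain:
    """Tissue = enclosure minus gap.

    The interface may be given as a level-set field (loops are extracted)
    or as closed contour loop(s).  ``outer`` is either ``None`` (the grid
    rectangle) or ``{"circle": (cx, cy, R)}``.
    """

    field: LevelSetField | None = None
    loops: list[Contour] | None = None
    outer: dict | None = None
    grid_spacing: float | None = None

    def resolve(self) -> tuple[list[Contour], LevelSetField]:
        from .geometry import extract_contours

        if self.field is not None:
            loops = self.loops or extract_contours(self.field)
            return loops, self.field
        if not self.loops:
            raise ValueError("domain needs a level-set field or contour loops")
        h = self.grid_spacing or max(self.loops[0].perimeter / 200, 1e-3)
        if self.outer and "circle" in self.outer:
            cx, cy, R = self.outer["circle"]
            lo = (cx - R - 5 * h, cy - R - 5 * h)
            n = int(np.ceil(2 * (R + 5 * h) / h)) + 1
            grid = Grid(lo, h, (n, n))
        else:
            grid = Grid.around(self.loops[0], h, margin=10 * h)
        return self.loops, signed_distance(self.loops, grid)


@dataclass
class VelocitySolution:
    """Nodal FEM velocity with interface samples and grid extension."""

    mesh: Mesh
    v: np.ndarray  # (N, 2) um/min
    residual: float
    params: ModelParams
    kappa: np.ndarray  # at interface nodes
    traction: np.ndarray  # scalar T at interface nodes

    @property
    def interface_points(self) -> np.ndarray:
        return self.mesh.points[: self.mesh.n_interface]

    @property
    def interface_velocity(self) -> np.ndarray:
        return self.v[: self.mesh.n_interface]

    @property
    def normal_speed(self) -> np.ndarray:
        """Edge speed v.n at interface nodes, positive toward the gap."""
        n = self.mesh.interface_normals
        return np.einsum("ij,ij->i", self.interface_velocity, n)

    def boundary_flux(self) -> float:
        """Closure flux: integral of v.n ds over the interface (um^2/min).

        Integrated per polygon segment with the segment's own gap-ward
        normal (exact for piecewise-linear velocity); vertex normals are
        angle bisectors and would misstate the flux at corners.
        """
        flux = 0.0
        v = self.interface_velocity
        p = self.interface_points
        for sl in self.mesh.loop_slices:
            idx = np.arange(sl.start, sl.stop)
            nxt = np.roll(idx, -1)
            seg = p[nxt] - p[idx]
            # CCW with the gap on the left: left normal (-dy, dx) is gap-ward
            n_ds = np.stack([-seg[:, 1], seg[:, 0]], axis=1)
            v_mid = 0.5 * (v[idx] + v[nxt])
            flux += float(np.einsum("ij,ij->", v_mid, n_ds))
        return flux

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Linear interpolation of the velocity at arbitrary tissue points."""
        interp = LinearNDInterpolator(self.mesh.points, self.v, fill_value=np.nan)
        return interp(points)

    def extend_to_grid(self, field: LevelSetField, band: float | None = None):
        """Velocity on the regular grid for level-set transport.

        Tissue-side grid points in the band (default 5 cells around the
        interface) carry the solved tissue velocity itself — important
        where the flow varies along the edge, e.g. the slow region behind
        a corner, which a closest-point extension would overwrite with
        face values.  Gap-side points (where no material exists) take the
        velocity of the nearest interface node, i.e. a constant extension
        across the interface.  Far from the interface the field is zero;
        it is rebuilt by redistancing after each step anyway.
        """
        h = field.spacing
        b = 5 * h if band is None else band
        vx = np.zeros(field.grid.shape)
        vy = np.zeros(field.grid.shape)
        mask = np.abs(field.values) <= b
        pts = field.grid.points()[mask.ravel()]
        vloc = np.empty((len(pts), 2))
        # exact grid-point mesh nodes keep their FEM value
        node_tree = cKDTree(self.mesh.points)
        d_node, i_node = node_tree.query(pts, k=1)
        on_mesh = d_node <= 1e-9
        vloc[on_mesh] = self.v[i_node[on_mesh]]
        # everything else (gap side and the thin exclusion strip along the
        # contour): constant extension from the nearest interface node
        rest = ~on_mesh
        if rest.any():
            ifc_tree = cKDTree(self.interface_points)
            _, i_ifc = ifc_tree.query(pts[rest], k=1)
            vloc[rest] = self.interface_velocity[i_ifc]
        vx[mask] = vloc[:, 0]
        vy[mask] = vloc[:, 1]
        return vx, vy


def solve_velocity(
    domain: TissueDomain,
    params: ModelParams,
    kappa: np.ndarray | None = None,
    mesh_opts: dict | None = None,
    operator: FactorizedOperator | None = None,
) -> VelocitySolution:
    """Solve the momentum balance for the instantaneous tissue velocity.

    ``kappa`` may supply the signed interface curvature at the resampled
    interface nodes; by default it is interpolated from the level-set
    curvature field (capped, validity-banded).  Passing a prebuilt
    ``operator`` reuses mesh and factorization across load cases
    (mechanism decomposition at fixed geometry).
    """
    loops, field = domain.resolve()
    if operator is None:
        opts = dict(mesh_opts or {})
        ell = params.screening_length
        h = field.spacing
        if np.isfinite(ell):
            opts.setdefault("band_fine", max(1.5 * ell, 6 * h))
            opts.setdefault("band_mid", max(4.0 * ell, 16 * h))
        # default is a body-fitted tissue mesh (most accurate against the
        # axisymmetric oracle); keep_gap=True switches to the fixed-domain
        # (one-fluid) formulation with a soft fictitious gap material
        opts.setdefault("keep_gap", False)
        mesh = build_mesh(loops, field.grid, field.values, outer=domain.outer, **opts)
        operator = FactorizedOperator(mesh, params.eta, params.c_f)
    mesh = operator.mesh
    if kappa is None:
        cf = curvature_levelset(field)
        kappa = cf.sample(mesh.points[: mesh.n_interface])
    kappa = np.asarray(kappa, dtype=float)
    T = boundary_traction(kappa, params)
    from ._fem import traction_load

    f = traction_load(mesh, T)
    v, res = operator.solve(f)
    return VelocitySolution(mesh, v, res, params, kappa, T)


def solve_flat_edge(
    width: float,
    depth: float,
    params: ModelParams,
    h: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Momentum balance for a straight tissue edge (tissue strip).

    The tissue occupies ``[0, width] x [-depth, 0]`` with its free edge
    along y = 0 (gap above, normal +y, kappa = 0); the other three sides
    are traction-free.  Returns ``(points, v, edge_normal_speed)`` where
    the last entry holds v_y at the edge nodes.  The exact solution is the
    1D profile v = (0, V exp(y / l)); purse-string alone exerts no force
    on a flat edge, so the load vector (and hence v) is exactly zero.
    """
    nx = int(round(width / h)) + 1
    ny = int(round(depth / h)) + 1
    xs = np.linspace(0, width, nx)
    ys = np.linspace(-depth, 0, ny)
    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i, j):
        return j * nx + i

    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            tris.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1)])
            tris.append([nid(i, j), nid(i + 1, j + 1), nid(i, j + 1)])
    tris = np.asarray(tris)
    edge_nodes = np.array([nid(i, ny - 1) for i in range(nx)])
    edges = np.stack([edge_nodes[:-1], edge_nodes[1:]], axis=1)
    normals = np.zeros((len(pts), 2))
    normals[edge_nodes] = (0.0, 1.0)
    mesh = Mesh(pts, tris, len(pts), edges, normals, [slice(0, len(pts))])
    op = FactorizedOperator(mesh, params.eta, params.c_f)
    T = np.zeros(len(pts))
    T[edge_nodes] = boundary_traction(0.0, params)
    from ._fem import traction_load

    f = traction_load(mesh, T)
    v, _ = op.solve(f)
    return pts, v, v[edge_nodes, 1]


# ---------------------------------------------------------------------------
# axisymmetric closed-form oracle


def _radial_coeffs(a: float, R_out: float, params: ModelParams):
    """Coefficients (A, B) of v_r = A I1(r/l) + B K1(r/l).

    Traction conditions: 2 eta v'(a) = f_L + gamma/a at the gap edge
    (sigma_rr there equals the applied traction magnitude) and
    sigma_rr(R_out) = 0 (traction-free rim); R_out may be infinite.
    """
    ell = params.screening_length
    T_a = params.f_l + params.gamma / a

    def dI1(z):
        return special.iv(0, z) - special.iv(1, z) / z

    def dK1(z):
        return -special.kv(0, z) - special.kv(1, z) / z

    za = a / ell
    rhs_a = T_a / (2 * params.eta) * ell
    if np.isinf(R_out):
        A = 0.0
        B = rhs_a / dK1(za)
        return A, B, ell
    zR = R_out / ell
    M = np.array([[dI1(za), dK1(za)], [dI1(zR), dK1(zR)]])
    rhs = np.array([rhs_a, 0.0])
    A, B = np.linalg.solve(M, rhs)
    return float(A), float(B), ell


def analytic_radial_velocity(
    r: np.ndarray | float, a: float, R_out: float, params: ModelParams
) -> np.ndarray | float:
    """Radial tissue velocity for an annular tissue around a circular gap.

    Solves 2 eta (v'' + v'/r - v/r^2) = C_f v with the edge traction
    condition at r = a and a traction-free rim at ``R_out`` (``inf``
    allowed).  Negative values mean the edge moves inward (gap closes).
    """
    if a >= R_out:
        raise ValueError("gap radius must be smaller than the outer radius")
    A, B, ell = _radial_coeffs(a, R_out, params)
    z = np.asarray(r, dtype=float) / ell
    v = A * special.iv(1, z) + B * special.kv(1, z)
    return v if np.ndim(r) else float(v)


def radial_ode_residual(
    a: float, R_out: float, params: ModelParams, n: int = 40000
) -> float:
    """Relative finite-difference residual of the radial ODE.

    Independent verification that the Bessel solution satisfies
    2 eta (v'' + v'/r - v/r^2) - C_f v = 0; returns the max residual
    relative to the max of C_f |v|.
    """
    Rmax = R_out if np.isfinite(R_out) else a + 12 * params.screening_length
    r = np.linspace(a, Rmax, n)
    v = analytic_radial_velocity(r, a, R_out, params)
    dr = r[1] - r[0]
    vp = np.gradient(v, dr, edge_order=2)
    vpp = np.gradient(vp, dr, edge_order=2)
    res = 2 * params.eta * (vpp + vp / r - v / r**2) - params.c_f * v
    scale = params.c_f * np.abs(v).max()
    return float(np.abs(res[2:-2]).max() / scale)


@dataclass
class ClosureCurve:
    """Gap radius and area versus time for a circular gap."""

    t: np.ndarray
    a: np.ndarray
    closing: bool

    @property
    def area(self) -> np.ndarray:
        return np.pi * self.a**2

    @property
    def closure_time(self) -> float:
        return float(self.t[-1]) if self.closing else np.inf

    def time_to_area(self, area_min: float) -> float:
        """Time at which the gap area first drops to ``area_min``."""
        a_min = np.sqrt(area_min / np.pi)
        if self.a[-1] > a_min:
            raise ValueError("curve does not reach the requested area")
        return float(np.interp(-a_min, -self.a, self.t))


def analytic_circular_closure(
    a0: float,
    params: ModelParams,
    R_out: float,
    a_stop: float | None = None,
    rtol: float = 1e-8,
) -> ClosureCurve:
    """Quasi-static closure of a circular gap: integrate da/dt = v_r(a).

    The outer tissue radius stays fixed (the far boundary is screened).
    Crawling-dominated closure proceeds at near-constant edge speed while
    a >> l; purse-string traction gamma/a grows as the gap shrinks, so
    |da/dt| accelerates near closure.  Non-closing parameter sets
    (f_L = gamma = 0) are reported as such rather than integrated forever.
    """
    if a0 >= R_out:
        raise ValueError("a0 must be below R_out")
    a_stop = a_stop if a_stop is not None else max(1e-3 * a0, 1e-6)
    v0 = analytic_radial_velocity(a0, a0, R_out, params)
    if v0 >= -1e-14:
        return ClosureCurve(np.array([0.0]), np.array([a0]), closing=False)

    def rhs(t, y):
        a = max(y[0], a_stop * 0.5)
        return [analytic_radial_velocity(a, a, R_out, params)]

    def hit(t, y):
        return y[0] - a_stop

    hit.terminal = True
    hit.direction = -1
    t_end = 10 * a0 / abs(v0)
    ts, As = [np.array([0.0])], [np.array([a0])]
    t0, y0 = 0.0, [a0]
    for _ in range(20):
        sol = solve_ivp(
            rhs, (t0, t0 + t_end), y0, events=hit, rtol=rtol, atol=1e-10,
            dense_output=False, max_step=t_end / 50,
        )
        ts.append(sol.t[1:])
        As.append(sol.y[0][1:])
        if sol.status == 1:  # event hit
            break
        t0, y0 = sol.t[-1], [sol.y[0][-1]]
    t = np.concatenate(ts)
    a = np.concatenate(As)
    # remaining time below a_stop at the last computed speed
    v_last = analytic_radial_velocity(max(a[-1], a_stop), max(a[-1], a_stop), R_out, params)
    t_extra = a[-1] / abs(v_last)
    t = np.append(t, t[-1] + t_extra)
    a = np.append(a, 0.0)
    return ClosureCurve(t, a, closing=True)
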