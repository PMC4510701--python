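"""Linear (P1) finite elements on a graded Delaunay mesh of the tissue.

The mesh is body-fitted: interface polyline vertices are mesh nodes, the
remaining nodes come from the regular level-set grid, thinned away from the
interface (full resolution within ``band_fine`` of the interface, every
second point to ``band_mid``, every fourth beyond).  Grid points closer
than 0.6 cells to the interface are dropped, which makes interface segments
Gabriel edges and hence edges of the Delaunay triangulation, so the
boundary traction can be integrated over actual mesh boundary edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .contours import Contour, gap_region


class SingularSystemError(RuntimeError):
    """The momentum balance has a null space (rigid-body modes)."""


@dataclass
class Mesh:
    points: np.ndarray  # (N, 2)
    triangles: np.ndarray  # (M, 3)
    n_interface: int  # interface nodes are points[:n_interface]
    interface_edges: np.ndarray  # (E, 2) node index pairs on the gap edge
    interface_normals: np.ndarray  # (n_interface, 2), gap-ward
    loop_slices: list  # per-loop slices into the interface nodes
    in_gap: np.ndarray | None = None  # per-triangle: fictitious gap material

    @property
    def n_points(self) -> int:
        return len(self.points)


def _thin_grid_points(grid, phi: np.ndarray, band_fine: float, band_mid: float) -> np.ndarray:
    ny, nx = grid.shape
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    dist = np.abs(phi)
    keep = dist <= band_fine
    keep |= (dist <= band_mid) & (iy % 2 == 0) & (ix % 2 == 0)
    keep |= (iy % 4 == 0) & (ix % 4 == 0)
    # always keep the grid border so the hull is the rectangle
    keep[0, :] = keep[-1, :] = True
    keep[:, 0] = keep[:, -1] = True
    X, Y = grid.meshgrid()
    return np.stack([X[keep], Y[keep]], axis=1), phi[keep]


def build_mesh(
    loops: list[Contour],
    grid,
    phi: np.ndarray,
    mesh_spacing: float | None = None,
    band_fine: float | None = None,
    band_mid: float | None = None,
    outer: dict | None = None,
    keep_gap: bool = False,
) -> Mesh:
    """Triangulate the tissue (enclosure minus gap).

    ``outer`` selects the outer boundary: ``None`` uses the grid rectangle,
    ``{"circle": (cx, cy, R)}`` clips to a disc (explicit rim nodes are
    added and exterior triangles dropped; the rim is traction-free, so its
    polygonal approximation only needs geometric fidelity).

    With ``keep_gap`` the gap is meshed too and marked in ``Mesh.in_gap``:
    the fixed-domain (one-fluid) formulation assigns it a very soft
    fictitious material and applies the edge traction as an internal
    force, which yields a smooth physical velocity on both sides of the
    interface.
    """
    h = grid.spacing
    hm = mesh_spacing or h
    b1 = band_fine if band_fine is not None else 8 * h
    b2 = band_mid if band_mid is not None else 20 * h

    ifc_pts, ifc_normals, slices = [], [], []
    start = 0
    for lp in loops:
        r = lp.resampled(hm)
        ifc_pts.append(r.points)
        ifc_normals.append(r.vertex_normals())
        slices.append(slice(start, start + r.n_points))
        start += r.n_points
    ifc_pts = np.vstack(ifc_pts)
    ifc_normals = np.vstack(ifc_normals)
    n_ifc = len(ifc_pts)

    gpts, gphi = _thin_grid_points(grid, phi, b1, b2)
    # clear of the interface so its segments stay Delaunay edges
    keep = (gphi <= -0.6 * hm) | (keep_gap & (gphi >= 0.6 * hm))
    gpts = gpts[keep]

    extra = []
    if outer and "circle" in outer:
        cx, cy, R = outer["circle"]
        r = np.hypot(gpts[:, 0] - cx, gpts[:, 1] - cy)
        gpts = gpts[r <= R - 0.6 * h]
        n_rim = max(32, int(np.ceil(2 * np.pi * R / (2 * h))))
        t = np.linspace(0, 2 * np.pi, n_rim, endpoint=False)
        extra.append(np.stack([cx + R * np.cos(t), cy + R * np.sin(t)], axis=1))

    pts = np.vstack([ifc_pts, gpts] + extra)
    tri = Delaunay(pts)
    simplices = tri.simplices
    cent = pts[simplices].mean(axis=1)

    region = gap_region(loops)
    shapely.prepare(region)
    in_gap = shapely.contains_xy(region, cent[:, 0], cent[:, 1])
    keep_tri = np.ones(len(simplices), bool) if keep_gap else ~in_gap
    if outer and "circle" in outer:
        cx, cy, R = outer["circle"]
        keep_tri &= np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) <= R
    simplices = simplices[keep_tri]
    in_gap = in_gap[keep_tri]

    # drop unused points and remap
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    if not np.all(remap[:n_ifc] == np.arange(n_ifc)):
        # every interface node must survive; otherwise traction is lost
        missing = int(np.sum(remap[:n_ifc] < 0))
        if missing:
            raise RuntimeError(f"{missing} interface nodes not meshed; refine the grid")
    pts = pts[used]
    simplices = remap[simplices]

    # interface edges: between-node edges on the gap boundary.  Without the
    # gap they are mesh boundary edges (exactly one adjacent triangle);
    # with the gap meshed they separate a tissue from a gap triangle.
    edges = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]]
    )
    edges_sorted = np.sort(edges, axis=1)
    if keep_gap:
        mat = np.tile(in_gap, 3)  # edges are block-stacked per local edge
        uniq, inv, counts = np.unique(
            edges_sorted, axis=0, return_inverse=True, return_counts=True
        )
        gap_count = np.zeros(len(uniq))
        np.add.at(gap_count, inv, mat.astype(float))
        two_sided = counts == 2
        mixed = two_sided & (gap_count == 1)
        bnd = uniq[mixed]
    else:
        uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
        bnd = uniq[counts == 1]
    on_ifc = (bnd[:, 0] < n_ifc) & (bnd[:, 1] < n_ifc)
    interface_edges = bnd[on_ifc]

    return Mesh(pts, simplices, n_ifc, interface_edges, ifc_normals, slices,
                in_gap if keep_gap else None)


# ---------------------------------------------------------------------------
# assembly


def _triangle_geometry(points: np.ndarray, tris: np.ndarray):
    p = points[tris]  # (M, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    detJ = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    area = 0.5 * np.abs(detJ)
    # gradients of the barycentric basis functions
    b = np.empty((len(tris), 3, 2))
    b[:, 0, 0] = p[:, 1, 1] - p[:, 2, 1]
    b[:, 1, 0] = p[:, 2, 1] - p[:, 0, 1]
    b[:, 2, 0] = p[:, 0, 1] - p[:, 1, 1]
    b[:, 0, 1] = p[:, 2, 0] - p[:, 1, 0]
    b[:, 1, 1] = p[:, 0, 0] - p[:, 2, 0]
    b[:, 2, 1] = p[:, 1, 0] - p[:, 0, 0]
    b /= detJ[:, None, None]
    return area, b


def assemble_operator(mesh: Mesh, eta, c_f) -> sparse.csc_matrix:
    """Assemble K for a(v, w) = int 2 eta D(v):D(w) + C_f v.w dx.

    ``eta`` and ``c_f`` may be scalars or per-triangle arrays (the
    fixed-domain formulation assigns the gap a soft fictitious material).
    Degrees of freedom are interleaved (node i -> 2i, 2i+1).  The operator
    is symmetric positive definite for C_f > 0; C_f = 0 leaves the three
    rigid-body modes (two translations, one rotation) unconstrained under
    pure-traction boundaries and is rejected upstream.
    """
    area, b = _triangle_geometry(mesh.points, mesh.triangles)
    M = len(mesh.triangles)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), (M,))
    c_f = np.broadcast_to(np.asarray(c_f, dtype=float), (M,))
    # strain-displacement matrix B (3 strain comps x 6 local dofs)
    B = np.zeros((M, 3, 6))
    for a_ in range(3):
        B[:, 0, 2 * a_] = b[:, a_, 0]  # e_xx <- u_x
        B[:, 1, 2 * a_ + 1] = b[:, a_, 1]  # e_yy <- u_y
        B[:, 2, 2 * a_] = b[:, a_, 1]  # gamma_xy
        B[:, 2, 2 * a_ + 1] = b[:, a_, 0]
    Cdiag = np.stack([2 * eta, 2 * eta, eta], axis=1)  # (M, 3)
    CB = Cdiag[:, :, None] * B
    Ke = np.einsum("mki,mkj->mij", B, CB) * area[:, None, None]
    # consistent mass for the friction term, per velocity component
    mloc = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]], dtype=float) / 12.0
    Me = np.zeros((M, 6, 6))
    Me[:, 0::2, 0::2] = mloc
    Me[:, 1::2, 1::2] = mloc
    Me *= (c_f * area)[:, None, None]
    Ke += Me

    dof = np.empty((M, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = sparse.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(2 * mesh.n_points, 2 * mesh.n_points)
    )
    return K.tocsc()


def traction_load(mesh: Mesh, traction_scalar: np.ndarray) -> np.ndarray:
    """Consistent load vector for the edge traction t = T(s) * n(s).

    ``traction_scalar`` holds T = f_L - gamma*kappa at each interface node;
    the vector traction T*n (n gap-ward) is integrated over the mesh
    boundary edges lying on the interface with linear interpolation.
    """
    f = np.zeros(2 * mesh.n_points)
    e = mesh.interface_edges
    if len(e) == 0:
        return f
    p = mesh.points
    L = np.linalg.norm(p[e[:, 1]] - p[e[:, 0]], axis=1)
    t0 = traction_scalar[e[:, 0], None] * mesh.interface_normals[e[:, 0]]
    t1 = traction_scalar[e[:, 1], None] * mesh.interface_normals[e[:, 1]]
    c0 = (L[:, None] / 6.0) * (2 * t0 + t1)
    c1 = (L[:, None] / 6.0) * (t0 + 2 * t1)
    np.add.at(f, 2 * e[:, 0], c0[:, 0])
    np.add.at(f, 2 * e[:, 0] + 1, c0[:, 1])
    np.add.at(f, 2 * e[:, 1], c1[:, 0])
    np.add.at(f, 2 * e[:, 1] + 1, c1[:, 1])
    return f


class FactorizedOperator:
    """LU-factorized momentum-balance operator reusable across load vectors.

    ``gap_softness`` sets the fictitious-material factor for gap triangles
    when the mesh carries them (fixed-domain formulation): both eta and
    C_f are scaled down so the gap fluid has the same screening length but
    negligible stresses, leaving the tissue-side traction condition intact
    up to that factor.
    """

    def __init__(self, mesh: Mesh, eta: float, c_f: float, gap_softness: float = 1e-3):
        if c_f <= 0:
            raise SingularSystemError(
                "C_f = 0 with pure-traction boundaries leaves a floating-body "
                "null space (translations and rotation); friction must be positive"
            )
        self.mesh = mesh
        if mesh.in_gap is not None:
            soft = np.where(mesh.in_gap, gap_softness, 1.0)
            self.K = assemble_operator(mesh, eta * soft, c_f * soft)
        else:
            self.K = assemble_operator(mesh, eta, c_f)
        self._lu = splu(self.K)

    def solve(self, f: np.ndarray) -> tuple[np.ndarray, float]:
        u = self._lu.solve(f)
        nf = np.linalg.norm(f)
        res = float(np.linalg.norm(self.K @ u - f) / nf) if nf > 0 else 0.0
        return u.reshape(-1, 2), res
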