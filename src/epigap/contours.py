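"""Closed planar contours describing the tissue-gap interface.

A :class:`Contour` is an ordered polyline of vertices in micrometres whose
last vertex implicitly connects back to the first.  The traversal sense is
normalized counter-clockwise, which places the gap interior on the left of
the direction of travel; with that convention the inward vertex normal
(rotate the tangent by +90 degrees) points into the gap, i.e. towards the
exterior of the tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import splev, splprep
from shapely.geometry import LinearRing, Polygon


class ContourError(ValueError):
    """Raised for degenerate or self-intersecting contours."""


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Closed, ordered polyline (``(n, 2)`` array of x, y in um).

    Parameters
    ----------
    points
        Vertex coordinates; the closing edge from the last vertex to the
        first is implicit (the first vertex is not repeated).
    metadata
        Free-form provenance (e.g. the generating shape specification).
    """

    points: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must be an (n, 2) array")
        # drop an explicit closing vertex and coincident consecutive points
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        if len(pts) > 1:
            d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            keep[1:] = d > 1e-12
        pts = pts[keep]
        # normalize orientation: counter-clockwise (gap interior on the left)
        if len(pts) >= 3 and _shoelace(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    # -- basic geometry -------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.roll(self.points, -1, axis=0) - self.points, axis=1)

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def signed_area(self) -> float:
        return _shoelace(self.points)

    @property
    def area(self) -> float:
        """Enclosed (gap) area in um^2."""
        return abs(self.signed_area)

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(Polygon(self.points).centroid.coords[0])

    def validate(self, min_points: int = 8) -> None:
        """Check the contour invariants, raising :class:`ContourError`."""
        if self.n_points < min_points:
            raise ContourError(f"contour has {self.n_points} < {min_points} points")
        if self.area <= 0:
            raise ContourError("contour encloses no area")
        if not self.is_simple():
            raise ContourError("contour is self-intersecting")

    def is_simple(self) -> bool:
        return LinearRing(self.points).is_valid

    def to_polygon(self) -> Polygon:
        return Polygon(self.points)

    # -- derived quantities ---------------------------------------------

    def arclength(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starting at 0)."""
        seg = self.segment_lengths
        return np.concatenate([[0.0], np.cumsum(seg[:-1])])

    def vertex_normals(self) -> np.ndarray:
        """Unit normals at vertices pointing into the gap (tissue exterior)."""
        nxt = np.roll(self.points, -1, axis=0)
        prv = np.roll(self.points, 1, axis=0)
        tangent = nxt - prv
        norm = np.linalg.norm(tangent, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        tangent /= norm
        # CCW traversal: interior (gap) is on the left; left normal = (-ty, tx)
        return np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)

    def resampled(self, spacing: float, min_points: int = 8) -> "Contour":
        """Resample at uniform arc-length ``spacing`` (linear interpolation)."""
        if spacing <= 0:
            raise ContourError("spacing must be positive")
        L = self.perimeter
        n = max(min_points, int(round(L / spacing)))
        s_new = np.linspace(0.0, L, n, endpoint=False)
        return Contour(self.interp_at(s_new), metadata=dict(self.metadata))

    def interp_at(self, s: np.ndarray) -> np.ndarray:
        """Positions at arc lengths ``s`` (periodic, linear)."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.mod(np.asarray(s, dtype=float), cum[-1])
        x = np.interp(s, cum, pts[:, 0])
        y = np.interp(s, cum, pts[:, 1])
        return np.stack([x, y], axis=1)

    def smoothed(self, sigma: float) -> "Contour":
        """Periodic Gaussian smoothing along arc length (scale ``sigma`` um).

        Intended for contours extracted from binary masks, whose
        pixel-scale raggedness otherwise corrupts normals and velocities;
        features larger than ``sigma`` are preserved.
        """
        from scipy.ndimage import gaussian_filter1d

        spacing = max(min(sigma / 2.0, 1.0), 1e-3)
        r = self.resampled(spacing)
        pts = r.points
        out = np.stack(
            [
                gaussian_filter1d(pts[:, 0], sigma / spacing, mode="wrap"),
                gaussian_filter1d(pts[:, 1], sigma / spacing, mode="wrap"),
            ],
            axis=1,
        )
        return Contour(out, metadata=dict(self.metadata))

    def max_turning_angle(self) -> float:
        """Largest exterior angle between consecutive segments (radians)."""
        seg = np.roll(self.points, -1, axis=0) - self.points
        seg = seg / np.maximum(np.linalg.norm(seg, axis=1, keepdims=True), 1e-300)
        cosang = np.clip(np.einsum("ij,ij->i", seg, np.roll(seg, 1, axis=0)), -1, 1)
        return float(np.arccos(cosang).max())

    def upsampled_smooth(self, spacing: float) -> "Contour":
        """Densify through a periodic cubic spline, or linearly at kinks.

        Used before signed-distance reconstruction so the faceting error
        of the polyline (the chord sagitta) stays far below the grid
        scale.  A cubic spline rings at tangent discontinuities and would
        displace the contour there on every redistancing, so contours
        with sharp turning angles are densified linearly instead (points
        stay exactly on the polyline).
        """
        pts = self.points
        L = self.perimeter
        n = max(16, int(np.ceil(L / spacing)))
        if self.max_turning_angle() > np.deg2rad(30.0):
            return self.resampled(spacing)
        try:
            tck, _ = splprep([pts[:, 0], pts[:, 1]], s=0.0, per=True, k=3)
            u = np.linspace(0.0, 1.0, n, endpoint=False)
            x, y = splev(u, tck)
            out = np.stack([x, y], axis=1)
            if not LinearRing(out).is_valid:  # spline overshoot
                raise ValueError
            return Contour(out, metadata=dict(self.metadata))
        except Exception:
            return self.resampled(spacing)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x_um,y_um", comments="")

    @classmethod
    def from_csv(cls, path) -> "Contour":
        return cls(np.loadtxt(path, delimiter=",", skiprows=1))

    def to_json(self, path) -> None:
        payload = {
            "format": "epigap-contour/1",
            "units": "um",
            "points": self.points.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Contour":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["points"]), metadata=payload.get("metadata", {}))


def gap_region(loops: list[Contour]):
    """Shapely region covered by the gap for a set of interface loops.

    Loops are combined even-odd (a loop nested inside another cuts a hole),
    which is the correct reading of "the set where the level-set field is
    positive" for nested interfaces.
    """
    region = None
    for lp in sorted(loops, key=lambda c: c.area, reverse=True):
        poly = Polygon(lp.points)
        if not poly.is_valid:
            poly = poly.buffer(0)
        region = poly if region is None else region.symmetric_difference(poly)
    return region


def contours_distance(a: Contour, b: Contour) -> float:
    """Max distance from vertices of ``a`` to the polyline of ``b``."""
    ring = LinearRing(b.points)
    pts = shapely.points(a.points)
    return float(shapely.distance(pts, ring).max())
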