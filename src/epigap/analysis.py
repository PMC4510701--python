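"""Edge kinematics: curvature-velocity sampling, fits, landmarks, shape.

Mirrors the kinematic analysis applied to segmented gap-closure movies:
points on the moving edge are characterized by their signed local
curvature (three-point circumcircle estimator at a fixed arc spacing,
15 um by default) and their normal velocity toward the gap, measured as
the displacement to the next contour along the local normal divided by
the frame interval.  Sampling is stratified across the curvature range so
the whole spread of curvatures is covered, and is deterministic under a
seed.  The velocity-curvature cloud is summarized either by a linear fit
near zero curvature (whose slope is proportional to the cable tension) or
by a logarithmic decay v = a - b*ln(kappa - kappa0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import LineString, LinearRing

from .contours import Contour
from .geometry import three_point_curvature


@dataclass
class VelocityCurvatureFit:
    form: str  # "linear" | "log"
    coefficients: dict
    r_squared: float
    n_samples: int
    window: tuple[float, float] | None = None

    def predict(self, kappa: np.ndarray) -> np.ndarray:
        k = np.asarray(kappa, dtype=float)
        c = self.coefficients
        if self.form == "linear":
            return c["intercept"] + c["slope"] * k
        return c["a"] - c["b"] * np.log(k - c["kappa0"])


@dataclass
class AreaSeries:
    t: np.ndarray
    area: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


def normal_displacement(
    point: np.ndarray,
    normal: np.ndarray,
    next_contour: Contour,
    window: float,
) -> float | None:
    """Signed distance from ``point`` to ``next_contour`` along ``normal``.

    Positive when the next contour lies on the gap side (edge advanced).
    ``None`` when the normal ray misses the next contour within the search
    window.
    """
    ray = LineString([point - window * normal, point + window * normal])
    hit = ray.intersection(LinearRing(next_contour.points))
    if hit.is_empty:
        return None
    if hit.geom_type == "Point":
        q = np.asarray(hit.coords[0])
    else:
        pts = [np.asarray(g.coords[0]) for g in getattr(hit, "geoms", [hit])]
        q = min(pts, key=lambda p: np.linalg.norm(p - point))
    return float(np.dot(q - point, normal))


def smoothed_normals(contour: Contour, support: float) -> np.ndarray:
    """Gap-ward unit normals from tangents over +/- ``support`` arc length.

    Segmented contours carry pixel-scale raggedness; a normal taken from
    adjacent vertices then points in an almost random direction, and the
    oblique crossing of the next contour overestimates the displacement by
    1/cos(error).  Averaging the tangent over a finite arc removes that
    bias without smoothing the contour itself.
    """
    s = contour.arclength()
    t = contour.interp_at(s + support) - contour.interp_at(s - support)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    t /= norm
    return np.stack([-t[:, 1], t[:, 0]], axis=1)


def sample_edge_points(
    contours: list[tuple[float, Contour]],
    n_points: int = 8,
    arc_spacing: float = 15.0,
    seed: int = 0,
    window: float | None = None,
    normal_support: float = 5.0,
    stratify: str = "kappa",
) -> tuple[pd.DataFrame, int]:
    """Sample curvature and normal velocity along a contour time series.

    For each consecutive frame pair, ``n_points`` vertices are drawn, one
    per stratum (seeded).  ``stratify="kappa"`` uses equal-width curvature
    bins so samples cover the whole curvature spread; ``stratify="arc"``
    uses equal arc-length sectors, appropriate when the contour has no
    genuine curvature spread (e.g. a circle, where the apparent spread is
    segmentation noise and curvature-extreme vertices are artifacts).
    Returns ``(samples, n_dropped)`` where ``samples`` has columns
    t, x, y, kappa_per_um, v_n_um_min.
    """
    if len(contours) < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    win = window if window is not None else arc_spacing
    rows, dropped = [], 0
    for (t0, c0), (t1, c1) in zip(contours[:-1], contours[1:]):
        if c0.perimeter <= 2 * arc_spacing:
            dropped += 1
            continue
        idx_all = np.arange(c0.n_points)
        kappa = three_point_curvature(c0, idx_all, arc_spacing)
        if stratify == "kappa":
            strat = kappa
        elif stratify == "arc":
            strat = c0.arclength()
        else:
            raise ValueError(f"unknown stratification {stratify!r}")
        edges = np.linspace(strat.min(), strat.max() + 1e-12, n_points + 1)
        normals = smoothed_normals(c0, normal_support)
        for b in range(n_points):
            sel = idx_all[(strat >= edges[b]) & (strat < edges[b + 1])]
            if len(sel) == 0:
                continue
            i = int(rng.choice(sel))
            disp = normal_displacement(c0.points[i], normals[i], c1, win)
            if disp is None:
                dropped += 1
                continue
            rows.append(
                dict(
                    t=t0,
                    x=c0.points[i, 0],
                    y=c0.points[i, 1],
                    kappa_per_um=float(kappa[i]),
                    v_n_um_min=disp / (t1 - t0),
                )
            )
    return pd.DataFrame(rows), dropped


def binned_mean_velocity(
    samples: pd.DataFrame, n_bins: int = 6
) -> pd.DataFrame:
    """Mean v_n in equal-count curvature bins (for monotonicity checks)."""
    df = samples.sort_values("kappa_per_um")
    df = df.assign(bin=pd.qcut(df["kappa_per_um"], n_bins, duplicates="drop"))
    out = (
        df.groupby("bin", observed=True)
        .agg(kappa=("kappa_per_um", "mean"), v_n=("v_n_um_min", "mean"), n=("v_n_um_min", "size"))
        .reset_index(drop=True)
    )
    return out


def fit_velocity_curvature(
    samples: pd.DataFrame,
    form: str = "log",
    window: tuple[float, float] | None = None,
) -> VelocityCurvatureFit:
    """Least-squares fit of the velocity-curvature relation.

    ``linear``: v = intercept + slope * kappa on the window (valid close to
    zero curvature; |slope| scales with the cable tension).
    ``log``: v = a - b * ln(kappa - kappa0) with the shift kappa0
    constrained below the smallest observed curvature.
    """
    df = samples
    if window is not None:
        df = df[(df.kappa_per_um >= window[0]) & (df.kappa_per_um <= window[1])]
    k = df["kappa_per_um"].to_numpy()
    v = df["v_n_um_min"].to_numpy()
    if len(k) < 5:
        raise ValueError("need at least 5 samples in the fit window")
    if np.ptp(k) < 1e-12:
        raise ValueError("degenerate design: all curvatures equal")
    if form == "linear":
        res = stats.linregress(k, v)
        fit = VelocityCurvatureFit(
            "linear",
            {"intercept": float(res.intercept), "slope": float(res.slope),
             "slope_stderr": float(res.stderr)},
            float(res.rvalue**2),
            len(k),
            window,
        )
        return fit
    if form != "log":
        raise ValueError(f"unknown fit form {form!r}")
    kmin = k.min()
    span = max(np.ptp(k), 1e-6)

    def model(theta):
        a, b, s = theta
        kappa0 = kmin - np.exp(s)
        return a - b * np.log(k - kappa0)

    def resid(theta):
        return model(theta) - v

    v_lo, v_hi = v[np.argmax(k)], v[np.argmin(k)]
    theta0 = np.array([np.mean(v), max((v_hi - v_lo), 1e-3), np.log(0.5 * span)])
    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=20000)
    a, b, s = sol.x
    kappa0 = kmin - np.exp(s)
    vhat = a - b * np.log(k - kappa0)
    return VelocityCurvatureFit(
        "log",
        {"a": float(a), "b": float(b), "kappa0": float(kappa0)},
        _r2(v, vhat),
        len(k),
        window,
    )


def pole_velocity(
    contours: list[tuple[float, Contour]],
    axis_x: float = 0.0,
) -> pd.DataFrame:
    """Edge speed at the two intersections of a vertical symmetry axis.

    The north pole is the larger-y intersection.  Speeds are positive when
    the landmark moves into the gap (the two intersections approach each
    other).  Frames where the contour no longer crosses the axis truncate
    the series (flagged by the returned frame count being short).
    """
    rows = []
    for t, c in contours:
        line = LineString(
            [(axis_x, c.points[:, 1].min() - 1.0), (axis_x, c.points[:, 1].max() + 1.0)]
        )
        hit = line.intersection(LinearRing(c.points))
        pts = []
        if hit.geom_type == "Point":
            pts = [hit.coords[0]]
        elif not hit.is_empty:
            pts = [g.coords[0] for g in hit.geoms]
        if len(pts) < 2:
            break
        ys = sorted(p[1] for p in pts)
        rows.append(dict(t=t, y_south=ys[0], y_north=ys[-1]))
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        dt = np.diff(df["t"])
        # north pole advances downward (into the gap), south pole upward
        df["v_north"] = np.concatenate([-np.diff(df["y_north"]) / dt, [np.nan]])
        df["v_south"] = np.concatenate([np.diff(df["y_south"]) / dt, [np.nan]])
    return df


def area_decay(series: list[tuple[float, float]] | "object") -> AreaSeries:
    """Linear fit of the gap-area decay A(t)."""
    if hasattr(series, "area_series"):
        t, A = series.area_series()
    else:
        arr = np.asarray(series, dtype=float)
        t, A = arr[:, 0], arr[:, 1]
    if len(t) < 3:
        raise ValueError("need at least 3 stored steps")
    res = stats.linregress(t, A)
    return AreaSeries(t, A, float(res.slope), float(res.intercept), float(res.rvalue**2))


def isoperimetric_ratio(contour: Contour) -> float:
    """Roundness Q = 4 pi A / P^2 in (0, 1]; Q = 1 iff circular."""
    P = contour.perimeter
    return float(4 * np.pi * contour.area / P**2)
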