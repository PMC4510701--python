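"""Synthetic inputs: gap geometries and textured phase-contrast-like frames.

The geometry families mirror the gap shapes used in micro-patterned
gap-closure assays: circles, moon-shaped gaps (a semicircle and a
semi-ellipse sharing a diameter, sweeping the edge curvature at the
elliptical pole through zero), multi-lobed non-convex shapes, and arbitrary
polygons.  The image generator produces frames in which the tissue carries
a stationary random texture while the gap is intensity-homogeneous, which
is the contrast a range-filter segmentation exploits.

Sign convention for the moon gap: ``h > 0`` makes the tissue bulge *into*
the gap at the elliptical pole, so the signed edge curvature there is
positive (tissue protrusion) and the gap area is ``pi R^2 / 2 - pi R h / 2``.
``h < 0`` bulges the gap outward (negative pole curvature, larger area);
``h = 0`` degenerates to a half-disk with a flat edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

from .contours import Contour, ContourError

ShapeFamily = Literal["circle", "moon", "lobed", "polygon"]


@dataclass
class ShapeSpec:
    """Parametric gap shape.

    family:
        ``circle``  -- ``radius``;
        ``moon``    -- ``radius`` (semicircle radius R) and ``h`` (signed
        semi-minor axis of the semi-ellipse, |h| < R, positive = tissue
        protrudes into the gap);
        ``lobed``   -- ``radius`` (base radius r0), ``lobe_amplitude`` eps
        (< r0) and ``lobe_count`` m: r(theta) = r0 + eps*cos(m*theta);
        ``polygon`` -- explicit ``vertices``.
    resolution:
        target arc-length spacing of the emitted points, um.
    """

    family: ShapeFamily
    radius: float | None = None
    h: float | None = None
    lobe_amplitude: float | None = None
    lobe_count: int | None = None
    vertices: Sequence[tuple[float, float]] | None = None
    center: tuple[float, float] = (0.0, 0.0)
    resolution: float = 1.0

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ContourError("resolution must be positive")
        if self.family in ("circle", "moon", "lobed"):
            if self.radius is None or self.radius <= 0:
                raise ContourError(f"{self.family} needs a positive radius")
        if self.family == "moon":
            if self.h is None or abs(self.h) >= self.radius:
                raise ContourError("moon needs |h| < radius")
        elif self.family == "lobed":
            if (
                self.lobe_amplitude is None
                or not 0 <= self.lobe_amplitude < self.radius
                or not self.lobe_count
                or self.lobe_count < 1
            ):
                raise ContourError("lobed needs 0 <= amplitude < radius and count >= 1")
        elif self.family == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ContourError("polygon needs >= 3 vertices")
        elif self.family not in ("circle", "moon", "lobed"):
            raise ContourError(f"unknown shape family {self.family!r}")

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        if "vertices" in d:
            d["vertices"] = [list(v) for v in d["vertices"]]
        return d


def _dense_circle(R: float, n: int) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([R * np.cos(t), R * np.sin(t)], axis=1)


def make_gap_contour(spec: ShapeSpec) -> Contour:
    """Emit the closed gap contour for ``spec`` at its arc-length resolution.

    The contour traverses counter-clockwise with the gap interior on the
    left; for the moon family the semicircular and semi-elliptical halves
    join with continuous position on the shared diameter (the tangent may
    be discontinuous there, which downstream curvature capping absorbs).
    """
    spec.validate()
    cx, cy = spec.center
    if spec.family == "circle":
        # uniform angular sampling is already uniform in arc length, so the
        # vertices are emitted exactly on the circle (no chordal resampling)
        n = max(8, int(round(2 * np.pi * spec.radius / spec.resolution)))
        pts = _dense_circle(spec.radius, n)
        contour = Contour(pts + np.array([cx, cy]))
        contour.metadata["shape_spec"] = spec.as_dict()
        contour.validate()
        return contour
    if spec.family == "moon":
        R, h = spec.radius, spec.h
        n = max(64, int(np.ceil(np.pi * R / spec.resolution)) * 4)
        # lower semicircle from (R, 0) through (0, -R) to (-R, 0)
        t = np.linspace(0.0, np.pi, n, endpoint=False)
        lower = np.stack([R * np.cos(-t), R * np.sin(-t)], axis=1)
        # upper boundary from (-R, 0) back to (R, 0): semi-ellipse with
        # signed semi-minor axis -h (h>0 dips into the half-disk)
        t2 = np.linspace(np.pi, 0.0, n, endpoint=False)
        upper = np.stack([R * np.cos(t2), -h * np.sin(t2)], axis=1)
        pts = np.vstack([lower, upper])
    elif spec.family == "lobed":
        r0, eps, m = spec.radius, spec.lobe_amplitude, spec.lobe_count
        n = max(128, int(np.ceil(2 * np.pi * (r0 + eps) / spec.resolution)) * 4)
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = r0 + eps * np.cos(m * t)
        pts = np.stack([r * np.cos(t), r * np.sin(t)], axis=1)
    else:  # polygon
        pts = np.asarray(spec.vertices, dtype=float)
        # densify edges so resampling respects the corners
        dense = []
        closed = np.vstack([pts, pts[:1]])
        for a, b in zip(closed[:-1], closed[1:]):
            k = max(1, int(np.ceil(np.linalg.norm(b - a) / (spec.resolution / 4))))
            seg = a + (b - a) * np.linspace(0, 1, k, endpoint=False)[:, None]
            dense.append(seg)
        pts = np.vstack(dense)
    contour = Contour(pts + np.array([cx, cy])).resampled(spec.resolution)
    contour.metadata["shape_spec"] = spec.as_dict()
    contour.validate()
    return contour


def moon_area(R: float, h: float) -> float:
    """Closed-form gap area of the moon parametrization (h signed)."""
    return np.pi * R**2 / 2 - np.pi * R * h / 2


def moon_pole_curvature(R: float, h: float) -> float:
    """Signed curvature at the elliptical pole (positive = tissue bulge)."""
    return h / R**2


# ---------------------------------------------------------------------------
# synthetic micrographs


@dataclass
class SyntheticImageSpec:
    """Textured fake micrograph: homogeneous gap inside textured tissue.

    The tissue texture is low-pass-filtered seeded Gaussian noise with local
    standard deviation ``sigma_tissue``; the gap is drawn around the same
    mean with ``sigma_gap << sigma_tissue``.  Generation is a pure function
    of (mask, spec): the same seed reproduces the frame bit-for-bit.
    """

    shape_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    mean_intensity: float = 100.0
    sigma_tissue: float = 20.0
    sigma_gap: float = 2.0
    sigma_noise: float = 1.0
    texture_corr_px: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.sigma_gap > self.sigma_tissue:
            raise ValueError("gap must be more homogeneous than tissue")


def contour_to_mask(contour: Contour, shape_px: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """Rasterize a gap contour to a boolean mask (True = gap).

    Pixel centres sit at ``(index + 0.5) * pixel_size_um``.
    """
    pts_px = contour.points / pixel_size_um - 0.5
    # polygon2mask expects (row, col) = (y, x)
    poly = np.stack([pts_px[:, 1], pts_px[:, 0]], axis=1)
    if poly[:, 0].min() < -0.5 or poly[:, 1].min() < -0.5 or \
       poly[:, 0].max() > shape_px[0] - 0.5 or poly[:, 1].max() > shape_px[1] - 0.5:
        raise ValueError("mask contour lies outside the image extent")
    return polygon2mask(shape_px, poly)


def _texture_fields(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded tissue-texture and gap-noise fields (unit variance)."""
    rng = np.random.default_rng(spec.seed)
    raw = rng.standard_normal(tuple(spec.shape_px))
    tex = gaussian_filter(raw, spec.texture_corr_px)
    std = tex.std()
    if std > 0:
        tex = tex / std
    gap_noise = rng.standard_normal(tuple(spec.shape_px))
    return tex, gap_noise


def make_synthetic_frame(
    mask: Contour | np.ndarray,
    spec: SyntheticImageSpec,
    fields: tuple[np.ndarray, np.ndarray] | None = None,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame; returns ``(image, ground_truth_mask)``.

    Pixels inside the gap come from the low-variance model, outside from
    the textured model, plus global additive noise.  ``fields`` may supply
    precomputed texture fields so a time-lapse shares one static tissue
    texture (as a real movie does) while ``noise_seed`` varies the
    additive noise per frame.
    """
    spec.validate()
    if isinstance(mask, Contour):
        mask = contour_to_mask(mask, spec.shape_px, spec.pixel_size_um)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(spec.shape_px):
        raise ValueError("mask shape does not match the image extent")
    tex, gap_noise = _texture_fields(spec) if fields is None else fields
    img = np.where(
        mask,
        spec.mean_intensity + spec.sigma_gap * gap_noise,
        spec.mean_intensity + spec.sigma_tissue * tex,
    )
    rng = np.random.default_rng([spec.seed if noise_seed is None else noise_seed, 2])
    img = img + spec.sigma_noise * rng.standard_normal(mask.shape)
    return img.astype(np.float32), mask


def make_shrinking_circle_movie(
    radius0_um: float,
    speed_um_min: float,
    n_frames: int,
    dt_min: float,
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-lapse of a circular gap shrinking at constant edge speed.

    Returns ``(stack, masks, times)``.  The tissue texture field is
    static across frames, as in a real time-lapse (cells do not redraw
    their texture between frames); only the additive sensor noise is
    refreshed per frame from substreams of ``spec.seed``.
    """
    ny, nx = spec.shape_px
    cx = nx * spec.pixel_size_um / 2
    cy = ny * spec.pixel_size_um / 2
    fields = _texture_fields(spec)
    frames, masks, times = [], [], []
    seeds = np.random.SeedSequence(spec.seed).spawn(n_frames)
    for i in range(n_frames):
        r = radius0_um - speed_um_min * i * dt_min
        if r <= 2 * spec.pixel_size_um:
            break
        c = make_gap_contour(
            ShapeSpec("circle", radius=r, center=(cx, cy), resolution=spec.pixel_size_um)
        )
        noise_seed = int(seeds[i].generate_state(1)[0] % 2**31)
        img, m = make_synthetic_frame(c, spec, fields=fields, noise_seed=noise_seed)
        frames.append(img)
        masks.append(m)
        times.append(i * dt_min)
    return np.stack(frames), np.stack(masks), np.asarray(times)


def write_tiff(path, stack: np.ndarray, pixel_size_um: float) -> None:
    """Write a single- or multi-page TIFF with the pixel size in metadata."""
    res = 1.0 / pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        path,
        stack,
        resolution=(res, res),
        metadata={"unit": "um", "pixel_size_um": pixel_size_um},
    )


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
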