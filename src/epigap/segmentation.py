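"""Gap segmentation for time-lapse frames: range filter -> threshold ->
morphological refinement -> binary mask -> contour.

The gap is intensity-homogeneous while the tissue is textured, so a
sliding-window range filter (max minus min over an odd window, 7-13 px in
practice) responds weakly inside the gap and strongly over the tissue.
Thresholding the response low-side and cleaning the mask morphologically
yields the gap mask; its boundary, in physical units, feeds the
curvature-velocity analysis directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .contours import Contour


class SegmentationError(RuntimeError):
    pass


@dataclass
class SegConfig:
    """Segmentation settings.

    ``threshold = None`` selects the automatic bimodal-histogram split
    (maximizing the between-class variance of the range response); a float
    overrides it.  The refinement sequence is binary closing, hole
    filling, then small-object removal, each configurable.
    """

    window: int = 9
    threshold: float | None = None
    closing_radius_px: int = 2
    min_object_px: int = 50
    fill_holes: bool = True
    compensate_window: bool = True
    contour_smooth_um: float = 2.0
    pixel_size_um: float = 0.5

    def validate(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.closing_radius_px < 0 or self.min_object_px < 0:
            raise ValueError("morphology parameters must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


def range_filter(image: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window max-minus-min response (edge-replicated borders)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    img = np.asarray(image, dtype=float)
    if min(img.shape) < window:
        raise ValueError("window does not fit in the image")
    mx = ndimage.maximum_filter(img, size=window, mode="nearest")
    mn = ndimage.minimum_filter(img, size=window, mode="nearest")
    return mx - mn


@dataclass
class BinaryMask:
    mask: np.ndarray  # True = gap
    pixel_size_um: float
    threshold: float
    n_components_removed: int = 0

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2


def segment_gap(image: np.ndarray, config: SegConfig) -> BinaryMask:
    """Segment the gap as the low-response region of the range filter."""
    config.validate()
    resp = range_filter(image, config.window)
    if config.threshold is None:
        if np.ptp(resp) == 0:
            raise SegmentationError("no gap found: flat range response")
        thr = float(threshold_otsu(resp))
    else:
        thr = float(config.threshold)
    gap = resp < thr
    if not gap.any():
        raise SegmentationError("no gap found: threshold leaves empty mask")
    if gap.all():
        raise SegmentationError("no tissue found: threshold selects the whole frame")
    if config.closing_radius_px > 0:
        gap = ndimage.binary_closing(
            gap, structure=morphology.disk(config.closing_radius_px)
        )
    if config.fill_holes:
        gap = ndimage.binary_fill_holes(gap)
    labels = measure.label(gap)
    n_comp = int(labels.max())
    if n_comp == 0:
        raise SegmentationError("no gap found after refinement")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    big_enough = np.flatnonzero(sizes >= config.min_object_px) + 1
    if len(big_enough) == 0:
        raise SegmentationError("no gap found after refinement")
    # keep the dominant component; report how many others were discarded
    keep = big_enough[int(np.argmax(sizes[big_enough - 1]))]
    gap = labels == keep
    if config.compensate_window:
        # the range filter responds to tissue texture anywhere within its
        # half-support, eroding the detected gap by ~window//2 pixels;
        # dilating by the same amount undoes the systematic bias
        gap = ndimage.binary_dilation(gap, structure=morphology.disk(config.window // 2))
    return BinaryMask(gap, config.pixel_size_um, thr, int(n_comp - len(big_enough)))


class ContourResult(NamedTuple):
    contour: Contour
    holes: list


def mask_to_contour(mask: BinaryMask | np.ndarray, pixel_size_um: float | None = None) -> ContourResult:
    """Boundary of the gap mask as a sub-pixel contour in micrometres.

    Pixel centres sit at ``(index + 0.5) * pixel_size``, matching the
    synthetic-frame rasterization.  The largest boundary loop is the gap
    contour; loops nested inside it (interior hole artifacts, e.g. with
    hole filling disabled) are returned separately.
    """
    if isinstance(mask, BinaryMask):
        arr, px = mask.mask, mask.pixel_size_um
    else:
        arr = np.asarray(mask, dtype=bool)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for a bare array")
        px = pixel_size_um
    if not arr.any():
        raise SegmentationError("gap closed: empty mask")
    # pad so loops touching the frame edge still close
    padded = np.pad(arr, 1, mode="constant").astype(float)
    loops = measure.find_contours(padded, 0.5)
    contours = []
    for rc in loops:
        if len(rc) < 8 or not np.allclose(rc[0], rc[-1]):
            continue
        rc = rc - 1.0
        pts = np.stack([(rc[:, 1] + 0.5) * px, (rc[:, 0] + 0.5) * px], axis=1)
        c = Contour(pts)
        if c.area > 0:
            contours.append(c)
    if not contours:
        raise SegmentationError("no closed gap boundary found")
    contours.sort(key=lambda c: c.area, reverse=True)
    return ContourResult(contours[0], contours[1:])


def segment_movie(
    stack: np.ndarray,
    config: SegConfig,
    times: np.ndarray | None = None,
    lock_threshold: bool = True,
) -> list[tuple[float, Contour]]:
    """Segment every frame of a stack into (time, contour) pairs.

    With ``lock_threshold`` (default) the automatic threshold is computed
    once on the first frame and reused, so the detected boundary does not
    drift with the shrinking gap fraction of the histogram.
    """
    out = []
    cfg = config
    for i, frame in enumerate(stack):
        t = float(times[i]) if times is not None else float(i)
        m = segment_gap(frame, cfg)
        if lock_threshold and cfg.threshold is None:
            cfg = replace(cfg, threshold=m.threshold)
        c = mask_to_contour(m).contour
        if cfg.contour_smooth_um > 0:
            c = c.smoothed(cfg.contour_smooth_um)
        out.append((t, c))
    return out


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0
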