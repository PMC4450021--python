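"""Hybrid morphological cell detection.

Converts one grayscale frame into a list of blob detections through a fixed
pipeline: iterative two-class mean thresholding, broken-edge mending, hole
filling by morphological reconstruction, binary median smoothing, dilation,
and a size/aspect-ratio component filter.

Coordinates are 0-based with x = column, y = row and pixel centers at
integers.  Components use 8-connectivity (background reachability for hole
filling uses the dual 4-connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure


class Detection(NamedTuple):
    """One segmented blob: centroid (px), pixel-count area, bounding box."""

    x: float
    y: float
    area: int
    bbox: tuple[int, int, int, int]  # (min_x, min_y, width, height)


class ThresholdResult(NamedTuple):
    threshold: float
    n_iter: int
    degenerate: bool  # constant image: one intensity class was empty


@dataclass(frozen=True)
class DetectConfig:
    """Parameters of the detection pipeline (intensities in [0, 255])."""

    init_threshold: float | None = None  # None: start from the intensity midrange
    threshold_tol: float = 0.5
    threshold_max_iter: int = 100
    median_window: int = 3
    dilation_radius: int = 1
    min_area: int = 20
    max_area: int = 5000
    ratio_lo: float = 0.5
    ratio_hi: float = 5.0


def _as_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    return img


def rescale_intensity(image: np.ndarray) -> np.ndarray:
    """Map an 8/16-bit or float frame linearly onto [0, 255]."""
    img = _as_image(image)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def stretch_contrast(image: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Percentile contrast stretch onto [0, 255] (plain utility)."""
    img = _as_image(image)
    lo, hi = np.percentile(img, [p_lo, p_hi])
    if hi == lo:
        return np.zeros_like(img)
    return np.clip((img - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def iterative_threshold(
    image: np.ndarray,
    init: float | None = None,
    tol: float = 0.5,
    max_iter: int = 100,
) -> ThresholdResult:
    """Two-class iterative mean threshold.

    Starting from ``init`` (the intensity midrange (min+max)/2 when
    omitted — robust when bright objects cover only a small fraction of
    the frame), pixels are split into an object set (> TH) and a
    background set (<= TH), and the threshold is replaced by the midpoint
    of the two class means until it moves by less than ``tol``.  On a
    constant image one class is empty; the mean of the remaining class
    (the constant itself) is returned with ``degenerate=True``.
    """
    img = _as_image(image)
    th = float((img.min() + img.max()) / 2.0 if init is None else init)
    for it in range(1, max_iter + 1):
        obj = img > th
        n_obj = int(obj.sum())
        if n_obj == 0 or n_obj == img.size:
            if img.min() == img.max():
                return ThresholdResult(float(img.mean()), it, True)
            th = float(img.mean())  # bad init emptied a class: restart
            continue
        m1 = img[obj].mean()
        m2 = img[~obj].mean()
        new = (m1 + m2) / 2.0
        if abs(new - th) < tol:
            # th reproduces itself within tolerance under one more iteration
            return ThresholdResult(th, it, False)
        th = new
    return ThresholdResult(th, max_iter, False)


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Object mask: 1 where intensity strictly exceeds the threshold."""
    return (_as_image(image) > threshold).astype(np.uint8)


def mend_edges(mask: np.ndarray) -> np.ndarray:
    """Repair single-pixel breaks in blob contours.

    A background pixel whose two opposite neighbors along any of the four
    directions (horizontal, vertical, both diagonals) are both foreground —
    i.e. the centered 3-pixel line sums to 2 — is promoted to foreground.
    Foreground pixels are never removed.
    """
    m = np.asarray(mask, dtype=np.uint8)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    p = np.pad(m, 1)
    core = p[1:-1, 1:-1]
    pairs = (
        (p[1:-1, :-2] & p[1:-1, 2:]),   # horizontal
        (p[:-2, 1:-1] & p[2:, 1:-1]),   # vertical
        (p[:-2, :-2] & p[2:, 2:]),      # main diagonal
        (p[:-2, 2:] & p[2:, :-2]),      # anti-diagonal
    )
    bridge = np.zeros_like(core)
    for pr in pairs:
        bridge |= pr
    return (core | ((core == 0) & bridge)).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not reachable from the image border.

    Morphological reconstruction from the border under the mask's
    complement; background connectivity is 4 (the dual of the 8-connected
    foreground convention).
    """
    m = np.asarray(mask, dtype=bool)
    return ndimage.binary_fill_holes(m).astype(np.uint8)


def median_smooth(mask: np.ndarray, window: int = 3) -> np.ndarray:
    """Binary median (majority) filter over a window x window neighborhood."""
    if window < 3 or window % 2 == 0:
        raise ValueError("median window must be an odd integer >= 3")
    m = np.asarray(mask, dtype=np.uint8)
    return ndimage.median_filter(m, size=window, mode="constant", cval=0)


def dilate(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Grow the foreground with a (2r+1) x (2r+1) square element."""
    if radius < 0:
        raise ValueError("dilation radius must be >= 0")
    m = np.asarray(mask, dtype=bool)
    if radius == 0:
        return m.astype(np.uint8)
    se = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return ndimage.binary_dilation(m, structure=se).astype(np.uint8)


def extract_components(
    mask: np.ndarray,
    min_area: int,
    max_area: int,
    ratio_lo: float = 0.5,
    ratio_hi: float = 5.0,
) -> list[Detection]:
    """Label 8-connected components and keep plausible cell blobs.

    Components outside [min_area, max_area] or whose bounding-box
    width/height ratio falls outside [ratio_lo, ratio_hi] are discarded as
    non-cell structure.  Centroids are the mean of member pixel coordinates.
    """
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    m = np.asarray(mask, dtype=np.uint8)
    labels = measure.label(m, connectivity=2)
    out: list[Detection] = []
    for region in measure.regionprops(labels):
        area = int(region.area)
        if area < min_area or area > max_area:
            continue
        min_row, min_col, max_row, max_col = region.bbox
        w, h = max_col - min_col, max_row - min_row
        ratio = w / h
        if ratio < ratio_lo or ratio > ratio_hi:
            continue
        cy, cx = region.centroid
        out.append(Detection(float(cx), float(cy), area, (min_col, min_row, w, h)))
    return out


def detect_cells(image: np.ndarray, config: DetectConfig | None = None) -> list[Detection]:
    """Full detection pipeline on one grayscale frame.

    threshold -> binarize -> mend -> fill holes -> median -> dilate ->
    component extraction, in that order.
    """
    cfg = config or DetectConfig()
    img = _as_image(image)
    th = iterative_threshold(
        img, cfg.init_threshold, cfg.threshold_tol, cfg.threshold_max_iter
    )
    if th.degenerate:
        return []
    mask = binarize(img, th.threshold)
    mask = mend_edges(mask)
    mask = fill_holes(mask)
    mask = median_smooth(mask, cfg.median_window)
    mask = dilate(mask, cfg.dilation_radius)
    return extract_components(
        mask, cfg.min_area, cfg.max_area, cfg.ratio_lo, cfg.ratio_hi
    )
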