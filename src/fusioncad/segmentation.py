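"""Lesion segmentation: contrast enhancement, denoising, binarization,
border following and padded bounding-box ROI extraction.

The pipeline mirrors the classical mammography preprocessing chain: global
histogram equalization stretches the low-contrast mass against the breast
tissue, a small median filter removes impulsive artifacts, a global threshold
(Otsu by default) binarizes, a 9x9 median filter cleans the binary image,
border following extracts ordered outer contours of every connected
component, the largest filled component is taken as the lesion, and a
25-pixel-padded bounding box crops the ROI.

Border following is the Suzuki-Abe style outer-border trace with
8-connectivity: the ordered contour of each component visits exactly the
foreground pixels that have at least one 4-connected background neighbour
(the component's morphological inner boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

AUTO = "auto"

#: clockwise Moore neighbourhood starting at the left neighbour
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_EIGHT = np.ones((3, 3), dtype=int)


class NoLesionFoundError(RuntimeError):
    """Raised when thresholding leaves no foreground to segment."""


@dataclass(frozen=True)
class Contour:
    """Ordered closed boundary of one connected component.

    ``points`` are (row, col) pixel coordinates; consecutive points (and the
    last-to-first pair when ``closed``) are 8-connected.
    """

    points: tuple[tuple[int, int], ...]
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=int)


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive pixel-coordinate rectangle."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError("degenerate bounding box")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min + 1, self.col_max - self.col_min + 1)

    def crop(self, img: np.ndarray) -> np.ndarray:
        return img[self.row_min : self.row_max + 1, self.col_min : self.col_max + 1]


@dataclass(frozen=True)
class SegmentationConfig:
    threshold: float | str = AUTO  # intensity in [0,255] or "auto" (Otsu)
    median_pre: int = 3  # denoising window before thresholding (3 or 5)
    median_post: int = 9  # binary cleanup window after thresholding
    tolerance: int = 25  # bounding-box padding in pixels
    fill_holes: bool = True


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization over the 256 intensity levels.

    The mapping is ``H'(v) = round(255 * cdf(v) / N)`` where ``cdf`` is the
    cumulative histogram; it is monotone non-decreasing in ``v``, so intensity
    ordering is preserved.
    """
    img = _check_gray(img)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    lut = np.round(255.0 * cdf / cdf[-1]).astype(np.uint8)
    return lut[img]


def median_filter(img: np.ndarray, window: int) -> np.ndarray:
    """Median filter with edge replication at the borders."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    img = np.asarray(img)
    return ndimage.median_filter(img, size=window, mode="nearest")


def threshold_binarize(img: np.ndarray, thr: float | str = AUTO) -> np.ndarray:
    """Binarize: mask = 1 where intensity strictly exceeds the threshold.

    ``thr="auto"`` picks the threshold by Otsu's between-class-variance
    criterion on the image histogram.
    """
    img = _check_gray(img)
    if isinstance(thr, str):
        if thr != AUTO:
            raise ValueError(f"threshold must be a number or '{AUTO}'")
        if img.min() == img.max():  # Otsu undefined on a constant image
            return np.zeros_like(img, dtype=np.uint8)
        thr_val = float(threshold_otsu(img))
    else:
        thr_val = float(thr)
        if not 0 <= thr_val <= 255:
            raise ValueError("threshold must lie in [0, 255]")
    return (img > thr_val).astype(np.uint8)


def _trace_border(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Follow the outer border of the component containing ``start``.

    ``start`` must be the first component pixel in raster order, so the pixel
    to its left is background. Clockwise Moore tracing with Jacob's stopping
    criterion (return to start entering from the initial backtrack direction).
    """
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c] != 0

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return [start]  # isolated single pixel

    contour: list[tuple[int, int]] = []
    cur = start
    prev_dir = 0  # scan clockwise beginning at the left neighbour (background)
    start_state: tuple[tuple[int, int], int] | None = None
    while True:
        for k in range(8):
            d = (prev_dir + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                break
        state = (cur, d)
        if start_state is None:
            start_state = state
        elif cur == start and state == start_state:
            break  # about to repeat the very first move: cycle complete
        contour.append(cur)
        cur = (nr, nc)
        # next scan starts just past the backtrack direction (d+4)
        prev_dir = (d + 5) % 8
    return contour


def trace_contours(mask: np.ndarray) -> list[Contour]:
    """Ordered outer border of every 8-connected foreground component.

    Components are reported in raster order of their first pixel. The pixel
    set of each contour equals the component's morphological boundary
    (foreground pixels with at least one 4-connected background neighbour).
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if mask.sum() == 0:
        return []
    labels, n = ndimage.label(mask, structure=_EIGHT)
    contours = []
    for lab in range(1, n + 1):
        comp = (labels == lab).astype(np.uint8)
        rs, cs = np.nonzero(comp)
        first = int(np.argmin(rs * mask.shape[1] + cs))
        start = (int(rs[first]), int(cs[first]))
        pts = _trace_border(comp, start)
        contours.append(Contour(points=tuple(pts), closed=True))
    return contours


def largest_lesion(
    contours: list[Contour], mask: np.ndarray
) -> tuple[Contour, np.ndarray]:
    """Pick the contour whose enclosed filled region has the largest area.

    Ties break in favour of the component whose first pixel comes first in
    raster (topmost, then leftmost) order; contours are already in that order.
    Returns the winning contour and its filled region as a mask.
    """
    if not contours:
        raise NoLesionFoundError("no lesion found: empty contour list")
    mask = np.asarray(mask)
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    best = None
    for contour in contours:
        r0, c0 = contour.points[0]
        comp = labels == labels[r0, c0]
        filled = ndimage.binary_fill_holes(comp)
        area = int(filled.sum())
        if best is None or area > best[0]:
            best = (area, contour, filled.astype(np.uint8))
    return best[1], best[2]


def bounding_box(
    contour: Contour, tolerance: int, image_shape: tuple[int, int]
) -> BoundingBox:
    """Minimal enclosing rectangle padded by ``tolerance``, clipped to bounds."""
    if len(contour) == 0:
        raise ValueError("empty contour")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pts = contour.as_array()
    h, w = image_shape
    return BoundingBox(
        row_min=max(0, int(pts[:, 0].min()) - tolerance),
        row_max=min(h - 1, int(pts[:, 0].max()) + tolerance),
        col_min=max(0, int(pts[:, 1].min()) - tolerance),
        col_max=min(w - 1, int(pts[:, 1].max()) + tolerance),
    )


def segment_lesion(
    img: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full segmentation chain; returns (full-size lesion mask, cropped ROI).

    equalize -> median(pre) -> threshold -> median(9x9) -> hole filling ->
    border following -> largest component -> padded bounding box -> crop of
    the *original* image. Deterministic for fixed config.
    """
    config = config or SegmentationConfig()
    img = _check_gray(img)
    eq = equalize_histogram(img)
    den = median_filter(eq, config.median_pre)
    binary = threshold_binarize(den, config.threshold)
    binary = median_filter(binary, config.median_post)
    if config.fill_holes:
        binary = ndimage.binary_fill_holes(binary).astype(np.uint8)
    if binary.sum() == 0:
        raise NoLesionFoundError("no lesion found: empty mask after thresholding")
    contours = trace_contours(binary)
    contour, lesion_mask = largest_lesion(contours, binary)
    box = bounding_box(contour, config.tolerance, img.shape)
    return lesion_mask, box.crop(img)


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img
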