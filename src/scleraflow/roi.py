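"""Region-of-interest detection from gradient informativity.

An unstable scleral video only intermittently shows well-focused vessels.
Each frame is scored by the Michelson-type contrast of its gradient-magnitude
image, ``C = (g_max - g_min) / (g_max + g_min)``; frames with ``C < 0.3``
carry too little information to analyse. For informative frames a
binarization threshold is picked at the knee of the cumulative gradient
histogram (the bin of maximum perpendicular distance to the chord between the
histogram's border points), small debris is removed by size, the surviving
objects are linked by dilation, and their joint bounding box is the ROI.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "GradientMap",
    "ContrastReport",
    "ROIBox",
    "gradient_magnitude",
    "contrast_index",
    "knee_threshold",
    "roi_from_frame",
]

LOW_INFORMATIVITY_C = 0.3  # frames below this contrast are discarded


@dataclasses.dataclass(frozen=True)
class GradientMap:
    """Per-pixel gradient magnitude of one frame (max of the two Sobel
    components), together with its extreme values."""

    g: np.ndarray
    g_max: float
    g_min: float

    @classmethod
    def from_array(cls, g: np.ndarray) -> "GradientMap":
        g = np.asarray(g, dtype=np.float64)
        return cls(g=g, g_max=float(g.max()), g_min=float(g.min()))


@dataclasses.dataclass(frozen=True)
class ContrastReport:
    """Informativity verdict for one gradient map."""

    C: float
    low_informativity: bool


@dataclasses.dataclass(frozen=True)
class ROIBox:
    """An axis-aligned informative rectangle on one frame.

    ``x0``/``y0`` are the top-left column/row; the box is half-open,
    ``[y0, y0+height) x [x0, x0+width)``.
    """

    x0: int
    y0: int
    width: int
    height: int
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must be at least 1x1")

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) center of the box."""
        return (self.y0 + (self.height - 1) / 2.0, self.x0 + (self.width - 1) / 2.0)

    def clip_to(self, shape: tuple[int, int]) -> "ROIBox":
        h, w = shape
        x0 = max(0, min(self.x0, w - 1))
        y0 = max(0, min(self.y0, h - 1))
        return ROIBox(
            x0=x0,
            y0=y0,
            width=min(self.width, w - x0),
            height=min(self.height, h - y0),
            frame_index=self.frame_index,
        )


def gradient_magnitude(frame: np.ndarray) -> GradientMap:
    """Gradient magnitude as the maximum of the two 3x3 Sobel responses.

    The horizontal and vertical Sobel operators are applied with edge
    replication at the border; the per-pixel result is
    ``max(|Sobel_h|, |Sobel_v|)``, collecting structure from both directions.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    gh = ndimage.sobel(frame, axis=1, mode="nearest")
    gv = ndimage.sobel(frame, axis=0, mode="nearest")
    g = np.maximum(np.abs(gh), np.abs(gv))
    return GradientMap.from_array(g)


def contrast_index(gmap: GradientMap) -> ContrastReport:
    """Michelson contrast of the gradient image.

    ``C = (g_max - g_min) / (g_max + g_min)``; a frame is flagged as low
    informativity when ``C < 0.3``. A blank map (both extremes zero) is
    defined as ``C = 0`` and flagged, with a warning.
    """
    total = gmap.g_max + gmap.g_min
    if total == 0:
        warnings.warn("blank gradient map: contrast undefined, reported as 0")
        return ContrastReport(C=0.0, low_informativity=True)
    c = (gmap.g_max - gmap.g_min) / total
    return ContrastReport(C=float(c), low_informativity=bool(c < LOW_INFORMATIVITY_C))


def knee_threshold(gmap: GradientMap | np.ndarray, n_bins: int = 256) -> float:
    """Binarization threshold at the knee of the cumulative gradient histogram.

    The histogram of gradient values is accumulated; a chord is drawn between
    its border points (first and last nonempty bins) and the threshold is the
    bin value at maximum perpendicular distance from that chord — the point of
    maximum bend of the cumulative curve. Ties break toward the lowest bin.
    """
    g = gmap.g if isinstance(gmap, GradientMap) else np.asarray(gmap, dtype=np.float64)
    if not np.isfinite(g).all():
        raise ValueError("gradient map contains non-finite values")
    gmax = g.max()
    if gmax <= 0:
        return 0.0
    hist, edges = np.histogram(g, bins=n_bins, range=(0.0, gmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    cum = np.cumsum(hist).astype(np.float64)
    nonempty = np.flatnonzero(hist)
    lo, hi = nonempty[0], nonempty[-1]
    if lo == hi:
        return float(centers[lo])
    # perpendicular distance of (i, cum[i]) from the chord (lo,cum[lo])-(hi,cum[hi])
    x = np.arange(lo, hi + 1, dtype=np.float64)
    y = cum[lo : hi + 1]
    dx, dy = float(hi - lo), float(cum[hi] - cum[lo])
    dist = np.abs(dy * (x - lo) - dx * (y - cum[lo])) / np.hypot(dx, dy)
    best = int(np.argmax(dist))  # argmax returns the first (lowest-bin) maximum
    return float(centers[lo + best])


def roi_from_frame(
    frame: np.ndarray,
    min_object_px: int = 20,
    dilation_radius: int = 2,
    frame_index: int = 0,
    n_bins: int = 256,
) -> tuple[ROIBox | None, ContrastReport]:
    """Locate the most informative region of one frame.

    Pipeline: gradient magnitude -> contrast index -> knee threshold ->
    binarize -> remove objects smaller than ``min_object_px`` -> dilate by a
    disk of ``dilation_radius`` to link separated objects -> bounding box of
    the remaining objects' contours. Returns ``(None, report)`` when the frame
    is low-informativity or nothing survives size filtering.
    """
    gmap = gradient_magnitude(frame)
    report = contrast_index(gmap)
    if report.low_informativity:
        return None, report
    thr = knee_threshold(gmap, n_bins=n_bins)
    binary = gmap.g >= thr
    binary = morphology.remove_small_objects(binary, max_size=int(min_object_px) - 1)
    if not binary.any():
        return None, report
    if dilation_radius > 0:
        binary = morphology.dilation(binary, morphology.disk(dilation_radius))
    rows = np.flatnonzero(binary.any(axis=1))
    cols = np.flatnonzero(binary.any(axis=0))
    box = ROIBox(
        x0=int(cols[0]),
        y0=int(rows[0]),
        width=int(cols[-1] - cols[0] + 1),
        height=int(rows[-1] - rows[0] + 1),
        frame_index=frame_index,
    )
    return box, report
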