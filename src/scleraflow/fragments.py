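"""Splitting an unstable video into stabilizable fragments.

The informative region's intensity-weighted centroid (center of mass of
contrast) is tracked frame to frame. When it drifts further than a constant
limit (100 px by default) from the fragment's first frame — or a frame has no
informative region at all — the current fragment ends and a new one begins.
Each fragment is then cropped to a common box: the minimum per-frame ROI
extent, centered on each frame's centroid, so that every cropped frame shows
the same vessel region at the same size.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np

from .roi import GradientMap, ROIBox
from .video import VideoSequence

__all__ = [
    "CentroidReport",
    "Fragment",
    "FragmenterConfig",
    "weighted_centroid",
    "split_fragments",
    "common_box",
    "crop_fragment",
    "write_fragment_manifest",
]

DRIFT_LIMIT_PX = 100.0  # centroid drift beyond this ends a fragment


@dataclasses.dataclass(frozen=True)
class CentroidReport:
    """Weighted center of mass of the informative pixels inside one ROI.

    ``p`` is the normalization coefficient that scales the maximum in-ROI
    intensity to unit weight; ``n`` counts the informative pixels.
    """

    x_c: float
    y_c: float
    n: int
    p: float

    @property
    def rc(self) -> np.ndarray:
        return np.array([self.y_c, self.x_c])


@dataclasses.dataclass
class Fragment:
    """A contiguous frame range sharing one tracked vessel region."""

    start_frame: int
    end_frame: int  # inclusive
    centers: list[CentroidReport]
    # common box: corner points and the (w_b, h_b) crop size
    corner_min: tuple[float, float] | None = None  # (x_c1, y_c1)
    corner_max: tuple[float, float] | None = None  # (x_c2, y_c2)
    box_size: tuple[int, int] | None = None  # (w_b, h_b)

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("fragment must contain at least one frame")
        if len(self.centers) != self.end_frame - self.start_frame + 1:
            raise ValueError("one centroid per frame required")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclasses.dataclass(frozen=True)
class FragmenterConfig:
    drift_limit: float = DRIFT_LIMIT_PX
    min_fragment_len: int = 2

    def __post_init__(self) -> None:
        if self.drift_limit <= 0:
            raise ValueError("drift_limit must be positive")


def weighted_centroid(
    gmap: GradientMap | np.ndarray,
    roi: ROIBox,
    threshold: float,
    literal_denominator: bool = False,
) -> CentroidReport:
    """Center of mass of the informative (above-threshold) pixels in the ROI.

    Weights are the gradient intensities scaled by ``p`` so the maximum in-ROI
    intensity has unit weight; the centroid is the standard weighted mean
    ``sum(x_i * I_i * p) / sum(I_i * p)``. With ``literal_denominator`` the
    sum of weighted coordinates is divided by the plain pixel count ``n``
    instead (an alternative reading that does not generally land inside the
    support; kept for comparison only).
    """
    g = gmap.g if isinstance(gmap, GradientMap) else np.asarray(gmap, dtype=np.float64)
    sub = g[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    rows, cols = np.nonzero(sub >= threshold)
    if rows.size == 0:
        raise ValueError("no informative pixel in ROI: centroid undefined")
    weights = sub[rows, cols]
    wmax = weights.max()
    p = 1.0 / wmax if wmax > 0 else 1.0
    wp = weights * p
    denom = float(rows.size) if literal_denominator else float(wp.sum())
    x_c = float((cols + roi.x0) @ wp) / denom
    y_c = float((rows + roi.y0) @ wp) / denom
    return CentroidReport(x_c=x_c, y_c=y_c, n=int(rows.size), p=float(p))


def split_fragments(
    per_frame_centers: Sequence[CentroidReport | None],
    cfg: FragmenterConfig = FragmenterConfig(),
) -> list[Fragment]:
    """Greedy split of the frame axis into fragments with a persistent region.

    A fragment ends before frame ``t`` when that frame has no informative
    region, or when its centroid lies further than ``cfg.drift_limit``
    (Euclidean) from the centroid of the fragment's first frame. Fragments
    shorter than ``cfg.min_fragment_len`` are discarded.
    """
    fragments: list[Fragment] = []
    start: int | None = None
    centers: list[CentroidReport] = []

    def flush(end: int) -> None:
        nonlocal start, centers
        if start is not None and end - start + 1 >= cfg.min_fragment_len:
            fragments.append(Fragment(start_frame=start, end_frame=end, centers=centers))
        start, centers = None, []

    for t, center in enumerate(per_frame_centers):
        if center is None:
            flush(t - 1)
            continue
        if start is None:
            start, centers = t, [center]
            continue
        drift = float(np.hypot(center.x_c - centers[0].x_c, center.y_c - centers[0].y_c))
        if drift > cfg.drift_limit:
            flush(t - 1)
            start, centers = t, [center]
        else:
            centers.append(center)
    flush(len(per_frame_centers) - 1)
    return fragments


def common_box(fragment: Fragment, per_frame_rois: Sequence[ROIBox]) -> Fragment:
    """Fill the fragment's common box from its per-frame ROIs.

    The corner points are the elementwise min/max of all ROI corner
    coordinates over the fragment's frames; the crop size ``(w_b, h_b)`` is
    the minimum per-frame ROI width/height, so the common window fits inside
    every frame's ROI.
    """
    if len(per_frame_rois) != fragment.n_frames:
        raise ValueError("one ROI per fragment frame required")
    xs0 = [r.x0 for r in per_frame_rois]
    ys0 = [r.y0 for r in per_frame_rois]
    xs1 = [r.x0 + r.width - 1 for r in per_frame_rois]
    ys1 = [r.y0 + r.height - 1 for r in per_frame_rois]
    w_b = min(r.width for r in per_frame_rois)
    h_b = min(r.height for r in per_frame_rois)
    if w_b < 1 or h_b < 1:
        raise ValueError("degenerate common box")
    fragment.corner_min = (float(min(xs0)), float(min(ys0)))
    fragment.corner_max = (float(max(xs1)), float(max(ys1)))
    fragment.box_size = (int(w_b), int(h_b))
    return fragment


def _window_origin(
    center_rc: np.ndarray, box: tuple[int, int], shape: tuple[int, int]
) -> tuple[int, int]:
    """Top-left of a (w_b, h_b) window centered on the centroid, shifted
    inward so it stays inside the frame."""
    w_b, h_b = box
    h, w = shape
    if w_b > w or h_b > h:
        raise ValueError("common box larger than frame")
    r0 = int(round(center_rc[0] - (h_b - 1) / 2.0))
    c0 = int(round(center_rc[1] - (w_b - 1) / 2.0))
    r0 = min(max(r0, 0), h - h_b)
    c0 = min(max(c0, 0), w - w_b)
    return r0, c0


def crop_fragment(video: VideoSequence, fragment: Fragment) -> VideoSequence:
    """Crop the fragment's frames to per-frame centered common-box windows.

    Every output frame has the identical shape ``(h_b, w_b)``; windows are
    centered on each frame's centroid and shifted inward at the border.
    """
    if fragment.box_size is None:
        raise ValueError("fragment has no common box: call common_box() first")
    w_b, h_b = fragment.box_size
    shape = video.frame_shape
    out = np.empty((fragment.n_frames, h_b, w_b))
    for i, center in enumerate(fragment.centers):
        frame = video[fragment.start_frame + i]
        r0, c0 = _window_origin(center.rc, (w_b, h_b), shape)
        out[i] = frame[r0 : r0 + h_b, c0 : c0 + w_b]
    return video.with_frames(out)


def write_fragment_manifest(fragments: Sequence[Fragment], path: str | os.PathLike) -> Path:
    """Write the fragment list as a JSON manifest."""
    payload = [
        {
            "start": f.start_frame,
            "end": f.end_frame,
            "centers": [[c.x_c, c.y_c] for c in f.centers],
            "corner_min": f.corner_min,
            "corner_max": f.corner_max,
            "box_size": f.box_size,
        }
        for f in fragments
    ]
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=2)
    return p
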