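"""Fragment stabilization: register every frame to a fixed coordinate system.

Two interchangeable translation estimators are provided, mirroring the two
approaches that work on vessel imagery:

* zero-normalized cross-correlation of a reference patch (the central 50% of
  the first frame's ROI) against every frame — slow but highest quality;
* Shi-Tomasi corners tracked with pyramidal Lucas–Kanade optical flow, the
  per-frame offset taken as the component-wise median of the tracked
  displacements — fast, with automatic fallback to correlation when too few
  points survive.

Only pure translation is modeled. Offsets are reported as the content's
displacement relative to frame 0; stabilization shifts each frame back by its
offset and crops to the common valid region.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import corner_shi_tomasi, match_template, peak_local_max

from .roi import ROIBox, roi_from_frame
from .video import VideoSequence

__all__ = [
    "ReferencePatch",
    "CorrelationMap",
    "MatchStats",
    "KeypointTrack",
    "OffsetVector",
    "reference_patch",
    "correlate",
    "zncc_direct",
    "detect_keypoints",
    "track_keypoints",
    "matching_rate",
    "frame_offset",
    "stabilize",
]


@dataclasses.dataclass(frozen=True)
class OffsetVector:
    """Translation of a frame's content relative to the origin frame."""

    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValueError("offset must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy])


@dataclasses.dataclass(frozen=True)
class ReferencePatch:
    """The matching template: a centered sub-window of the first frame's ROI.

    ``origin_rc`` is the patch's top-left (row, col) in the reference frame;
    the patch center is the coordinate origin of the stabilized system.
    """

    pixels: np.ndarray
    origin_rc: tuple[int, int]

    @property
    def center_rc(self) -> tuple[float, float]:
        h, w = self.pixels.shape
        return (self.origin_rc[0] + (h - 1) / 2.0, self.origin_rc[1] + (w - 1) / 2.0)


@dataclasses.dataclass(frozen=True)
class CorrelationMap:
    """Normalized cross-correlation values over all valid shifts.

    ``G[r, c]`` is the correlation of the patch with its top-left placed at
    ``(r, c)`` in the searched frame; values lie in ``[-1, 1]``.
    """

    G: np.ndarray


@dataclasses.dataclass(frozen=True)
class MatchStats:
    """Key-point matching summary between two frames."""

    Kp1: int
    Kp2: int
    M: int
    elapsed: float = 0.0

    @property
    def Mr(self) -> float:
        return matching_rate(self.Kp1, self.Kp2, self.M)


@dataclasses.dataclass(frozen=True)
class KeypointTrack:
    """Subpixel point correspondences between two frames."""

    points1: np.ndarray  # (N, 2) (row, col) on frame 1
    points2: np.ndarray  # (N, 2) tracked positions on frame 2
    status: np.ndarray  # (N,) bool, True = tracked

    @property
    def displacements(self) -> np.ndarray:
        """(M, 2) (drow, dcol) of the tracked points only."""
        return (self.points2 - self.points1)[self.status]


def reference_patch(fragment_video: VideoSequence, roi: ROIBox) -> ReferencePatch:
    """Cut the matching template from the first frame.

    The template covers 50% of the ROI's linear extent in each axis and
    shares the ROI's center (floor rounding for odd extents).
    """
    if roi.width < 4 or roi.height < 4:
        raise ValueError("ROI too small for a reference patch (needs >= 4x4)")
    ph, pw = roi.height // 2, roi.width // 2
    r0 = roi.y0 + (roi.height - ph) // 2
    c0 = roi.x0 + (roi.width - pw) // 2
    pixels = np.array(fragment_video[0][r0 : r0 + ph, c0 : c0 + pw])
    return ReferencePatch(pixels=pixels, origin_rc=(r0, c0))


def zncc_direct(frame: np.ndarray, patch: np.ndarray) -> np.ndarray:
    """Direct double-sum zero-normalized cross-correlation over valid shifts.

    Reference implementation: for each shift the patch and the overlapped
    window are mean-centered and correlated, normalized by the product of
    their energies. Quadratic cost; used as the oracle for the fast path.
    """
    frame = np.asarray(frame, dtype=np.float64)
    patch = np.asarray(patch, dtype=np.float64)
    kh, kw = patch.shape
    H, W = frame.shape
    pc = patch - patch.mean()
    pnorm = np.sqrt((pc**2).sum())
    out = np.zeros((H - kh + 1, W - kw + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            win = frame[r : r + kh, c : c + kw]
            wc = win - win.mean()
            denom = pnorm * np.sqrt((wc**2).sum())
            out[r, c] = 0.0 if denom == 0 else float((wc * pc).sum() / denom)
    return out


def correlate(
    frame: np.ndarray, patch: ReferencePatch, pad: int = 0
) -> tuple[CorrelationMap, OffsetVector]:
    """Locate the reference patch in a frame by normalized cross-correlation.

    The offset is the argmax location minus the patch's reference position;
    ties break toward the smallest offset magnitude, then row-major order.

    ``pad`` extends the search beyond the frame border by edge replication,
    so a region that has partially drifted out of view can still be located
    instead of the estimate clamping at the last fully-visible shift.
    """
    frame = np.asarray(frame, dtype=np.float64)
    pix = patch.pixels
    if pix.shape[0] > frame.shape[0] or pix.shape[1] > frame.shape[1]:
        raise ValueError("patch larger than frame")
    if pix.std() == 0:
        raise ValueError("zero-variance patch: correlation undefined")
    search = np.pad(frame, pad, mode="edge") if pad > 0 else frame
    G = match_template(search, pix)  # FFT-based ZNCC, top-left indexed
    gmax = G.max()
    ties = np.argwhere(np.isclose(G, gmax, rtol=0.0, atol=1e-12))
    r0, c0 = patch.origin_rc
    d = ties - np.array([r0 + pad, c0 + pad])
    order = np.lexsort((d[:, 1], d[:, 0], np.hypot(d[:, 0], d[:, 1])))
    drow, dcol = d[order[0]]
    return CorrelationMap(G=G), OffsetVector(dx=float(dcol), dy=float(drow))


def detect_keypoints(
    frame: np.ndarray,
    max_points: int = 50,
    quality: float = 0.01,
    min_distance: int = 7,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Shi-Tomasi corners: maxima of the structure tensor's minimum eigenvalue.

    Peaks above ``quality`` times the global maximum response are kept with
    non-maximum suppression at ``min_distance``; the returned ``(N, 2)``
    (row, col) array is ordered by response, ties broken row-major, so
    repeated calls are identical.

    ``smooth_sigma`` optionally blurs the frame first. For registration this
    should be set near the vessel radius: it suppresses the fine moving blood
    texture inside the lumen so corners land on the vascular geometry (branch
    nodes and bends), which moves with the eye rather than with the blood.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if smooth_sigma > 0:
        frame = ndimage.gaussian_filter(frame, sigma=smooth_sigma, mode="nearest")
    response = corner_shi_tomasi(frame)
    # the structure tensor is unreliable in a border band and its artifacts
    # would otherwise dominate the relative quality threshold
    band = max(int(min_distance), 5)
    response[:band] = response[-band:] = 0.0
    response[:, :band] = response[:, -band:] = 0.0
    if response.max() <= 0:
        return np.empty((0, 2), dtype=np.float64)
    peaks = peak_local_max(
        response,
        min_distance=int(min_distance),
        threshold_rel=float(quality),
        exclude_border=True,
    )
    if peaks.size == 0:
        return np.empty((0, 2), dtype=np.float64)
    resp = response[peaks[:, 0], peaks[:, 1]]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -resp))
    return peaks[order[:max_points]].astype(np.float64)


def _silhouette_map(frame: np.ndarray) -> np.ndarray:
    """Blurred binary silhouette of the vessel net in one frame.

    Intraluminal texture is carried by the blood, so intensity corners track
    the flow rather than the eye. The lumen is segmented coarsely (Otsu
    split, vessels as the minority class), its boundary ironed smooth by
    opening/closing so texture-driven bulges disappear, and the binary shape
    blurred so it supports subpixel differential tracking. Registration on
    this map follows the vascular geometry — branch nodes, tube ends and
    bends — which moves with the eye, never with the blood.
    """
    from skimage.filters import threshold_otsu
    from skimage.morphology import closing, disk, opening

    vals = np.asarray(frame, dtype=np.float64)
    if np.ptp(vals) < 1e-9:
        return np.zeros_like(vals)
    dark = vals < threshold_otsu(vals)
    lumen = dark if dark.mean() <= 0.5 else ~dark
    se = disk(3)
    lumen = closing(opening(lumen, se), se)
    return ndimage.gaussian_filter(lumen.astype(np.float64), 2.0)


def _geometry_corners(
    frame: np.ndarray, max_points: int = 12, min_distance: int = 7, **_unused
) -> np.ndarray:
    """Shi-Tomasi corners of the vessel silhouette (see _silhouette_map).

    Real geometry corners — tube ends, branch-node wedges, sharp bends —
    respond far more strongly than the shallow boundary undulations the
    advected blood texture imprints on the silhouette, but how much more
    varies per scene. The corner list is therefore cut at the largest ratio
    gap in the sorted response spectrum instead of at a fixed quality
    threshold, keeping exactly the strong-geometry cluster.
    """
    from skimage.feature import peak_local_max

    smap = _silhouette_map(frame)
    response = corner_shi_tomasi(smap)
    band = max(int(min_distance), 5)
    response[:band] = response[-band:] = 0.0
    response[:, :band] = response[:, -band:] = 0.0
    if response.max() <= 0:
        return np.empty((0, 2))
    peaks = peak_local_max(
        response, min_distance=int(min_distance), threshold_rel=0.01, exclude_border=True
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    resp = response[peaks[:, 0], peaks[:, 1]]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -resp))
    peaks, resp = peaks[order], resp[order]
    peaks, resp = peaks[:max_points], resp[:max_points]
    if len(peaks) > 2:
        ratios = resp[1:-1] / np.maximum(resp[2:], 1e-12)  # cut after >= 2 points
        k = int(np.argmax(ratios)) + 2
        peaks = peaks[:k]
    return peaks.astype(np.float64)


def _registration_frame(frame: np.ndarray, margin: int = 1) -> np.ndarray:
    """Texture-suppressed copy of a frame for differential tracking.

    The lumen interior (coarse Otsu minority class, eroded by ``margin``) is
    flattened to the mean lumen intensity: the vessel boundary contrast that
    carries the eye motion survives, while the advected blood speckle that
    would bias the tracked displacements is erased.
    """
    from skimage.filters import threshold_otsu
    from skimage.morphology import disk, erosion

    fs = ndimage.gaussian_filter(np.asarray(frame, dtype=np.float64), 1.5, mode="nearest")
    if np.ptp(fs) < 1e-9:
        return fs
    dark = fs < threshold_otsu(fs)
    lumen = dark if dark.mean() <= 0.5 else ~dark
    inner = erosion(lumen, disk(margin))
    out = fs.copy()
    if inner.any():
        out[inner] = fs[lumen].mean()
    return ndimage.gaussian_filter(out, 1.5, mode="nearest")


def _pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [frame]
    for _ in range(levels - 1):
        prev = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(prev[::2, ::2])
    return pyr


def _sample_window(img: np.ndarray, center_rc: np.ndarray, half: int) -> np.ndarray:
    """Bilinear (half*2+3)^2 window around a subpixel center; the extra ring
    supports central-difference gradients."""
    span = np.arange(-half - 1, half + 2, dtype=np.float64)
    rows = center_rc[0] + span
    cols = center_rc[1] + span
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, [rr, cc], order=1, mode="nearest")


def track_keypoints(
    frame1: np.ndarray,
    frame2: np.ndarray,
    points: np.ndarray,
    window: int = 15,
    levels: int = 3,
    max_iter: int = 15,
    eps: float = 0.01,
    min_eig: float = 1e-4,
    init: np.ndarray | None = None,
) -> KeypointTrack:
    """Pyramidal Lucas–Kanade tracking of sparse points from frame1 to frame2.

    Per point the 2x2 structure-tensor system (sums of ``fx^2``, ``fx fy``,
    ``fy^2`` against ``-fx ft``, ``-fy ft`` over the window) is solved and
    refined iteratively, coarse-to-fine over a Gaussian image pyramid so
    larger motions stay within the linearization range. Points whose tensor
    is ill-conditioned, that exit the frame, or whose update diverges are
    flagged lost rather than raised.

    ``init`` optionally supplies per-point initial displacement guesses
    (``(N, 2)`` as (drow, dcol)), e.g. the offset recovered for the previous
    frame, letting the tracker resolve only the residual motion.
    """
    frame1 = np.asarray(frame1, dtype=np.float64)
    frame2 = np.asarray(frame2, dtype=np.float64)
    if frame1.shape != frame2.shape:
        raise ValueError("frames must share a shape")
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if init is None:
        init = np.zeros_like(points)
    init = np.asarray(init, dtype=np.float64).reshape(points.shape)
    half = window // 2
    pyr1 = _pyramid(frame1, levels)
    pyr2 = _pyramid(frame2, levels)

    out = np.empty_like(points)
    status = np.ones(len(points), dtype=bool)
    H, W = frame1.shape

    for k, p in enumerate(points):
        # init carried to the coarsest level, then refined coarse-to-fine
        g = init[k] / (2.0 ** (levels - 1))
        lost = False
        for lvl in range(levels - 1, -1, -1):
            img1, img2 = pyr1[lvl], pyr2[lvl]
            p_l = p / (2.0**lvl)
            win1 = _sample_window(img1, p_l, half)
            ix = (win1[1:-1, 2:] - win1[1:-1, :-2]) / 2.0
            iy = (win1[2:, 1:-1] - win1[:-2, 1:-1]) / 2.0
            t1 = win1[1:-1, 1:-1]
            gxx = (ix * ix).sum()
            gxy = (ix * iy).sum()
            gyy = (iy * iy).sum()
            trace = gxx + gyy
            det = gxx * gyy - gxy * gxy
            lam_min = trace / 2.0 - np.sqrt(max(trace * trace / 4.0 - det, 0.0))
            n_px = t1.size
            if lam_min / n_px < min_eig * max(float(np.ptp(img1)) ** 2, 1e-12):
                lost = True
                break
            nu = np.zeros(2)
            for _ in range(max_iter):
                q = p_l + g + nu
                if not (0 <= q[0] < img1.shape[0] and 0 <= q[1] < img1.shape[1]):
                    lost = True
                    break
                win2 = _sample_window(img2, q, half)
                dt = t1 - win2[1:-1, 1:-1]
                bx = (ix * dt).sum()
                by = (iy * dt).sum()
                delta_c = (gyy * bx - gxy * by) / det
                delta_r = (gxx * by - gxy * bx) / det
                nu += (delta_r, delta_c)
                if np.hypot(delta_r, delta_c) < eps:
                    break
            if lost or np.hypot(*nu) > window:
                lost = True
                break
            g = 2.0 * (g + nu) if lvl > 0 else g + nu
        if lost:
            out[k] = p
            status[k] = False
            continue
        q = p + g
        if not (0 <= q[0] < H and 0 <= q[1] < W):
            status[k] = False
            out[k] = p
        else:
            out[k] = q
    return KeypointTrack(points1=points, points2=out, status=status)


def matching_rate(Kp1: int, Kp2: int, M: int) -> float:
    """Symmetric key-point matching rate in percent: ``M * 200 / (Kp1 + Kp2)``."""
    if Kp1 + Kp2 <= 0:
        raise ValueError("matching rate undefined for zero detected points")
    return M * 200.0 / (Kp1 + Kp2)


def frame_offset(track: KeypointTrack) -> OffsetVector:
    """Frame offset as the component-wise median of tracked displacements.

    The median corresponds to the dominant (camera) shift and is robust to a
    minority of points moving with the blood rather than the eye. For even
    counts the mean of the two middle values is used.
    """
    disp = track.displacements
    if disp.shape[0] == 0:
        raise ValueError("no tracked point: offset undefined")
    med = np.median(disp, axis=0)
    return OffsetVector(dx=float(med[1]), dy=float(med[0]))


class _SilhouetteVerifier:
    """Scores a candidate frame offset by silhouette alignment at the
    geometry corners.

    Some tracked corners may sit on silhouette undulations that advect with
    the blood; their displacement cluster and the camera cluster are locally
    indistinguishable. The decisive evidence lives at the vessel net's
    tips, branch wedges and bends: only the camera offset aligns those
    frame-0 neighborhoods with frame ``t``. The score sums the normalized
    correlations of silhouette windows around each geometry corner, sampled
    at the candidate shift.
    """

    def __init__(self, sil: np.ndarray, corners: np.ndarray, half: int = 10):
        self.sil = sil
        H, W = sil[0].shape
        span = np.arange(-half, half + 1, dtype=np.float64)
        self.windows = []
        for r, c in np.atleast_2d(corners).reshape(-1, 2):
            rr, cc = np.meshgrid(r + span, c + span, indexing="ij")
            ref = ndimage.map_coordinates(sil[0], [rr, cc], order=1, mode="nearest")
            ref = ref - ref.mean()
            norm = float(np.sqrt((ref**2).sum()))
            if norm > 1e-9:
                self.windows.append((rr, cc, ref, norm))

    def score(self, t: int, shift_rc: np.ndarray) -> float:
        total = 0.0
        for rr, cc, ref, norm in self.windows:
            win = ndimage.map_coordinates(
                self.sil[t], [rr + shift_rc[0], cc + shift_rc[1]], order=1, mode="nearest"
            )
            win = win - win.mean()
            denom = norm * np.sqrt((win**2).sum())
            if denom > 1e-12:
                total += float((ref * win).sum() / denom)
        return total


def _verified_offset(
    track: KeypointTrack,
    verifier: _SilhouetteVerifier,
    t: int,
    extra_candidates: Sequence[np.ndarray] = (),
    radius: float = 1.5,
) -> OffsetVector:
    """Median displacement over the silhouette-verified inlier cluster.

    Candidate offsets are the per-point tracked displacements, their median,
    and any ``extra_candidates`` (e.g. the patch-correlation estimate); the
    one aligning the vessel silhouette best wins, and the returned offset is
    the median of the tracked displacements within ``radius`` of it — or the
    winning candidate itself when no tracked point supports it.
    """
    disp = track.displacements  # (M, 2) (drow, dcol)
    candidates = [np.median(disp, axis=0)] + list(disp) + list(extra_candidates)
    scores = [verifier.score(t, c) for c in candidates]
    best = candidates[int(np.argmax(scores))]
    inliers = disp[np.linalg.norm(disp - best, axis=1) <= radius]
    med = np.median(inliers, axis=0) if len(inliers) else np.asarray(best, float)
    return OffsetVector(dx=float(med[1]), dy=float(med[0]))


def _cross_validate_offsets(
    offsets: list[OffsetVector],
    fragment_video: VideoSequence,
    patch: ReferencePatch,
    verifier: "_SilhouetteVerifier",
    agree_px: float = 1.5,
) -> list[OffsetVector]:
    """Cross-validate keypoint offsets against the patch-correlation series.

    When both series agree, the correlation one is adopted (it is the
    cleaner subpixel estimate and immune to isolated corner mistracks).
    When they disagree — which happens when the advected blood texture has
    captured the intensity correlation on a texture-dominated scene, or a
    corner track has gone wrong — the series whose offsets align the vessel
    silhouette better at the geometry corners, summed over all frames, is
    the one still locked to the eye.
    """
    n = len(offsets)
    if n < 4 or not verifier.windows:
        return offsets
    kp = np.array([[o.dy, o.dx] for o in offsets])
    corr = np.zeros_like(kp)
    corr_offsets = [OffsetVector(0.0, 0.0)]
    pad = min(patch.pixels.shape) // 3
    for t in range(1, n):
        _, c = correlate(fragment_video[t], patch, pad=pad)
        corr[t] = (c.dy, c.dx)
        corr_offsets.append(c)
    med_diff = float(np.median(np.hypot(*(kp - corr).T)))
    if med_diff <= agree_px:
        return corr_offsets
    score_kp = sum(verifier.score(t, kp[t]) for t in range(1, n))
    score_corr = sum(verifier.score(t, corr[t]) for t in range(1, n))
    return offsets if score_kp > score_corr else corr_offsets


def _valid_region(
    shape: tuple[int, int], shifts: np.ndarray
) -> tuple[int, int, int, int]:
    """(r0, r1, c0, c1) of the region covered by every shifted frame."""
    H, W = shape
    r0 = int(max(0, shifts[:, 0].max()))
    r1 = int(H + min(0, shifts[:, 0].min()))
    c0 = int(max(0, shifts[:, 1].max()))
    c1 = int(W + min(0, shifts[:, 1].min()))
    if r1 - r0 < 1 or c1 - c0 < 1:
        raise ValueError("stabilization failed: no common valid region")
    return r0, r1, c0, c1


def stabilize(
    fragment_video: VideoSequence,
    method: Literal["keypoint", "correlation"] = "keypoint",
    roi: ROIBox | None = None,
    min_tracked: int = 2,
    keypoint_kwargs: dict | None = None,
) -> tuple[VideoSequence, list[OffsetVector]]:
    """Register a fragment to frame 0 and crop to the common valid region.

    Offsets are content displacements relative to frame 0. The correlation
    method matches the central 50% of the first frame's ROI in every frame.
    The keypoint method detects Shi-Tomasi corners of the frame-0 vessel
    silhouette and tracks them with pyramidal Lucas–Kanade into every frame
    (anchored to frame 0 and warm-started from the previous offset, so
    errors cannot accumulate); the frame offset is the median tracked
    displacement, with correlation as fallback when fewer than
    ``min_tracked`` corners survive. Frames are resampled by integer shifts,
    so no output pixel is interpolated or undefined.
    """
    if len(fragment_video) < 2:
        raise ValueError("stabilization needs at least 2 frames")
    kp_kwargs = dict(keypoint_kwargs or {})
    if roi is None:
        roi, _ = roi_from_frame(fragment_video[0])
    if roi is None:  # featureless first frame: treat whole frame as ROI
        h, w = fragment_video.frame_shape
        roi = ROIBox(x0=0, y0=0, width=w, height=h)
    patch = reference_patch(fragment_video, roi)

    n = len(fragment_video)
    offsets = [OffsetVector(0.0, 0.0)]
    search_pad = min(patch.pixels.shape) // 3
    if method == "correlation":
        for t in range(1, n):
            _, off = correlate(fragment_video[t], patch, pad=search_pad)
            offsets.append(off)
    elif method == "keypoint":
        # corners come from the vessel silhouette (branch nodes, tube ends,
        # bends — landmarks that move with the eye); tracking runs on
        # texture-suppressed frames so the blood speckle cannot bias the
        # displacements
        reg = np.stack([_registration_frame(f) for f in fragment_video])
        sil = np.stack([_silhouette_map(f) for f in fragment_video])
        pts = _geometry_corners(reg[0], **kp_kwargs)
        verifier = _SilhouetteVerifier(sil, pts)
        # anchor every frame to frame 0: tracking against the reference frame
        # (warm-started from the previous offset) cannot accumulate drift the
        # way chained frame-to-frame steps would
        disp = np.zeros_like(pts) if len(pts) else np.zeros((0, 2))
        for t in range(1, n):
            step: OffsetVector | None = None
            tracked_mask = None
            if len(pts) >= min_tracked:
                track = track_keypoints(reg[0], reg[t], pts, init=disp)
                if int(track.status.sum()) >= min_tracked:
                    step = _verified_offset(track, verifier, t)
                    tracked_mask = track.status
                    disp = np.where(track.status[:, None], track.points2 - track.points1, disp)
            if step is None:  # too few trackable corners: absolute correlation
                _, step = correlate(fragment_video[t], patch, pad=search_pad)
            elif len(pts):
                # re-seed lost points at the tracking consensus so they can
                # re-lock once their structure comes back into view (a
                # correlation-fallback consensus is not used for seeding:
                # on texture-dominated scenes it may follow the blood)
                disp[~tracked_mask] = np.array([step.dy, step.dx])
            offsets.append(step)
        offsets = _cross_validate_offsets(offsets, fragment_video, patch, verifier)
    else:
        raise ValueError(f"unknown stabilization method {method!r}")

    # shift each frame back by its offset (integer resampling)
    shifts = np.array([[-round(o.dy), -round(o.dx)] for o in offsets], dtype=int)
    H, W = fragment_video.frame_shape
    shifted = np.zeros((n, H, W))
    for t, (sr, sc) in enumerate(shifts):
        src = fragment_video[t]
        r_src0, r_src1 = max(0, -sr), min(H, H - sr)
        c_src0, c_src1 = max(0, -sc), min(W, W - sc)
        shifted[t, r_src0 + sr : r_src1 + sr, c_src0 + sc : c_src1 + sc] = src[
            r_src0:r_src1, c_src0:c_src1
        ]
    r0, r1, c0, c1 = _valid_region((H, W), shifts)
    out = shifted[:, r0:r1, c0:c1]
    return fragment_video.with_frames(out), offsets
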