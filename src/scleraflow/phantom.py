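"""Synthetic vessel-video phantoms with full ground truth.

The generator emulates the acquisition defects of hand-held scleral video —
inter-frame translation jitter including large jumps, per-frame sharpness
loss, slow illumination drift — over a branching vessel tree whose lumen
carries advected speckle texture at known per-segment speeds. Every rendered
video comes with its ground truth (true camera offsets, binary vessel mask,
centerline polylines, per-segment speeds), so each pipeline stage can be
tested without clinical data.

Geometry is row/col, origin top-left, 0-based. Vessels are darker than the
background by default (fundus-style polarity); the polarity is configurable.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .video import VideoSequence

__all__ = [
    "Segment",
    "PhantomScene",
    "MotionSpec",
    "GroundTruth",
    "make_vessel_tree",
    "scene_from_polylines",
    "assign_speeds",
    "render_video",
    "write_phantom",
]

WIDTH_MIN = 2.0
WIDTH_MAX = 12.0


@dataclasses.dataclass(frozen=True)
class Segment:
    """One tube of the vessel tree: a subpixel polyline plus its width.

    The width tapers linearly from ``width_start`` at the first point to
    ``width_end`` at the last, so widths vary smoothly along the tree.
    """

    points: np.ndarray  # (N, 2) float (row, col)
    width_start: float
    width_end: float
    parent: int = -1  # index of parent segment, -1 for the root

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("segment polyline must be (N>=2, 2)")
        if min(self.width_start, self.width_end) <= 0:
            raise ValueError("segment widths must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def mean_width(self) -> float:
        return 0.5 * (self.width_start + self.width_end)


@dataclasses.dataclass(frozen=True)
class PhantomScene:
    """A static vessel scene: tube tree, canvas and photometry."""

    segments: tuple[Segment, ...]
    canvas_size: tuple[int, int]  # (height, width)
    background_level: float = 0.75
    vessel_contrast: float = 0.45
    # weak static texture of the surrounding tissue (episcleral structure);
    # it moves with the eye, so trackers anchor on it as they do on real
    # scleral video, where the background is never optically flat
    background_texture: float = 0.04
    vessels_dark: bool = True
    junctions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        h, w = self.canvas_size
        if not (0.0 <= self.background_level <= 1.0 and 0.0 <= self.vessel_contrast <= 1.0):
            raise ValueError("photometric levels must lie in [0, 1]")
        for seg in self.segments:
            pts = seg.points
            if pts[:, 0].min() < 0 or pts[:, 1].min() < 0 or pts[:, 0].max() >= h or pts[:, 1].max() >= w:
                raise ValueError("segment polyline leaves the canvas")


@dataclasses.dataclass(frozen=True)
class MotionSpec:
    """Acquisition-defect model for one rendered video.

    ``jitter_sd`` is the per-frame standard deviation of the camera's random
    translation step (pixels). Frames listed in ``jump_frames`` instead move
    by ``jump_magnitude`` pixels in a random direction — deliberately beyond
    the fragmenter's drift limit. ``blur_sd_range`` draws a per-frame Gaussian
    blur sigma; ``illumination_drift_amplitude`` is the amplitude of a slow
    sinusoidal brightness drift as a fraction of the dynamic range. ``seed``
    fixes the entire realization.
    """

    jitter_sd: float = 0.0
    jump_frames: frozenset[int] = frozenset()
    jump_magnitude: float = 120.0
    blur_sd_range: tuple[float, float] = (0.0, 0.0)
    illumination_drift_amplitude: float = 0.0
    seed: int = 0
    subpixel: bool = False

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        object.__setattr__(self, "jump_frames", frozenset(self.jump_frames))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Everything the pipeline is later asked to recover.

    ``offsets[t] = (dx, dy)`` is the true displacement of frame ``t``'s
    content relative to scene coordinates (frame 0 has offset (0, 0) unless it
    jitters); ``mask`` and ``centerline`` describe the vessels at zero offset;
    ``speeds`` are the per-segment advection speeds in px/frame.
    """

    offsets: np.ndarray  # (n_frames, 2) float, columns (dx, dy)
    mask: np.ndarray  # (H, W) bool
    centerline: tuple[np.ndarray, ...]  # per segment, (M, 2) float (row, col)
    speeds: np.ndarray  # (n_segments,) float px/frame
    junctions: tuple[tuple[float, float], ...] = ()


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length spacing.

    Returns (samples (M,2), arc lengths (M,), unit tangents (M,2)).
    """
    pts = np.asarray(points, dtype=np.float64)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline")
    n = max(2, int(math.ceil(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    rows = np.interp(si, s, pts[:, 0])
    cols = np.interp(si, s, pts[:, 1])
    samples = np.column_stack([rows, cols])
    tang = np.gradient(samples, si, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.maximum(norm, 1e-12)
    return samples, si, tang


def _grow_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length: float,
    canvas: tuple[int, int],
    margin: float,
    step: float = 2.0,
    wiggle: float = 0.06,
    avoid: np.ndarray | None = None,
    clearance: float = 0.0,
    ignore_radius: float = 0.0,
    self_clearance: float = 0.0,
) -> np.ndarray:
    """Random smooth curve: constant step, small heading increments, steered
    back toward the canvas interior near the margin.

    ``avoid`` supplies sample points of already-placed tubes: candidate steps
    closer than ``clearance`` to them (outside ``ignore_radius`` of the start,
    so a child may leave its own junction) are rejected and the heading turned
    away; if no turn escapes, growth stops early. This keeps the tree free of
    undeclared crossings.
    """
    h, w = canvas
    center = np.array([h / 2.0, w / 2.0])
    tree = cKDTree(avoid) if avoid is not None and len(avoid) else None
    pts = [start.astype(np.float64)]
    theta = heading
    max_turn = 1.7  # rad: a branch may bend but not hairpin back on itself
    n_steps = max(2, int(round(length / step)))
    for _ in range(n_steps):
        p = pts[-1]
        near_edge = (
            p[0] < margin or p[0] > h - 1 - margin or p[1] < margin or p[1] > w - 1 - margin
        )
        if near_edge:
            to_center = math.atan2(center[0] - p[0], center[1] - p[1])
            # steer smoothly toward the interior; the turn rate stays below
            # the tube curvature that would make its boundary self-intersect
            dtheta = (to_center - theta + math.pi) % (2 * math.pi) - math.pi
            theta += np.clip(dtheta, -0.2, 0.2)
        theta += rng.normal(0.0, wiggle)
        dev = (theta - heading + math.pi) % (2 * math.pi) - math.pi
        theta = heading + np.clip(dev, -max_turn, max_turn)

        lookback = int(self_clearance / step) + 4
        placed = False
        for turn in (0.0, 0.15, -0.15, 0.3, -0.3):
            cand_theta = theta + turn
            nxt = p + step * np.array([math.sin(cand_theta), math.cos(cand_theta)])
            nxt[0] = np.clip(nxt[0], 1.0, h - 2.0)
            nxt[1] = np.clip(nxt[1], 1.0, w - 2.0)
            if tree is not None and np.linalg.norm(nxt - start) > ignore_radius:
                if tree.query(nxt)[0] < clearance:
                    continue
            if self_clearance > 0 and len(pts) > lookback:
                own = np.asarray(pts[:-lookback])
                if np.min(np.linalg.norm(own - nxt, axis=1)) < self_clearance:
                    continue
            theta = cand_theta
            pts.append(nxt)
            placed = True
            break
        if not placed:
            break  # boxed in: stop rather than cross another tube
    return np.asarray(pts)


def _segment_width_at(seg: Segment, samples: np.ndarray, s: np.ndarray) -> np.ndarray:
    frac = s / max(s[-1], 1e-9)
    return seg.width_start + (seg.width_end - seg.width_start) * frac


def _scene_is_valid(scene: PhantomScene, min_segment_len: float = 14.0) -> bool:
    """Check the tree invariant: tubes meet only at their declared junctions.

    Rejects stub segments the skeleton could not resolve, tube pairs closer
    than the sum of their half-widths away from a shared junction, and
    segments whose own path comes back onto itself.
    """
    segs = scene.segments
    sampled = []
    for seg in segs:
        if seg.length < min_segment_len:
            return False
        chord = float(np.linalg.norm(seg.points[-1] - seg.points[0]))
        if chord < 0.6 * seg.length:
            return False  # hairpin: its legs could enclose a background pocket
        samples, s, _ = _resample_polyline(seg.points, step=1.0)
        sampled.append((samples, s, _segment_width_at(seg, samples, s)))

    junctions = np.asarray(scene.junctions, dtype=float).reshape(-1, 2)

    def junction_arc_dist(seg_idx: int) -> np.ndarray:
        """Per-sample arc distance to the nearest junction lying on one of
        this segment's endpoints (inf if the segment touches no junction)."""
        samples, s, _w = sampled[seg_idx]
        out = np.full(len(samples), np.inf)
        for J in junctions:
            if np.linalg.norm(samples[0] - J) < 1.5:
                out = np.minimum(out, s)
            if np.linalg.norm(samples[-1] - J) < 1.5:
                out = np.minimum(out, s[-1] - s)
        return out

    arc_to_junction = [junction_arc_dist(i) for i in range(len(segs))]

    for i in range(len(segs)):
        pts_i, s_i, w_i = sampled[i]
        # self-contact: distant-in-arc samples must stay apart in the plane
        look = int(3 * segs[i].mean_width) + 6
        if len(pts_i) > 2 * look:
            tree_i = cKDTree(pts_i)
            for k in range(look, len(pts_i)):
                d, idx = tree_i.query(pts_i[k], k=len(pts_i))
                close = d < segs[i].mean_width + 1.0
                if np.any(np.abs(idx[close] - k) > look):
                    return False
        for j in range(i + 1, len(segs)):
            pts_j, s_j, w_j = sampled[j]
            tree = cKDTree(pts_i)
            d, idx = tree.query(pts_j)
            # +2.5 px margin: rasterized boundaries 1 px apart can still end
            # up 8-connected after thinning
            need = (w_i[idx] + w_j) / 2.0 + 2.5
            bad = np.flatnonzero(d < need)
            if bad.size:
                # a contact is legitimate only right at a shared junction:
                # both touching samples must sit within the junction's
                # footprint along their own arcs
                exempt_arc = (segs[i].mean_width + segs[j].mean_width) / 2.0 + 4.0
                ok = (arc_to_junction[j][bad] < exempt_arc) & (
                    arc_to_junction[i][idx[bad]] < exempt_arc
                )
                if not ok.all():
                    return False
    return True


def make_vessel_tree(
    n_branches: int,
    seed: int,
    canvas: tuple[int, int] = (192, 256),
    root_width: float | None = None,
) -> PhantomScene:
    """Generate a connected binary tree of tube segments.

    ``n_branches`` counts the terminal tips of the tree: 1 gives a single
    unbranched tube, 2 a single bifurcation (one junction), and each further
    tip adds one junction. Child widths shrink by a fixed factor so widths lie
    in the 2–12 px range; the realization is fully determined by ``seed``.
    The grown tree is validated against its own invariant (tubes meet only at
    declared junctions, no stubs); invalid draws are regenerated from a seed
    derived deterministically from ``seed``.
    """
    for attempt in range(40):
        scene = _make_vessel_tree_once(n_branches, np.random.default_rng([seed, attempt]), canvas, root_width)
        if _scene_is_valid(scene):
            return scene
    raise RuntimeError(
        f"could not realize a clean {n_branches}-branch tree on canvas {canvas}"
    )


def _make_vessel_tree_once(
    n_branches: int,
    rng: np.random.Generator,
    canvas: tuple[int, int],
    root_width: float | None,
) -> PhantomScene:
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    h, w = canvas
    if h < 64 or w < 64:
        raise ValueError("canvas must be at least 64x64")
    if n_branches > min(h, w) // 32:
        raise ValueError(
            f"canvas {canvas} too small for {n_branches} branches "
            f"(supports up to {min(h, w) // 32})"
        )
    if root_width is None:
        root_width = float(rng.uniform(8.0, 11.0))
    root_width = float(np.clip(root_width, WIDTH_MIN, WIDTH_MAX))
    margin = root_width / 2 + 3.0

    start = np.array([h / 2.0 + rng.uniform(-h / 8, h / 8), margin + 1.0])
    main_len = 0.55 * w
    root_pts = _grow_polyline(
        rng, start, heading=0.0, length=main_len, canvas=canvas, margin=margin,
        self_clearance=root_width + 3.0,
    )
    taper = 0.93
    segments: list[Segment] = [Segment(root_pts, root_width, root_width * taper, parent=-1)]
    junctions: list[tuple[float, float]] = []
    leaves = [0]  # indices of segments that may still bifurcate

    while len(leaves) < n_branches:
        # split the widest remaining leaf for a balanced-looking tree
        leaves.sort(key=lambda i: -segments[i].mean_width)
        parent_idx = leaves.pop(0)
        parent = segments[parent_idx]
        tip = parent.points[-1]
        tang = parent.points[-1] - parent.points[-2]
        heading = math.atan2(tang[0], tang[1])
        junctions.append((float(tip[0]), float(tip[1])))
        w_child = max(WIDTH_MIN, parent.width_end * 0.75)
        child_len = max(30.0, 0.6 * parent.length)
        for sign in (+1.0, -1.0):
            occupied = np.vstack(
                [_resample_polyline(s.points, step=1.0)[0] for s in segments]
            )
            # the junction neighborhood itself must not repel the child,
            # or it could never leave its parent's end cap
            clearance = max(w_child + 3.0, (w_child + root_width) / 2.0 + 2.0)
            occupied = occupied[np.linalg.norm(occupied - tip, axis=1) > clearance + 1.0]
            # a truncated child (boxed in by existing tubes) would be a stub
            # the skeleton cannot resolve: redraw its angle a few times and
            # keep the longest realization
            best_pts: np.ndarray | None = None
            for _attempt in range(5):
                ang = heading + sign * rng.uniform(0.45, 0.7)
                pts = _grow_polyline(
                    rng,
                    tip.copy(),
                    heading=ang,
                    length=child_len,
                    canvas=canvas,
                    margin=margin,
                    avoid=occupied,
                    clearance=clearance,
                    ignore_radius=4.0,
                    self_clearance=w_child + 3.0,
                )
                if best_pts is None or len(pts) > len(best_pts):
                    best_pts = pts
                if len(best_pts) >= max(11, int(0.5 * child_len / 2.0)):
                    break
            pts = best_pts
            if len(pts) < 2:  # boxed in immediately: leave a short stub
                direction = np.array([math.sin(ang), math.cos(ang)])
                pts = np.vstack([tip, np.clip(tip + 6.0 * direction, 1.0, np.array(canvas) - 2.0)])
            segments.append(Segment(pts, w_child, w_child * taper, parent=parent_idx))
            leaves.append(len(segments) - 1)

    return PhantomScene(
        segments=tuple(segments),
        canvas_size=(h, w),
        junctions=tuple(junctions),
    )


def scene_from_polylines(
    polylines: Sequence[np.ndarray],
    widths: Sequence[float] | float,
    canvas: tuple[int, int],
    parents: Sequence[int] | None = None,
    junctions: Sequence[tuple[float, float]] = (),
    **photometry,
) -> PhantomScene:
    """Build a scene from explicit polylines (straight tubes, arcs, Y shapes)."""
    if np.isscalar(widths):
        widths = [float(widths)] * len(polylines)
    if parents is None:
        parents = [-1] * len(polylines)
    segs = tuple(
        Segment(np.asarray(p, dtype=float), float(wd), float(wd), parent=par)
        for p, wd, par in zip(polylines, widths, parents)
    )
    return PhantomScene(
        segments=segs,
        canvas_size=tuple(canvas),
        junctions=tuple(junctions),
        **photometry,
    )


def assign_speeds(
    scene: PhantomScene, v_root: float = 2.0, conserve_flow: bool = True
) -> np.ndarray:
    """Per-segment advection speeds (px/frame), root first.

    With ``conserve_flow`` the volumetric rate ``Q = v * S`` (circular cross
    section, ``S = pi (w/2)^2`` from the segment's mean width) is conserved at
    every bifurcation: each child receives the parent's Q split in proportion
    to its own cross-section, so ``sum(Q_children) == Q_parent`` exactly.
    Without it every segment simply advects at ``v_root``.
    """
    n = len(scene.segments)
    speeds = np.full(n, float(v_root))
    if not conserve_flow:
        return speeds
    areas = np.array([math.pi * (s.mean_width / 2) ** 2 for s in scene.segments])
    children: dict[int, list[int]] = {}
    for i, seg in enumerate(scene.segments):
        if seg.parent >= 0:
            children.setdefault(seg.parent, []).append(i)
    # breadth-first from roots
    order = [i for i, s in enumerate(scene.segments) if s.parent == -1]
    queue = list(order)
    while queue:
        p = queue.pop(0)
        kids = children.get(p, [])
        if not kids:
            continue
        q_parent = speeds[p] * areas[p]
        s_kids = areas[kids].sum()
        for k in kids:
            speeds[k] = q_parent / s_kids
            queue.append(k)
    return speeds


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _generate_offsets(motion: MotionSpec, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative camera offsets, (n, 2) as (dy, dx) in scene axes."""
    steps = np.zeros((n_frames, 2))
    for t in range(1, n_frames):
        if t in motion.jump_frames:
            ang = rng.uniform(0, 2 * math.pi)
            steps[t] = motion.jump_magnitude * np.array([math.sin(ang), math.cos(ang)])
        elif motion.jitter_sd > 0:
            steps[t] = rng.normal(0.0, motion.jitter_sd, size=2)
    offsets = np.cumsum(steps, axis=0)
    if not motion.subpixel:
        offsets = np.round(offsets)
        # rounding must not pull a jump back under the drift limit
        for t in sorted(motion.jump_frames):
            if 0 < t < n_frames:
                d = offsets[t] - offsets[t - 1]
                mag = np.hypot(*d)
                if mag < motion.jump_magnitude:
                    offsets[t:] += np.round(d / max(mag, 1e-9) * 3.0)
    return offsets


@dataclasses.dataclass
class _SceneMaps:
    """Per-pixel tube lookup on a padded scene grid."""

    seg_id: np.ndarray  # int, -1 outside any tube
    s_idx: np.ndarray  # int index into the texture's arc-length axis
    r_idx: np.ndarray  # int index into the texture's radial axis
    alpha: np.ndarray  # float coverage in [0, 1]
    pad: int


def _build_scene_maps(scene: PhantomScene, pad: int, n_radial: int) -> _SceneMaps:
    h, w = scene.canvas_size
    hp, wp = h + 2 * pad, w + 2 * pad
    rr, cc = np.mgrid[0:hp, 0:wp]
    pix = np.column_stack([rr.ravel() - pad, cc.ravel() - pad]).astype(np.float64)

    seg_id = np.full(hp * wp, -1, dtype=np.int32)
    s_idx = np.zeros(hp * wp, dtype=np.int32)
    r_idx = np.zeros(hp * wp, dtype=np.int32)
    alpha = np.zeros(hp * wp)

    for i, seg in enumerate(scene.segments):
        samples, s, tang = _resample_polyline(seg.points, step=0.5)
        tree = cKDTree(samples)
        wmax = max(seg.width_start, seg.width_end)
        dist, idx = tree.query(pix, distance_upper_bound=wmax / 2 + 2.0)
        hit = np.isfinite(dist)
        if not hit.any():
            continue
        idx_h = idx[hit]
        near = samples[idx_h]
        diff = pix[hit] - near
        t_h = tang[idx_h]
        # signed radial coordinate: cross(tangent, offset)
        r_signed = t_h[:, 1] * diff[:, 0] - t_h[:, 0] * diff[:, 1]
        frac = s[idx_h] / max(seg.length, 1e-9)
        half_w = 0.5 * (seg.width_start + (seg.width_end - seg.width_start) * frac)
        a = np.clip(half_w - np.abs(r_signed) + 0.5, 0.0, 1.0)
        sel_local = a > alpha[hit]  # pixel adopts the tube covering it best
        target = np.flatnonzero(hit)[sel_local]
        alpha[target] = a[sel_local]
        seg_id[target] = i
        s_idx[target] = np.round(s[idx_h][sel_local] / 1.0).astype(np.int32)
        r_idx[target] = np.clip(
            np.round(r_signed[sel_local] + n_radial / 2).astype(np.int32), 0, n_radial - 1
        )

    shape = (hp, wp)
    return _SceneMaps(
        seg_id=seg_id.reshape(shape),
        s_idx=s_idx.reshape(shape),
        r_idx=r_idx.reshape(shape),
        alpha=alpha.reshape(shape),
        pad=pad,
    )


def _segment_textures(
    scene: PhantomScene, n_radial: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Band-limited multiplicative speckle per segment, periodic along arc
    length so advection wraps cleanly. Values in [0.3, 1.0].

    The smoothed noise is normalized by its local standard deviation before
    the amplitude mapping: smooth Gaussian noise has occasional flat
    stretches, and a tube section without visible texture would carry no
    measurable motion — blood, by contrast, always carries cells.
    """
    textures = []
    for seg in scene.segments:
        n_s = max(8, int(math.ceil(seg.length)) + 1)
        noise = rng.standard_normal((n_s, n_radial))
        # wrap-pad along s before smoothing to keep the texture periodic
        sm = gaussian_filter(noise, sigma=(1.6, 1.2), mode=("wrap", "nearest"))
        local_var = gaussian_filter(sm**2, sigma=(6.0, 3.0), mode=("wrap", "nearest")) - (
            gaussian_filter(sm, sigma=(6.0, 3.0), mode=("wrap", "nearest")) ** 2
        )
        sm = sm / np.maximum(np.sqrt(np.clip(local_var, 0.0, None)), 0.2 * sm.std())
        textures.append(0.65 + 0.35 * np.tanh(sm))
    return textures


def render_video(
    scene: PhantomScene,
    motion: MotionSpec,
    speeds: Sequence[float] | np.ndarray,
    n_frames: int,
) -> tuple[VideoSequence, GroundTruth]:
    """Render the phantom video and its ground truth.

    Frames contain the tube tree filled with speckle advected at the
    prescribed per-segment speed along the centerline tangent; the whole
    content is translated per frame by the true camera offsets; per-frame blur
    and illumination drift follow the :class:`MotionSpec`. Intensities lie in
    ``[0, 1]``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    speeds = np.asarray(speeds, dtype=np.float64)
    if speeds.shape != (len(scene.segments),):
        raise ValueError("one speed per segment required")
    if (speeds < 0).any():
        raise ValueError("speeds must be >= 0")
    for seg, v in zip(scene.segments, speeds):
        if v > seg.length:
            raise ValueError(
                f"speed {v} px/frame exceeds segment length {seg.length:.1f} px: "
                "texture would alias"
            )

    rng = np.random.default_rng(motion.seed)
    offsets_yx = _generate_offsets(motion, n_frames, rng)  # (n, 2) (dy, dx)
    blur_sds = rng.uniform(*motion.blur_sd_range, size=n_frames) if max(
        motion.blur_sd_range
    ) > 0 else np.zeros(n_frames)

    n_radial = int(math.ceil(WIDTH_MAX)) + 4
    textures = _segment_textures(scene, n_radial, rng)

    pad = int(math.ceil(np.abs(offsets_yx).max())) + 2
    maps = _build_scene_maps(scene, pad, n_radial)
    h, w = scene.canvas_size

    # static tissue texture in scene coordinates, translated with the eye
    if scene.background_texture > 0:
        bg_noise = gaussian_filter(
            rng.standard_normal((h + 2 * pad, w + 2 * pad)), sigma=1.5, mode="nearest"
        )
        bg_noise *= scene.background_texture / max(bg_noise.std(), 1e-9)
    else:
        bg_noise = np.zeros((h + 2 * pad, w + 2 * pad))

    sign = -1.0 if scene.vessels_dark else 1.0
    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        dy, dx = offsets_yx[t]
        # content displaced by (dy, dx): frame(r, c) = scene(r - dy, c - dx)
        r0 = pad - int(round(dy))
        c0 = pad - int(round(dx))
        sid = maps.seg_id[r0 : r0 + h, c0 : c0 + w]
        sidx = maps.s_idx[r0 : r0 + h, c0 : c0 + w]
        ridx = maps.r_idx[r0 : r0 + h, c0 : c0 + w]
        al = maps.alpha[r0 : r0 + h, c0 : c0 + w]

        base = scene.background_level + motion.illumination_drift_amplitude * math.sin(
            2 * math.pi * t / max(n_frames, 1)
        )
        frame = base + bg_noise[r0 : r0 + h, c0 : c0 + w]
        for i in range(len(scene.segments)):
            sel = sid == i
            if not sel.any():
                continue
            tex = textures[i]
            n_s = tex.shape[0]
            # linear interpolation along arc length: nearest-neighbor would
            # quantize non-integer speeds to alternating integer shifts,
            # which a frame-pair velocimeter reads with a systematic bias
            u = (sidx[sel] - speeds[i] * t) % n_s
            u0 = np.floor(u).astype(np.int64)
            fr = u - u0
            m = (1.0 - fr) * tex[u0 % n_s, ridx[sel]] + fr * tex[(u0 + 1) % n_s, ridx[sel]]
            bg_here = bg_noise[r0 : r0 + h, c0 : c0 + w][sel]
            frame[sel] = (
                base
                + bg_here * (1.0 - al[sel])
                + sign * scene.vessel_contrast * m * al[sel]
            )
        if blur_sds[t] > 0.05:
            frame = gaussian_filter(frame, sigma=blur_sds[t], mode="nearest")
        frames[t] = np.clip(frame, 0.0, 1.0)

    # ground truth at zero offset
    mask = maps.alpha[pad : pad + h, pad : pad + w] >= 0.5
    centerline = []
    for seg in scene.segments:
        samples, _, _ = _resample_polyline(seg.points, step=0.7)
        centerline.append(samples)
    offsets_dxdy = offsets_yx[:, ::-1].copy()  # report as (dx, dy)
    gt = GroundTruth(
        offsets=offsets_dxdy,
        mask=mask,
        centerline=tuple(centerline),
        speeds=speeds.copy(),
        junctions=scene.junctions,
    )
    return VideoSequence(frames), gt


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------


def write_phantom(
    video: VideoSequence, gt: GroundTruth, out_dir: str | os.PathLike
) -> Path:
    """Write frames (PNG), offsets+speeds (JSON), mask (PNG), centerline (CSV)."""
    import imageio.v3 as iio
    import pandas as pd

    from .video import write_frames

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_frames(video, out / "frames")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "offsets_dx_dy": gt.offsets.tolist(),
                "speeds_px_per_frame": gt.speeds.tolist(),
                "junctions_row_col": [list(j) for j in gt.junctions],
            },
            fh,
            indent=2,
        )
    iio.imwrite(out / "mask.png", (gt.mask.astype(np.uint8) * 255))
    rows = []
    for sid, poly in enumerate(gt.centerline):
        for order, (r, c) in enumerate(poly):
            rows.append((sid, order, r, c))
    pd.DataFrame(rows, columns=["segment_id", "order", "row", "col"]).to_csv(
        out / "centerline.csv", index=False
    )
    return out
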