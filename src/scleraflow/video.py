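"""Video containers and frame-sequence I/O.

A :class:`VideoSequence` is the unit every pipeline stage consumes and emits:
an ordered stack of single-channel float frames in ``[0, 1]`` with optional
physical calibration (micrometres per pixel, frames per second).

All modules share the same geometric convention: arrays are indexed
``(row, col)`` with the origin at the top-left, 0-based, and crop windows are
half-open (``[r0, r0+h) x [c0, c0+w)``).
"""

from __future__ import annotations

import dataclasses
import os
import re
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Calibration", "VideoSequence", "read_video", "write_frames"]


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Physical calibration of an acquisition.

    Parameters
    ----------
    um_per_px : float
        Micrometres imaged per pixel.
    fps : float
        Frames per second of the camera.
    """

    um_per_px: float
    fps: float

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or self.fps <= 0:
            raise ValueError("calibration constants must be positive")


class VideoSequence:
    """Ordered grayscale frames with optional physical calibration.

    Frames are stored as a single ``(n_frames, height, width)`` float64 array
    with values in ``[0, 1]``.
    """

    def __init__(
        self,
        frames: np.ndarray | Sequence[np.ndarray],
        calibration: Calibration | None = None,
    ) -> None:
        arr = np.asarray(frames, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected (n, h, w) frame stack, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("a video needs at least one frame")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")
        self._frames = np.clip(arr, 0.0, 1.0)
        self.calibration = calibration

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self._frames.shape[0]

    def __getitem__(self, index: int) -> np.ndarray:
        return self._frames[index]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self._frames)

    @property
    def frames(self) -> np.ndarray:
        return self._frames

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self._frames.shape[1:]  # type: ignore[return-value]

    def with_frames(self, frames: np.ndarray) -> "VideoSequence":
        """New sequence with the same calibration but different frames."""
        return VideoSequence(frames, calibration=self.calibration)


_FRAME_EXTENSIONS = {".png", ".tif", ".tiff"}


def _numeric_key(name: str) -> tuple:
    """Sort key ordering embedded integers numerically (frame_2 < frame_10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_unit_float(img: np.ndarray, source: str) -> np.ndarray:
    if img.ndim == 3:
        # Luma conversion (Rec. 601); the acquisition is grayscale video, so a
        # color input is unexpected but tolerated.
        import warnings

        warnings.warn(f"{source}: color input converted to luma", stacklevel=3)
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2:
        raise ValueError(f"{source}: expected a 2-D frame, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    out = img.astype(np.float64)
    if out.size and out.max() > 1.0:  # already scaled integer data in float form
        out = out / out.max()
    return out


def read_video(path: str | os.PathLike, calibration: Calibration | None = None) -> VideoSequence:
    """Read a video from a directory of numbered frames or a multi-page TIFF.

    Frames are converted to float in ``[0, 1]`` (8-bit scaled by 255, 16-bit by
    65535) and ordered by numeric filename.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If no frames are found, a frame is unreadable (the offending file is
        named), or frame shapes are inconsistent.
    """
    import imageio.v3 as iio

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))

    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTENSIONS),
            key=lambda f: _numeric_key(f.name),
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {p}")
        frames = []
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:  # pragma: no cover - backend specific
                raise ValueError(f"unreadable frame {f.name}: {exc}") from exc
            frames.append(_to_unit_float(np.asarray(img), f.name))
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {p}: {sorted(shapes)}")
        return VideoSequence(np.stack(frames), calibration=calibration)

    # single file: multi-page TIFF
    import tifffile

    stack = np.asarray(tifffile.imread(p))
    if stack.ndim == 2:
        stack = stack[None]
    frames = [_to_unit_float(fr, f"{p.name}[{i}]") for i, fr in enumerate(stack)]
    return VideoSequence(np.stack(frames), calibration=calibration)


def write_frames(video: VideoSequence, out_dir: str | os.PathLike, prefix: str = "frame") -> list[Path]:
    """Write a sequence as zero-padded 8-bit PNG frames; returns the paths."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(video) - 1)))
    paths = []
    for i, frame in enumerate(video):
        fp = out / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(fp, (np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
        paths.append(fp)
    return paths
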