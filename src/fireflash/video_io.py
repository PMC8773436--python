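"""Reading flash-scene video and frame stacks, and time-stacking projections.

Night-time firefly recordings arrive either as constant-rate video clips
(30 or 60 fps, i.e. 0.03 or 0.02 s frame delay) or as TIFF frame stacks
exported from such clips.  Everything downstream works on an 8-bit grayscale
:class:`FrameSequence`; RGB input is averaged to grayscale on load and 16-bit
input is linearly rescaled.  Time-stacking (max-intensity projection and the
temporal color code) collapses a frame range into a single image in which a
flying firefly appears as a dotted trajectory and a perching one as a tight
cluster of round spots.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "FrameSequence",
    "ProjectionImage",
    "load_frames",
    "to_grayscale",
    "max_project",
    "temporal_color_code",
    "decimate",
    "save_frames",
]


class InputError(ValueError):
    """Unreadable, empty or out-of-range input."""


class FormatError(ValueError):
    """Structurally inconsistent input (e.g. mixed frame sizes)."""


@dataclass
class FrameSequence:
    """An ordered stack of equally sized 8-bit grayscale frames.

    Parameters
    ----------
    frames
        Array of shape (n_frames, height, width), dtype uint8.
    frame_delay
        Seconds per frame (0.03 for 30 fps, 0.02 for 60 fps).
    t0
        Wall-clock timestamp of the first frame in seconds (label only).
    """

    frames: np.ndarray
    frame_delay: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n, h, w) stack, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise FormatError(f"frames must be uint8, got {self.frames.dtype}")
        if self.frame_delay <= 0:
            raise InputError(f"frame_delay must be positive, got {self.frame_delay}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_delay

    def time_of(self, frame_idx: int | np.ndarray) -> float | np.ndarray:
        """Timestamp(s) of a frame index: t0 + idx * frame_delay."""
        return self.t0 + np.asarray(frame_idx) * self.frame_delay

    def metadata(self) -> dict:
        return {
            "n_frames": len(self),
            "width": self.width,
            "height": self.height,
            "fps": self.fps,
            "frame_delay_s": self.frame_delay,
            "t0_s": self.t0,
        }


@dataclass
class ProjectionImage:
    """A time-stacked image over a half-open frame range [first, last)."""

    pixels: np.ndarray
    source_range: tuple[int, int]


def _coerce_to_uint8(arr: np.ndarray, color: bool | None = None) -> np.ndarray:
    """Convert a frame array to 8-bit: gray-average RGB, rescale 16-bit.

    ``color`` states whether the trailing axis is a channel axis; when None it
    is inferred (trailing axis of size 3/4 on a >=3-D array).
    """
    if color is None:
        color = arr.ndim >= 3 and arr.shape[-1] in (3, 4)
    if color:
        # (n,h,w,c) or (h,w,c): average the color channels (alpha dropped).
        arr = np.round(arr[..., :3].astype(np.float64).mean(axis=-1))
        arr = arr.astype(np.uint16) if arr.max(initial=0) > 255 else arr.astype(np.uint8)
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scaled = arr.astype(np.float64) * (255.0 / max(info.max, 1))
        return np.round(scaled).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.round(np.clip(arr, 0, 255)).astype(np.uint8)
    raise FormatError(f"unsupported frame dtype {arr.dtype}")


def to_grayscale(rgb_frame: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Convert an RGB frame to 8-bit grayscale.

    By default the unweighted channel mean is used, rounded half-up, matching
    the plain RGB->8-bit stack conversion used for flash footage.  Setting
    ``weighted=True`` applies ITU-R 601 luminance weights instead.
    """
    rgb = np.asarray(rgb_frame, dtype=np.float64)
    if rgb.ndim < 1 or rgb.shape[-1] != 3:
        raise FormatError(f"expected trailing RGB axis of size 3, got {rgb.shape}")
    if weighted:
        gray = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        gray = rgb.mean(axis=-1)
    # round half-up (np.round is banker's rounding)
    return np.floor(gray + 0.5).astype(np.uint8)


def _read_tiff(path: Path) -> tuple[np.ndarray, bool]:
    """Read a TIFF, returning (array, has_channel_axis) using series axes."""
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        color = series.axes.endswith("S") and arr.shape[-1] in (3, 4)
    if arr.ndim == 2 or (color and arr.ndim == 3):
        arr = arr[None]
    return arr, color


def load_frames(path: str | os.PathLike, fps_hint: float | None = None) -> FrameSequence:
    """Load an MP4 clip, a multipage TIFF, or a directory of TIFF frames.

    The frame delay is taken from container metadata when available and from
    ``fps_hint`` otherwise (TIFF stacks carry no rate; the hint is required
    unless the caller accepts the 30 fps default).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")

    frame_delay = 1.0 / fps_hint if fps_hint else None

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise InputError(f"directory contains no TIFF frames: {path}")
        stacks = [_coerce_to_uint8(*_read_tiff(f)) for f in files]
        shapes = {s.shape[1:] for s in stacks}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent frame sizes in {path}: {sorted(shapes)}")
        arr = np.concatenate(stacks, axis=0)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = _coerce_to_uint8(*_read_tiff(path))
    elif path.suffix.lower() in (".mp4", ".avi", ".mov", ".mts"):
        try:
            import imageio.v3 as iio

            arr = np.stack([_coerce_to_uint8(f) for f in iio.imiter(str(path))])
            if frame_delay is None:
                meta = iio.immeta(str(path))
                fps = meta.get("fps")
                if fps:
                    frame_delay = 1.0 / float(fps)
        except ImportError as exc:
            raise InputError(
                f"no video codec backend available to read {path}: {exc}"
            ) from exc
        except Exception as exc:  # unreadable container
            raise InputError(f"could not read video {path}: {exc}") from exc
    else:
        raise InputError(f"unsupported input format: {path}")

    if arr.size == 0:
        raise InputError(f"no frames decoded from {path}")
    if frame_delay is None:
        frame_delay = 0.03  # 30 fps default, the common field setting
    return FrameSequence(frames=arr, frame_delay=frame_delay)


def save_frames(seq: FrameSequence, path: str | os.PathLike,
                write_metadata: bool = True) -> None:
    """Write a FrameSequence as a multipage TIFF plus a JSON metadata header."""
    path = Path(path)
    tifffile.imwrite(str(path), seq.frames, photometric="minisblack")
    if write_metadata:
        path.with_suffix(".json").write_text(json.dumps(seq.metadata(), indent=2))


def _check_range(seq: FrameSequence, rng: tuple[int, int] | None) -> tuple[int, int]:
    first, last = (0, len(seq)) if rng is None else rng
    if not (0 <= first < last <= len(seq)):
        raise InputError(
            f"empty or out-of-bounds frame range [{first}, {last}) for {len(seq)} frames"
        )
    return first, last


def max_project(seq: FrameSequence, rng: tuple[int, int] | None = None) -> ProjectionImage:
    """Max-intensity projection over a half-open frame range.

    Each output pixel is the maximum of that pixel across the selected frames,
    so every flash footprint in the range is superimposed into one image.
    """
    first, last = _check_range(seq, rng)
    return ProjectionImage(
        pixels=seq.frames[first:last].max(axis=0), source_range=(first, last)
    )


def temporal_color_code(
    seq: FrameSequence, rng: tuple[int, int] | None = None
) -> ProjectionImage:
    """Color-coded time stack: hue encodes *when* each pixel peaked.

    Each pixel takes the hue of the frame (within the range) at which it
    attains its maximum, mapped along a fixed rainbow ramp from the first
    frame (red end) to the last (violet end); brightness is the maximum value
    scaled to the global 8-bit range.  Output pixels are (h, w, 3) uint8 RGB.
    """
    from matplotlib.colors import hsv_to_rgb

    first, last = _check_range(seq, rng)
    block = seq.frames[first:last].astype(np.float64)
    argmax = block.argmax(axis=0)
    vmax = block.max(axis=0)
    n = last - first
    # hue ramp red (0.0) -> violet (0.83), the usual rainbow LUT span
    frac = argmax / max(n - 1, 1)
    hsv = np.stack([frac * 0.83, np.ones_like(frac), vmax / 255.0], axis=-1)
    rgb = np.round(hsv_to_rgb(hsv) * 255).astype(np.uint8)
    return ProjectionImage(pixels=rgb, source_range=(first, last))


def decimate(seq: FrameSequence, factor: int) -> FrameSequence:
    """Keep every ``factor``-th frame (indices 0, factor, 2*factor, ...).

    Mirrors the frame-reduction step used to avoid re-detecting the same
    flash in adjacent frames: a reduction factor of 30 on a 30 fps clip keeps
    one frame per second.  ``frame_delay`` is multiplied accordingly.
    """
    factor = int(factor)
    if factor < 1:
        raise InputError(f"reduction factor must be >= 1, got {factor}")
    return FrameSequence(
        frames=seq.frames[::factor].copy(),
        frame_delay=seq.frame_delay * factor,
        t0=seq.t0,
    )
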