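"""Prominence-based flash-spot detection and population flash counting.

A firefly flash appears as a compact bright blob on a dark, noisy background.
Spots are detected per frame as local intensity maxima whose *topographic
prominence* — peak value minus the highest saddle connecting the peak to any
strictly higher maximum — reaches a threshold (default 80 on the 8-bit
scale, the setting used for field footage).  Detection over a clip decimates
the frame stack first (default one frame in 30) so a flash lasting several
frames is not counted once per frame.

Semantics of the maxima finder (8-connectivity throughout):

* a *plateau* is a maximal connected set of equal-valued pixels; it is a
  local maximum iff no neighboring pixel is higher;
* a local-max plateau at value v is accepted iff the connected component of
  ``{pixels > v - prominence}`` containing it holds no strictly higher pixel
  (equivalently, the saddle to higher terrain lies at or below
  v - prominence) and v >= min_background + prominence;
* equal-valued maxima joined above that level count once (the plateau
  containing the raster-smallest pixel is reported), matching the
  one-output-per-flooded-region behavior of interactive maxima finders;
* an accepted plateau is reported at its centroid, rounded to the nearest
  pixel with ties toward the smaller index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .video_io import FrameSequence, InputError, decimate as _decimate

__all__ = [
    "DetectionParams",
    "FlashSpot",
    "find_maxima",
    "detect_sequence",
    "merge_duplicate_spots",
    "flash_rate",
    "spots_to_frame",
]

SPOT_COLUMNS = ["frame_idx", "t_s", "x_px", "y_px", "peak", "area_px", "elongation"]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionParams:
    """Settings for flash-spot detection.

    prominence
        Minimum topographic prominence of an accepted maximum (8-bit units).
    min_background
        Intensity floor; maxima must reach min_background + prominence.
    decimation_factor
        Keep one frame in this many before detecting (duplicate control).
    merge_duplicates / merge_radius_px
        Optional suppression of the same flash re-detected in consecutive
        retained frames within the radius; off by default (decimation is the
        primary duplicate control).
    """

    prominence: float = 80.0
    min_background: float = 10.0
    decimation_factor: int = 30
    merge_duplicates: bool = False
    merge_radius_px: float = 3.0

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise InputError(f"prominence must be > 0, got {self.prominence}")
        if self.min_background < 0:
            raise InputError(f"min_background must be >= 0, got {self.min_background}")
        if self.decimation_factor < 1:
            raise InputError(
                f"decimation_factor must be >= 1, got {self.decimation_factor}"
            )


@dataclass
class FlashSpot:
    """One detected flash: location, brightness, and footprint shape."""

    x: float
    y: float
    peak_intensity: float
    area: int
    elongation: float
    frame_idx: int = -1
    t: float = float("nan")


def _footprint_shape(
    image: np.ndarray, r: int, c: int, background: float
) -> tuple[int, float]:
    """Area and elongation of the half-height region around a peak.

    The region is the connected set of pixels >= background + 0.5*(peak -
    background) containing the peak.  Elongation is the major/minor axis
    ratio of the region's binary second moments; degenerate regions (single
    pixel, collinear) report max(major_axis, 1) so the value stays >= 1.
    """
    peak = float(image[r, c])
    thresh = background + 0.5 * (peak - background)
    labels, _ = ndimage.label(image >= thresh, structure=_EIGHT)
    region_mask = labels == labels[r, c]
    area = int(region_mask.sum())
    if area <= 1:
        return area, 1.0
    props = measure.regionprops(region_mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    major = props.axis_major_length
    if minor < 1e-9:
        return area, max(major, 1.0)
    return area, max(major / minor, 1.0)


def find_maxima(image: np.ndarray, params: DetectionParams | None = None) -> list[FlashSpot]:
    """Detect flash spots in one frame as prominent local maxima.

    Returns one :class:`FlashSpot` per accepted maximum (``frame_idx`` and
    ``t`` unset); an empty list on blank frames.
    """
    params = params or DetectionParams()
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("empty image")
    img = image.astype(np.float64)
    h, w = img.shape
    floor = params.min_background + params.prominence

    # candidate pixels: as high as every neighbor, and above the floor
    maxfilt = ndimage.maximum_filter(img, footprint=_EIGHT, mode="constant", cval=-np.inf)
    cand = (img >= maxfilt) & (img >= floor)
    if not cand.any():
        return []
    cand_labels, n_cand = ndimage.label(cand, structure=_EIGHT)

    spots: list[FlashSpot] = []
    for lab in range(1, n_cand + 1):
        rows, cols = np.nonzero(cand_labels == lab)
        v = float(img[rows[0], cols[0]])
        # component of {img > v - prominence} containing this plateau
        above = img > v - params.prominence
        rlab, _ = ndimage.label(above, structure=_EIGHT)
        region = rlab == rlab[rows[0], cols[0]]
        if img[region].max() > v:
            continue  # saddle to higher terrain is above v - prominence
        # among equal maxima in one region, report the raster-smallest only
        vmask = region & (img == v)
        first = int(np.flatnonzero(vmask.ravel())[0])
        if first not in (rows * w + cols):
            continue
        pr, pc = float(rows.mean()), float(cols.mean())
        rr = int(np.ceil(pr - 0.5))  # ties toward the smaller index
        cc = int(np.ceil(pc - 0.5))
        area, elong = _footprint_shape(img, int(rows[0]), int(cols[0]),
                                       params.min_background)
        spots.append(
            FlashSpot(x=float(cc), y=float(rr), peak_intensity=v,
                      area=area, elongation=elong)
        )
    spots.sort(key=lambda s: (s.y, s.x))
    return spots


def spots_to_frame(spots: Iterable[FlashSpot]) -> pd.DataFrame:
    """Flatten FlashSpot records into the exported spot table."""
    rows = [
        {
            "frame_idx": s.frame_idx,
            "t_s": s.t,
            "x_px": s.x,
            "y_px": s.y,
            "peak": s.peak_intensity,
            "area_px": s.area,
            "elongation": s.elongation,
        }
        for s in spots
    ]
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def detect_sequence(seq: FrameSequence, params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect flash spots across a clip.

    The stack is decimated by ``params.decimation_factor`` first, then
    :func:`find_maxima` runs on each retained frame; each spot is stamped
    with its original frame index and timestamp.  Returns the flat spot
    table (columns: frame_idx, t_s, x_px, y_px, peak, area_px, elongation).
    """
    params = params or DetectionParams()
    if len(seq) == 0:
        raise InputError("empty frame sequence")
    reduced = _decimate(seq, params.decimation_factor)
    spots: list[FlashSpot] = []
    for k in range(len(reduced)):
        orig_idx = k * params.decimation_factor
        for s in find_maxima(reduced.frames[k], params):
            s.frame_idx = orig_idx
            s.t = float(seq.time_of(orig_idx))
            spots.append(s)
    table = spots_to_frame(spots)
    if params.merge_duplicates and len(table):
        table = merge_duplicate_spots(
            table, radius_px=params.merge_radius_px,
            frame_step=params.decimation_factor,
        )
    return table


def merge_duplicate_spots(
    table: pd.DataFrame, radius_px: float, frame_step: int
) -> pd.DataFrame:
    """Collapse the same flash re-detected in consecutive retained frames.

    Spots in successive retained frames (frame_idx differing by exactly
    ``frame_step``) within ``radius_px`` of each other are chained into one
    flash; the brightest spot of each chain is kept.  Spots further apart in
    time or space are left untouched.
    """
    if table.empty:
        return table
    table = table.sort_values(["frame_idx", "y_px", "x_px"]).reset_index(drop=True)
    chain_id = np.arange(len(table))
    by_frame = {f: g for f, g in table.groupby("frame_idx")}
    for f in sorted(by_frame):
        prev = by_frame.get(f - frame_step)
        if prev is None:
            continue
        for i in by_frame[f].index:
            dx = prev["x_px"].to_numpy() - table.at[i, "x_px"]
            dy = prev["y_px"].to_numpy() - table.at[i, "y_px"]
            d = np.hypot(dx, dy)
            j = int(np.argmin(d))
            if d[j] <= radius_px:
                chain_id[i] = chain_id[prev.index[j]]  # join the earlier chain
    for i in range(len(table)):  # resolve chains (links always point earlier)
        r = chain_id[i]
        while chain_id[r] != r:
            r = chain_id[r]
        chain_id[i] = r
    table = table.assign(_chain=chain_id)
    keep = table.loc[table.groupby("_chain")["peak"].idxmax()]
    return keep.drop(columns="_chain").sort_values("frame_idx").reset_index(drop=True)


def flash_rate(spot_table: pd.DataFrame, clip_duration: float) -> float:
    """Population flash activity: total detected flashes per second."""
    if clip_duration <= 0:
        raise InputError(f"clip duration must be positive, got {clip_duration}")
    return len(spot_table) / clip_duration
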