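"""Emission-spectrum summaries: averaging, peak wavelength, FWHM.

Flash color is characterized by the peak wavelength (lambda_max) and the
full width at half maximum (FWHM) of the emission spectrum measured over
400–700 nm.  Reference values for the three species studied here: 563 nm /
59 nm (A. cerata, yellowish), 574 nm / 48 nm (L. kagiana) and 571 nm /
53 nm (L. curtithorax), both in the yellowish-orange band.

Half maximum is measured above the series minimum (the dark offset of the
reading); lambda_max uses a three-point parabolic refinement around the
gridded maximum so nm-level peaks are recovered from nm-gridded readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .video_io import InputError

__all__ = ["SpectrumSummary", "average_spectra", "peak_and_fwhm", "read_spectrum_csv"]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548 * sigma


class BoundaryError(ValueError):
    """A half-maximum crossing falls outside the measured range."""

    def __init__(self, message: str, partial: "SpectrumSummary | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class SpectrumSummary:
    lambda_max: float  # nm
    fwhm: float  # nm (nan when flagged partial)
    readings_averaged: int
    wavelength_range: tuple[float, float]


def average_spectra(
    readings: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean of several (wavelength, intensity) readings.

    Readings on different grids are resampled onto the first reading's grid
    by linear interpolation before averaging.
    """
    if not readings:
        raise InputError("no spectra to average")
    grid = np.asarray(readings[0][0], dtype=float)
    acc = np.zeros_like(grid)
    for wl, inten in readings:
        wl = np.asarray(wl, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if wl.shape == grid.shape and np.allclose(wl, grid):
            acc += inten
        else:
            acc += np.interp(grid, wl, inten)
    return grid, acc / len(readings)


def _parabolic_peak(wl: np.ndarray, inten: np.ndarray, i: int) -> float:
    """Sub-grid peak position from a least-squares parabola over the peak top.

    The fit uses the contiguous run of samples within 10% of the peak height
    (above the dark offset) around the argmax — averaging instrument noise
    over many samples — and falls back to the three-point parabola when the
    top is too narrow.  The vertex is clamped to the fitted window.
    """
    vmin, vmax = float(inten.min()), float(inten.max())
    level = vmin + 0.9 * (vmax - vmin)
    lo = i
    while lo > 0 and inten[lo - 1] >= level:
        lo -= 1
    hi = i
    while hi < len(wl) - 1 and inten[hi + 1] >= level:
        hi += 1
    if hi - lo + 1 >= 3:
        x = wl[lo : hi + 1] - wl[i]
        y = inten[lo : hi + 1]
        a, b, _ = np.polyfit(x, y, 2)
        if a < 0:
            vertex = float(wl[i] - b / (2 * a))
            return float(np.clip(vertex, wl[lo], wl[hi]))
    if i == 0 or i == len(wl) - 1:
        return float(wl[i])
    y0, y1, y2 = inten[i - 1], inten[i], inten[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wl[i])
    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return float(wl[i] + delta * (wl[i + 1] - wl[i]))


def peak_and_fwhm(
    series: tuple[np.ndarray, np.ndarray], readings_averaged: int = 1
) -> SpectrumSummary:
    """Peak wavelength and full width at half maximum of a spectrum.

    The half-maximum level is (min + max) / 2 — i.e. half the peak height
    above the dark offset — and its two crossings are linearly interpolated.
    A flat series violates the unique-maximum precondition; a missing
    crossing on either side raises :class:`BoundaryError` carrying a partial
    summary (fwhm = nan).
    """
    wl = np.asarray(series[0], dtype=float)
    inten = np.asarray(series[1], dtype=float)
    if wl.size < 3:
        raise InputError("spectrum needs at least three samples")
    vmin, vmax = float(inten.min()), float(inten.max())
    if vmax <= vmin:
        raise InputError("flat spectrum: no unique maximum above baseline")
    i = int(np.argmax(inten))
    lam = _parabolic_peak(wl, inten, i)
    half = 0.5 * (vmin + vmax)

    left = None
    for j in range(i, 0, -1):
        if inten[j - 1] < half <= inten[j]:
            left = wl[j - 1] + (half - inten[j - 1]) * (wl[j] - wl[j - 1]) / (
                inten[j] - inten[j - 1]
            )
            break
    right = None
    for j in range(i, wl.size - 1):
        if inten[j + 1] < half <= inten[j]:
            right = wl[j] + (inten[j] - half) * (wl[j + 1] - wl[j]) / (
                inten[j] - inten[j + 1]
            )
            break
    rng = (float(wl.min()), float(wl.max()))
    if left is None or right is None:
        partial = SpectrumSummary(lam, float("nan"), readings_averaged, rng)
        side = "left" if left is None else "right"
        raise BoundaryError(
            f"no half-maximum crossing on the {side} side within "
            f"{rng[0]:.0f}-{rng[1]:.0f} nm",
            partial=partial,
        )
    return SpectrumSummary(
        lambda_max=lam,
        fwhm=float(right - left),
        readings_averaged=readings_averaged,
        wavelength_range=rng,
    )


def read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one spectrometer reading: CSV with wavelength_nm, intensity."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    wl_col = cols.get("wavelength_nm") or list(df.columns)[0]
    in_col = cols.get("intensity") or list(df.columns)[1]
    return df[wl_col].to_numpy(dtype=float), df[in_col].to_numpy(dtype=float)
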