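"""Synchronous 2D correlation maps and chemical contrast images.

Synchronous two-dimensional correlation spectroscopy (2D-COS) here uses
Pearson correlation coefficients: entry (i, j) of the map is the
correlation, across the spectrum set, between the intensity series at
channels i and j.  Coordinated band changes appear as off-diagonal
features even when the bands are not resolved in any single spectrum.
Chemical contrast images reduce a raster-scanned hyperspectral set to
one intensity per position within a chosen band (e.g., the
phosphatidylcholine band near 717 cm^-1 in cell maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import SpectrumSet

__all__ = ["SyncMap", "ContrastImage", "synchronous_correlation", "contrast_image"]


@dataclass(frozen=True)
class SyncMap:
    """Square correlation-coefficient matrix over a channel range.

    Entries for zero-variance channels are NaN (undefined), flagged in
    ``undefined_channels``.
    """

    matrix: np.ndarray
    channel_axis: np.ndarray
    undefined_channels: np.ndarray


@dataclass(frozen=True)
class ContrastImage:
    """Raster image of band intensity; missing positions are NaN."""

    grid: np.ndarray
    band_center: float
    band_halfwidth: float


def synchronous_correlation(sset: SpectrumSet, lo: float, hi: float,
                            normalize: bool = True) -> SyncMap:
    """Synchronous 2D-COS correlation-coefficient map over [lo, hi].

    Spectra are first normalized to their tallest-peak intensities when
    ``normalize`` is true.  The map is symmetric with unit diagonal
    wherever the channel intensity series has nonzero variance.
    """
    if len(sset) < 3:
        raise ValueError("need at least 3 spectra for a correlation map")
    if lo >= hi:
        raise ValueError("lo must be < hi")
    sel = (sset.axis >= lo) & (sset.axis <= hi)
    if not sel.any():
        raise ValueError("channel range outside the axis")
    data = sset.intensities.copy()
    if normalize:
        tallest = data.max(axis=1, keepdims=True)
        if np.any(tallest <= 0):
            raise ValueError("cannot normalize a spectrum with no positive peak")
        data = data / tallest
    block = data[:, sel]  # (n_spectra, n_channels_in_range)
    std = block.std(axis=0)
    defined = std > 0
    centered = block - block.mean(axis=0)
    denom = np.outer(std, std) * block.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ centered) / denom
    corr[~defined, :] = np.nan
    corr[:, ~defined] = np.nan
    idx = np.where(defined)[0]
    corr[idx, idx] = 1.0  # exact unit diagonal for defined channels
    corr = np.clip(corr, -1.0, 1.0, out=corr)
    return SyncMap(matrix=corr, channel_axis=sset.axis[sel],
                   undefined_channels=sset.axis[sel][~defined])


def contrast_image(sset: SpectrumSet, band_center: float,
                   band_halfwidth: float, reducer: str = "max") -> ContrastImage:
    """Band-intensity raster image from a hyperspectral set with coords.

    Per raster position the image value is the maximum (or mean,
    ``reducer="mean"``) intensity within band_center +- band_halfwidth;
    a halfwidth of 0 picks the nearest channel.  Raster positions with
    no spectrum are NaN.
    """
    if sset.coords is None:
        raise ValueError("spectrum set carries no raster coordinates")
    axis = sset.axis
    if band_center < axis[0] or band_center > axis[-1]:
        raise ValueError("band center outside the axis")
    if band_halfwidth < 0:
        raise ValueError("band halfwidth must be >= 0")
    if reducer not in ("max", "mean"):
        raise ValueError("reducer must be 'max' or 'mean'")
    sel = np.abs(axis - band_center) <= band_halfwidth
    if not sel.any():
        sel = np.zeros_like(axis, dtype=bool)
        sel[int(np.argmin(np.abs(axis - band_center)))] = True
    reduce = np.max if reducer == "max" else np.mean
    values = [float(reduce(row[sel])) for row in sset.intensities]
    rows = [r for r, _ in sset.coords]
    cols = [c for _, c in sset.coords]
    r0, c0 = min(rows), min(cols)
    grid = np.full((max(rows) - r0 + 1, max(cols) - c0 + 1), np.nan)
    for (r, c), v in zip(sset.coords, values):
        grid[r - r0, c - c0] = v
    return ContrastImage(grid=grid, band_center=band_center,
                         band_halfwidth=band_halfwidth)
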