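"""Core containers for one-dimensional spectra and parametric peak lists.

A :class:`Spectrum` pairs a strictly increasing coordinate axis (channel
index or Raman shift in cm^-1) with one intensity vector; a
:class:`SpectrumSet` stacks several intensity vectors on a shared axis and
may carry integer raster coordinates for hyperspectral maps.  Peak-fitting
results are carried as :class:`PeakList` objects holding
:class:`FittedPeak` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Spectrum", "SpectrumSet", "FittedPeak", "PeakList"]


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must not be empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """One spectrum: a strictly increasing axis and one intensity per channel."""

    axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        axis = _as_1d_float(self.axis, "axis")
        inten = _as_1d_float(self.intensities, "intensities")
        if axis.shape != inten.shape:
            raise ValueError(
                f"axis length {axis.size} != intensities length {inten.size}"
            )
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing (no duplicates)")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities) -> "Spectrum":
        """Same axis, new intensity vector."""
        return Spectrum(self.axis, intensities)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.axis, other.axis) and np.array_equal(
            self.intensities, other.intensities
        )

    @staticmethod
    def from_channels(intensities) -> "Spectrum":
        """Spectrum on an integer channel axis 0..N-1."""
        inten = np.asarray(intensities, dtype=float)
        return Spectrum(np.arange(inten.size, dtype=float), inten)


@dataclass(frozen=True)
class SpectrumSet:
    """Spectra stacked on one shared axis, optionally with raster coordinates.

    ``coords`` is a sequence of (row, col) integer positions, one per
    spectrum, used for chemical contrast imaging; positions must be unique.
    """

    axis: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_channels)
    coords: tuple | None = None

    def __post_init__(self):
        axis = _as_1d_float(self.axis, "axis")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        inten = np.asarray(self.intensities, dtype=float)
        if inten.ndim != 2:
            raise ValueError("intensities must be 2-D (n_spectra, n_channels)")
        if inten.shape[1] != axis.size:
            raise ValueError(
                f"channel count {inten.shape[1]} does not match axis length {axis.size}"
            )
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities contain non-finite values")
        coords = self.coords
        if coords is not None:
            coords = tuple((int(r), int(c)) for r, c in coords)
            if len(coords) != inten.shape[0]:
                raise ValueError("coords must supply one (row, col) per spectrum")
            if len(set(coords)) != len(coords):
                raise ValueError("raster coordinates must be unique per spectrum")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for row in self.intensities:
            yield Spectrum(self.axis, row)

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i])

    @staticmethod
    def from_spectra(spectra: Sequence[Spectrum], coords=None) -> "SpectrumSet":
        if not spectra:
            raise ValueError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.axis, axis):
                raise ValueError("all spectra must share one axis")
        return SpectrumSet(axis, np.vstack([s.intensities for s in spectra]), coords)


@dataclass(frozen=True)
class FittedPeak:
    """One fitted peak: position (channels), amplitude, HWHM, and lineshape.

    ``shape`` is the pseudo-Voigt mixing fraction in [0, 1] (0 Gaussian,
    1 Lorentzian) or the Pearson VII exponent m > 0.5, depending on
    ``family`` ("pseudo_voigt" or "pearson7").
    """

    position: float
    amplitude: float
    hwhm: float
    shape: float = 1.0
    family: str = "pseudo_voigt"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.hwhm <= 0:
            raise ValueError("hwhm must be > 0")
        if self.family not in ("pseudo_voigt", "pearson7"):
            raise ValueError(f"unknown profile family {self.family!r}")
        if self.family == "pseudo_voigt" and not (0.0 <= self.shape <= 1.0):
            raise ValueError("pseudo-Voigt mixing fraction must be in [0, 1]")
        if self.family == "pearson7" and self.shape <= 0.5:
            raise ValueError("Pearson VII exponent must be > 0.5")


@dataclass
class PeakList:
    """Fitted peaks kept sorted by position; no two peaks share a position."""

    peaks: list = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.position)
        positions = [p.position for p in self.peaks]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate peak positions in PeakList")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude for p in self.peaks], dtype=float)

    @property
    def hwhms(self) -> np.ndarray:
        return np.array([p.hwhm for p in self.peaks], dtype=float)
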