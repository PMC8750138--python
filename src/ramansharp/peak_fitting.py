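"""Parametric peak decomposition and artificially narrowed reconstruction.

Two fitters produce a :class:`~ramansharp.spectrum.PeakList` from a
spectrum:

* **Moving-window fitting** — up to seven consecutive peaks are fitted
  simultaneously by bounded nonlinear least squares, then the window
  slides one peak at a time.  The first window records its first four
  peaks; each subsequent window records only its center peak; the last
  window records all remaining peaks.  Starting peaks come from the
  envelope-shaped once-repeated pseudospectrum of the input, with
  starting widths at half the user-supplied spectral resolution.
  Positions may move a few channels from their start, widths are bounded
  between one channel and three times the spectral resolution, and
  fitted peaks below a small amplitude floor are discarded.

* **Fit-and-subtract** — as long as the residual's tallest point
  exceeds a height threshold, a single Pearson VII peak is seeded
  there, fitted against the residual, and subtracted; the accumulated
  peaks form the decomposition.

Either fitter's result can be re-rendered with widths reduced to a
fraction of the fitted widths and heights raised commensurately (area
is preserved), producing an artificially narrowed spectrum.
"""

from __future__ import annotations

import logging

import numpy as np
import lmfit
from scipy.signal import find_peaks

from .base import SpectrumTransformer
from .sharpening import _ep_enhance_array
from .spectrum import FittedPeak, PeakList, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "MovingWindowFitter",
    "IterativePeakFitter",
    "pearson7_profile",
    "pseudo_voigt_profile",
    "profile_array",
    "initial_peaks",
    "moving_window_fit",
    "fit_and_subtract",
    "reconstruct_narrowed",
]

WINDOW_SIZE = 7  # peaks fitted simultaneously in the moving window


def _pearson7(axis, position, amplitude, hwhm, m):
    if m <= 0.5:
        raise ValueError("Pearson VII exponent must be > 0.5")
    u = (axis - position) / hwhm
    return amplitude * (1.0 + u * u * (2.0 ** (1.0 / m) - 1.0)) ** (-m)


def _pseudo_voigt(axis, position, amplitude, hwhm, frac):
    u = (axis - position) / hwhm
    lorentz = 1.0 / (1.0 + u * u)
    gauss = np.exp(-np.log(2.0) * u * u)
    return amplitude * (frac * lorentz + (1.0 - frac) * gauss)


def profile_array(peak: FittedPeak, axis: np.ndarray) -> np.ndarray:
    """Evaluate one fitted peak on an axis."""
    if peak.family == "pearson7":
        return _pearson7(axis, peak.position, peak.amplitude, peak.hwhm, peak.shape)
    return _pseudo_voigt(axis, peak.position, peak.amplitude, peak.hwhm, peak.shape)


def pearson7_profile(peak: FittedPeak, axis) -> Spectrum:
    """Pearson VII lineshape: Lorentzian at m = 1, near-Gaussian as m grows.

    A * [1 + ((v - p) / w)^2 * (2^(1/m) - 1)]^(-m); the maximum equals
    the amplitude at the position and the value is half the amplitude at
    one HWHM from it, for every exponent m.
    """
    axis = np.asarray(axis, dtype=float)
    return Spectrum(axis, _pearson7(axis, peak.position, peak.amplitude,
                                    peak.hwhm, peak.shape))


def pseudo_voigt_profile(peak: FittedPeak, axis) -> Spectrum:
    """Pseudo-Voigt: linear mix of Lorentzian (frac=1) and Gaussian (frac=0)
    of equal height and HWHM."""
    axis = np.asarray(axis, dtype=float)
    return Spectrum(axis, _pseudo_voigt(axis, peak.position, peak.amplitude,
                                        peak.hwhm, peak.shape))


def render_peaks(peaks, axis: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis, dtype=float)
    for p in peaks:
        out += profile_array(p, axis)
    return out


def _initial_peaks_array(x: np.ndarray, resolution: int) -> list[FittedPeak]:
    try:
        enhanced = _ep_enhance_array(x, resolution, alignment=0, degree=2)
    except ValueError:
        return []
    maxima, _ = find_peaks(enhanced)
    maxima = maxima[enhanced[maxima] > 0]
    peaks = []
    for m in maxima:
        peaks.append(FittedPeak(position=float(m), amplitude=float(max(x[m], 0.0)),
                                hwhm=resolution / 2.0))
    if not peaks:
        logger.info("no starting peaks found")
    return peaks


def initial_peaks(s: Spectrum, spectral_resolution: int = 9) -> PeakList:
    """Starting peaks from the envelope-shaped once-repeated pseudospectrum.

    Each local maximum becomes a starting peak with amplitude equal to
    the spectrum value there and HWHM equal to half the spectral
    resolution.
    """
    return PeakList(_initial_peaks_array(s.intensities, spectral_resolution))


def _make_params(peaks, axis, family, max_shift, width_min, width_max):
    params = lmfit.Parameters()
    lo, hi = axis[0], axis[-1]
    for j, p in enumerate(peaks):
        params.add(f"p{j}_amp", value=max(p.amplitude, 1e-6), min=0.0)
        params.add(f"p{j}_pos", value=p.position,
                   min=max(lo, p.position - max_shift),
                   max=min(hi, p.position + max_shift))
        params.add(f"p{j}_hwhm", value=np.clip(p.hwhm, width_min, width_max),
                   min=width_min, max=width_max)
        if family == "pearson7":
            params.add(f"p{j}_shape", value=1.5, min=0.51, max=100.0)
        else:
            params.add(f"p{j}_shape", value=0.5, min=0.0, max=1.0)
    return params


def _peaks_from_params(params, n, family) -> list[FittedPeak]:
    out = []
    for j in range(n):
        out.append(FittedPeak(
            position=float(params[f"p{j}_pos"].value),
            amplitude=float(params[f"p{j}_amp"].value),
            hwhm=float(params[f"p{j}_hwhm"].value),
            shape=float(params[f"p{j}_shape"].value),
            family=family,
        ))
    return out


def _fit_group(peaks, axis, data, family, max_shift, width_min, width_max):
    """Bounded least-squares fit of a group of peaks; returns fitted list."""
    params = _make_params(peaks, axis, family, max_shift, width_min, width_max)

    def residual(pars):
        model = np.zeros_like(axis)
        for j in range(len(peaks)):
            args = (axis, pars[f"p{j}_pos"].value, pars[f"p{j}_amp"].value,
                    pars[f"p{j}_hwhm"].value, pars[f"p{j}_shape"].value)
            model += (_pearson7(*args) if family == "pearson7"
                      else _pseudo_voigt(*args))
        return model - data

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-10, ftol=1e-10)
    if not result.success:
        logger.warning("window fit did not converge; keeping starting values")
        return list(peaks), False
    return _peaks_from_params(result.params, len(peaks), family), True


def _moving_window_fit_array(
    x: np.ndarray,
    resolution: int = 9,
    max_shift: float = 2.0,
    width_min: float = 1.0,
    width_max: float = 7.5,
    amplitude_floor: float = 0.001,
    family: str = "pseudo_voigt",
) -> list[FittedPeak]:
    axis = np.arange(x.size, dtype=float)
    start = _initial_peaks_array(x, resolution)
    for i, p in enumerate(start):
        start[i] = FittedPeak(p.position, p.amplitude, p.hwhm,
                              0.5 if family == "pseudo_voigt" else 1.5, family)
    n = len(start)
    if n == 0:
        return []
    pad = 3.0 * max(p.hwhm for p in start)

    def window_slice(peaks):
        lo = max(0, int(np.floor(min(p.position for p in peaks) - pad)))
        hi = min(x.size, int(np.ceil(max(p.position for p in peaks) + pad)) + 1)
        return slice(lo, hi)

    recorded: dict[int, FittedPeak] = {}
    if n <= WINDOW_SIZE:
        sl = window_slice(start)
        fitted, _ = _fit_group(start, axis[sl], x[sl], family,
                               max_shift, width_min, width_max)
        recorded = dict(enumerate(fitted))
    else:
        for i in range(0, n - WINDOW_SIZE + 1):
            group = start[i: i + WINDOW_SIZE]
            sl = window_slice(group)
            fitted, _ = _fit_group(group, axis[sl], x[sl], family,
                                   max_shift, width_min, width_max)
            if i == 0:
                for j in range(4):           # first window: record peaks 1-4
                    recorded[j] = fitted[j]
            elif i == n - WINDOW_SIZE:       # last window: center + remainder
                for j in range(3, WINDOW_SIZE):
                    recorded[i + j] = fitted[j]
            else:                            # interior windows: center only
                recorded[i + 3] = fitted[3]
    kept = [p for _, p in sorted(recorded.items()) if p.amplitude >= amplitude_floor]
    # guard against coincident fitted positions (PeakList forbids duplicates)
    seen, unique = set(), []
    for p in kept:
        if p.position not in seen:
            seen.add(p.position)
            unique.append(p)
    return unique


def moving_window_fit(
    s: Spectrum,
    resolution: int = 9,
    max_shift: float = 2.0,
    width_min: float = 1.0,
    width_max: float = 7.5,
    amplitude_floor: float = 0.001,
    family: str = "pseudo_voigt",
) -> PeakList:
    """Moving-window simultaneous fit; see :class:`MovingWindowFitter`."""
    return PeakList(_moving_window_fit_array(
        s.intensities, resolution, max_shift, width_min, width_max,
        amplitude_floor, family))


def _fit_and_subtract_array(
    x: np.ndarray,
    height_threshold: float = 0.015,
    initial_width: float = 8.0,
    max_peaks: int = 60,
    family: str = "pearson7",
) -> list[FittedPeak]:
    if height_threshold <= 0:
        raise ValueError("height threshold must be > 0")
    if initial_width < 1:
        raise ValueError("initial width must be >= 1")
    axis = np.arange(x.size, dtype=float)
    residual = x.astype(float).copy()
    peaks: list[FittedPeak] = []
    while residual.max() > height_threshold:
        if len(peaks) >= max_peaks:
            logger.warning("fit-and-subtract truncated at %d peaks", max_peaks)
            break
        top = int(np.argmax(residual))
        seed = FittedPeak(position=float(top), amplitude=float(residual[top]),
                          hwhm=float(initial_width),
                          shape=1.5 if family == "pearson7" else 0.5,
                          family=family)
        fitted, ok = _fit_group(
            [seed], axis, residual, family,
            max_shift=3.0 * initial_width, width_min=1.0,
            width_max=10.0 * initial_width,
        )
        peak = fitted[0]
        if peak.amplitude <= 0:
            break
        residual = residual - profile_array(peak, axis)
        if any(abs(q.position - peak.position) < 1e-9 for q in peaks):
            logger.warning("fit-and-subtract stalled at channel %g", peak.position)
            break
        peaks.append(peak)
    return peaks


def fit_and_subtract(
    s: Spectrum,
    height_threshold: float = 0.015,
    initial_width: float = 8.0,
    max_peaks: int = 60,
    family: str = "pearson7",
) -> PeakList:
    """Iterative tallest-peak fitting; see :class:`IterativePeakFitter`."""
    return PeakList(_fit_and_subtract_array(
        s.intensities, height_threshold, initial_width, max_peaks, family))


def reconstruct_narrowed(peaks: PeakList, width_fraction: float,
                         axis) -> Spectrum:
    """Re-render fitted peaks with widths scaled down and heights scaled up.

    Each peak's HWHM is multiplied by ``width_fraction`` and its
    amplitude divided by it, preserving the fitted area, then all peaks
    are summed on the axis.
    """
    if not 0 < width_fraction <= 1:
        raise ValueError("width_fraction must be in (0, 1]")
    axis = np.asarray(axis, dtype=float)
    narrowed = [
        FittedPeak(p.position, p.amplitude / width_fraction,
                   p.hwhm * width_fraction, p.shape, p.family)
        for p in peaks
    ]
    return Spectrum(axis, render_peaks(narrowed, axis))


class MovingWindowFitter(SpectrumTransformer):
    """Moving-window multi-peak fitting with narrowed reconstruction.

    ``transform`` fits each spectrum and returns its reconstruction with
    widths reduced to ``width_fraction`` of the fitted widths; the
    fitted decompositions are kept in ``peak_lists_``.

    Parameters
    ----------
    resolution : int, default 9
        Spectral resolution (channels) used for the starting-peak search
        and starting widths (half of it).
    max_shift : float, default 2.0
        Channels a fitted position may move from its start (0-5).
    width_max : float, default 7.5
        Upper bound on fitted HWHM (channels); the lower bound is
        ``width_min``.
    width_fraction : float, default 0.33
        Width reduction used for the narrowed reconstruction.
    family : str, default "pseudo_voigt"
        Lineshape family for fitting ("pseudo_voigt" or "pearson7").
    """

    def __init__(self, resolution: int = 9, max_shift: float = 2.0,
                 width_min: float = 1.0, width_max: float = 7.5,
                 amplitude_floor: float = 0.001, width_fraction: float = 0.33,
                 family: str = "pseudo_voigt"):
        self.resolution = resolution
        self.max_shift = max_shift
        self.width_min = width_min
        self.width_max = width_max
        self.amplitude_floor = amplitude_floor
        self.width_fraction = width_fraction
        self.family = family

    def transform(self, X):
        self.peak_lists_ = []
        return super().transform(X)

    def _transform_one(self, x: np.ndarray) -> np.ndarray:
        peaks = _moving_window_fit_array(
            x, self.resolution, self.max_shift, self.width_min,
            self.width_max, self.amplitude_floor, self.family)
        self.peak_lists_.append(PeakList(peaks))
        axis = np.arange(x.size, dtype=float)
        if not peaks:
            return np.zeros_like(x)
        return reconstruct_narrowed(PeakList(peaks), self.width_fraction,
                                    axis).intensities


class IterativePeakFitter(SpectrumTransformer):
    """Fit-and-subtract Pearson VII fitting with narrowed reconstruction.

    ``transform`` decomposes each spectrum by repeatedly fitting and
    subtracting the tallest residual peak, then returns the narrowed
    reconstruction; decompositions are kept in ``peak_lists_``.

    Parameters
    ----------
    height_threshold : float, default 0.015
        Stop once the residual maximum falls below this height.
    initial_width : float, default 8.0
        Starting HWHM (channels) of each seeded peak.
    max_peaks : int, default 60
        Safety cap on the number of fitted peaks.
    width_fraction : float, default 0.33
        Width reduction used for the narrowed reconstruction.
    """

    def __init__(self, height_threshold: float = 0.015,
                 initial_width: float = 8.0, max_peaks: int = 60,
                 width_fraction: float = 0.33, family: str = "pearson7"):
        self.height_threshold = height_threshold
        self.initial_width = initial_width
        self.max_peaks = max_peaks
        self.width_fraction = width_fraction
        self.family = family

    def transform(self, X):
        self.peak_lists_ = []
        return super().transform(X)

    def _transform_one(self, x: np.ndarray) -> np.ndarray:
        peaks = _fit_and_subtract_array(
            x, self.height_threshold, self.initial_width,
            self.max_peaks, self.family)
        self.peak_lists_.append(PeakList(peaks))
        axis = np.arange(x.size, dtype=float)
        if not peaks:
            return np.zeros_like(x)
        return reconstruct_narrowed(PeakList(peaks), self.width_fraction,
                                    axis).intensities
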