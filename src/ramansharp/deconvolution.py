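"""Deconvolution-based resolution enhancement.

* **Blind Richardson-Lucy deconvolution** — joint maximum-likelihood
  estimation of the deblurred spectrum and the unknown instrument
  point-spread function (IPSF).  Each iteration performs one
  multiplicative RL update of the PSF (initialized uniform over its
  support) followed by one update of the signal; an optional damping
  dead-band leaves the update ratio at 1 wherever the reconvolution
  residual is smaller than the damping level, suppressing noise-driven
  ringing.  A second pass ("BD 2x") reruns the whole procedure on the
  restored spectrum, which narrows peaks further at the cost of
  satellite artefacts.

* **Weighted over-deconvolution** — deliberate deconvolution with a
  Gaussian kernel *broader* than the true blur so that the restored
  peaks end up narrower than the intrinsic ones.  The restored spectrum
  x >= 0 minimizes || (s - x * g) . w ||_2 where w = s / max(s), so
  reconvolution mismatch is penalized most under the tall peaks and
  satellite bands in low-intensity regions are tolerated, then damped.
  The optimization starts from the squared input envelope-shaped back
  to the input intensities, which is already narrow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import convolve

from .base import SpectrumTransformer
from .sharpening import _envelope_shape_array
from .spectrum import Spectrum
from .synthetic import gaussian_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "BlindDeconvolver",
    "OverDeconvolver",
    "BlindResult",
    "richardson_lucy",
    "blind_deconvolve",
    "over_deconvolve",
]

_TINY = 1e-12


def _conv_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    return convolve(x, k, mode="same")


def _rl_ratio(s: np.ndarray, model: np.ndarray, damping: float) -> np.ndarray:
    ratio = np.where(model > _TINY, s / np.maximum(model, _TINY), 1.0)
    if damping > 0:
        ratio = np.where(np.abs(model - s) < damping, 1.0, ratio)
    return ratio


def _richardson_lucy_array(s: np.ndarray, psf: np.ndarray, iterations: int,
                           damping: float) -> np.ndarray:
    if np.any(s < 0):
        raise ValueError("Richardson-Lucy requires a nonnegative spectrum")
    x = s.copy()
    flipped = psf[::-1]
    for _ in range(iterations):
        model = _conv_same(x, psf)
        x = x * _conv_same(_rl_ratio(s, model, damping), flipped)
    return np.clip(x, 0.0, None)


def richardson_lucy(s: Spectrum, psf, iterations: int = 10,
                    damping: float = 0.0) -> Spectrum:
    """Damped Richardson-Lucy deconvolution with a known, normalized PSF."""
    psf = np.asarray(psf, dtype=float)
    if np.any(psf < 0):
        raise ValueError("PSF must be nonnegative")
    return s.with_intensities(
        _richardson_lucy_array(s.intensities, psf, iterations, damping)
    )


@dataclass(frozen=True)
class BlindResult:
    """Restored spectrum plus the jointly estimated PSF."""

    restored: Spectrum
    psf_estimate: np.ndarray


def _blind_pass(s: np.ndarray, psf_size: int, iterations: int,
                damping: float) -> tuple[np.ndarray, np.ndarray]:
    n = s.size
    half = psf_size // 2
    x = s.copy()
    psf = np.full(psf_size, 1.0 / psf_size)
    center = n - 1  # zero-lag index of a full correlation of two length-n arrays
    for _ in range(iterations):
        # PSF update: correlate the residual ratio against the current signal
        model = _conv_same(x, psf)
        ratio = _rl_ratio(s, model, damping)
        corr = np.correlate(ratio, x, mode="full")
        denom = max(x.sum(), _TINY)
        psf = psf * corr[center - half: center + half + 1] / denom
        psf = np.clip(psf, 0.0, None)
        total = psf.sum()
        psf = np.full(psf_size, 1.0 / psf_size) if total <= _TINY else psf / total
        # signal update with the refreshed PSF
        model = _conv_same(x, psf)
        x = x * _conv_same(_rl_ratio(s, model, damping), psf[::-1])
        x = np.clip(x, 0.0, None)
    return x, psf


def _blind_deconvolve_array(s: np.ndarray, psf_size: int, iterations: int,
                            damping: float, passes: int):
    if psf_size % 2 == 0 or psf_size < 3:
        raise ValueError("psf_size must be odd and >= 3")
    if np.any(s < 0):
        raise ValueError("blind deconvolution requires a nonnegative spectrum")
    x = s
    psf = None
    for _ in range(passes):
        x, psf = _blind_pass(x, psf_size, iterations, damping)
    return x, psf


def blind_deconvolve(s: Spectrum, psf_size: int = 15, damping: float = 0.0,
                     iterations: int = 10, passes: int = 1) -> BlindResult:
    """Blind RL deconvolution; see :class:`BlindDeconvolver`."""
    x, psf = _blind_deconvolve_array(s.intensities, psf_size, iterations,
                                     damping, passes)
    return BlindResult(restored=s.with_intensities(x), psf_estimate=psf)


class BlindDeconvolver(SpectrumTransformer):
    """Blind Richardson-Lucy deconvolution (single or repeated pass).

    Parameters
    ----------
    psf_size : int, default 15
        Odd support, in channels, of the estimated PSF.
    damping : float, default 0.0
        Dead-band level in intensity units: reconvolution residuals
        smaller than this contribute no update, suppressing ringing.
    iterations : int, default 10
        Alternating PSF/signal update iterations per pass.
    passes : int, default 1
        1 for a single blind deconvolution, 2 to rerun on the restored
        spectrum ("BD 2x"), which narrows more but can create artefacts.

    Attributes
    ----------
    psf_estimates_ : list of ndarray
        PSF estimated for each spectrum during the last ``transform``.
    """

    def __init__(self, psf_size: int = 15, damping: float = 0.0,
                 iterations: int = 10, passes: int = 1):
        self.psf_size = psf_size
        self.damping = damping
        self.iterations = iterations
        self.passes = passes

    def transform(self, X):
        self.psf_estimates_ = []
        return super().transform(X)

    def _transform_one(self, x: np.ndarray) -> np.ndarray:
        restored, psf = _blind_deconvolve_array(
            x, self.psf_size, self.iterations, self.damping, self.passes
        )
        self.psf_estimates_.append(psf)
        return restored


# ---------------------------------------------------------------------------
# Weighted over-deconvolution


def _over_deconvolve_array(s: np.ndarray, psf_size: int,
                           damping_threshold: float,
                           max_iter: int = 500) -> tuple[np.ndarray, dict]:
    if psf_size % 2 == 0 or psf_size < 3:
        raise ValueError("psf_size must be odd and >= 3")
    if np.any(s < 0):
        raise ValueError("over-deconvolution requires a nonnegative spectrum")
    smax = s.max()
    if smax <= 0:
        raise ValueError("spectrum must have positive maximum")
    g = gaussian_kernel(sigma=psf_size / 6.0, support=psf_size).weights
    w = s / smax
    half = psf_size // 2
    mask = np.zeros_like(s)
    mask[half: s.size - half] = 1.0  # cost on interior channels only
    w2 = mask * w * w

    def cost_grad(x):
        r = s - _conv_same(x, g)
        c = float(np.sum(w2 * r * r))
        grad = -2.0 * _conv_same(w2 * r, g[::-1])
        return c, grad

    # narrow start: squared peaks shaped back to the input envelope
    x0 = _envelope_shape_array(s * s, s)
    res = minimize(
        cost_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * s.size,
        options={"maxiter": max_iter, "ftol": 1e-8},
    )
    x = np.clip(res.x, 0.0, None)
    if damping_threshold > 0:
        x = np.where(x < damping_threshold * x.max(), 0.0, x)
    diagnostics = {
        "converged": bool(res.success),
        "message": str(res.message),
        "n_iterations": int(res.nit),
        "start_cost": cost_grad(x0)[0],
        "final_cost": float(res.fun),
    }
    if not res.success:
        logger.warning("over-deconvolution did not converge: %s", res.message)
    return x, diagnostics


def over_deconvolve(s: Spectrum, psf_size: int = 39,
                    damping_threshold: float = 0.02) -> Spectrum:
    """Weighted over-deconvolution; see :class:`OverDeconvolver`."""
    x, _ = _over_deconvolve_array(s.intensities, psf_size, damping_threshold)
    return s.with_intensities(x)


class OverDeconvolver(SpectrumTransformer):
    """Weighted over-deconvolution by bound-constrained least squares.

    Parameters
    ----------
    psf_size : int, default 39
        Odd support of the Gaussian deconvolution kernel (sigma =
        psf_size / 6, so the support spans +-3 sigma).  Choosing a
        kernel broader than the instrument blur narrows peaks beyond
        the intrinsic linewidth ("over"-deconvolution).
    damping_threshold : float, default 0.02
        After optimization, channels below this fraction of the restored
        maximum are zeroed to suppress residual satellite bands.

    Attributes
    ----------
    diagnostics_ : list of dict
        Per-spectrum optimizer convergence report from the last
        ``transform``.
    """

    def __init__(self, psf_size: int = 39, damping_threshold: float = 0.02):
        self.psf_size = psf_size
        self.damping_threshold = damping_threshold

    def transform(self, X):
        self.diagnostics_ = []
        return super().transform(X)

    def _transform_one(self, x: np.ndarray) -> np.ndarray:
        restored, diag = _over_deconvolve_array(
            x, self.psf_size, self.damping_threshold
        )
        self.diagnostics_.append(diag)
        return restored
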