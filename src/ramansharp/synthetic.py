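"""Synthetic nine-peak benchmark for resolution-enhancement methods.

The benchmark emulates a Raman measurement m = s * ipsf + n: nine
Lorentzian peaks on a 1000-channel axis whose heights evolve over ten
stages, blurred by a Gaussian instrument point-spread function (IPSF)
with a five-channel standard deviation.  Three aligned sets result:

* **truth** — the noiseless individual peak components per stage,
* **targets** — the per-stage sums of the truth components (what a
  perfect resolution-enhancement method should recover),
* **tests** — the IPSF-blurred targets that the methods are run on.

Peak channels are 340, 465, 532, 584, 618, 645, 656, 800 and 813
(P1..P9).  P1 has an HWHM of six channels, all others three.  The
amplitude schedules exercise distinct failure modes: P1/P5 grow
geometrically (x1.5 per stage); P2 grows arithmetically; P3 decays
slightly; P4 is flat then ramps; P6 decays to zero underneath the
constant P7 (the fused pair); P7–P9 are constant, with P8/P9 a mildly
overlapped constant-height doublet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import Spectrum, SpectrumSet

__all__ = [
    "PEAK_POSITIONS",
    "PEAK_HWHMS",
    "PeakSpec",
    "StageSchedule",
    "IPSFKernel",
    "SyntheticDataset",
    "build_stage_schedule",
    "lorentzian_profile",
    "gaussian_kernel",
    "convolve_ipsf",
    "generate_dataset",
]

N_PEAKS = 9
N_STAGES = 10
PEAK_POSITIONS = np.array([340, 465, 532, 584, 618, 645, 656, 800, 813], dtype=float)
PEAK_HWHMS = np.array([6.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0])


@dataclass(frozen=True)
class PeakSpec:
    """A single benchmark peak: channel position, HWHM, height, lineshape."""

    position: float
    hwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.hwhm <= 0:
            raise ValueError("hwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class StageSchedule:
    """9 peaks x 10 stages matrix of peak heights."""

    amplitudes: np.ndarray

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.shape != (N_PEAKS, N_STAGES):
            raise ValueError(f"schedule must be {N_PEAKS}x{N_STAGES}")
        object.__setattr__(self, "amplitudes", amps)


@dataclass(frozen=True)
class IPSFKernel:
    """Discrete, area-normalized, symmetric instrument blur kernel."""

    weights: np.ndarray
    sigma: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size % 2 == 0:
            raise ValueError("kernel support must be odd")
        if np.any(w < 0):
            raise ValueError("kernel weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    @property
    def support(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class SyntheticDataset:
    """Per-stage truth components, targets, IPSF-blurred tests, and the kernel."""

    truth: tuple            # 10 stages, each a tuple of 9 single-peak Spectra
    targets: SpectrumSet    # 10 spectra
    tests: SpectrumSet      # 10 spectra
    schedule: StageSchedule
    kernel: IPSFKernel
    noise_sigma: float = 0.0

    @property
    def axis(self) -> np.ndarray:
        return self.targets.axis


def build_stage_schedule() -> StageSchedule:
    """The ten-stage height schedule for the nine benchmark peaks.

    P1 grows geometrically from 0.15 by 50% per stage (raw maximum 5.77,
    the row then normalized to unit maximum); P2 = 0.10 + 0.10k; P3
    declines linearly 1.00 -> 0.95; P4 holds at 0.50 through stage five
    then ramps to 1.00; P5 is identical to P1; P6 declines linearly
    1.00 -> 0; P7, P8, P9 are constant at 1.00.
    """
    k = np.arange(N_STAGES)
    p1_raw = 0.15 * 1.5 ** k
    p1 = p1_raw / p1_raw.max()
    p2 = 0.10 + 0.10 * k
    p3 = np.linspace(1.00, 0.95, N_STAGES)
    p4 = np.concatenate([np.full(5, 0.50), np.linspace(0.60, 1.00, 5)])
    p6 = np.linspace(1.00, 0.00, N_STAGES)
    const = np.ones(N_STAGES)
    return StageSchedule(np.vstack([p1, p2, p3, p4, p1, p6, const, const, const]))


def lorentzian_profile(peak: PeakSpec, axis) -> Spectrum:
    """Lorentzian A * g^2 / ((v - p)^2 + g^2); maximum A at v = p, HWHM g."""
    axis = np.asarray(axis, dtype=float)
    g2 = peak.hwhm ** 2
    inten = peak.amplitude * g2 / ((axis - peak.position) ** 2 + g2)
    return Spectrum(axis, inten)


def gaussian_kernel(sigma: float = 5.0, support: int | None = None) -> IPSFKernel:
    """Discretized zero-mean Gaussian, truncated at +-3 sigma, unit area.

    ``support`` must be odd and at least 6*sigma + 1; by default the
    smallest odd support covering +-3 sigma is used.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if support is None:
        half = int(np.ceil(3 * sigma))
        support = 2 * half + 1
    if support % 2 == 0:
        raise ValueError("kernel support must be odd")
    if support < 6 * sigma - 1:
        raise ValueError("support must cover +-3 sigma")
    half = support // 2
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2) / (np.sqrt(2 * np.pi) * sigma)
    return IPSFKernel(w / w.sum(), sigma)


def convolve_ipsf(s: Spectrum, kernel: IPSFKernel) -> Spectrum:
    """Zero-phase, zero-padded convolution with the IPSF (same length)."""
    if kernel.support >= len(s):
        raise ValueError("kernel support must be smaller than the spectrum")
    blurred = np.convolve(s.intensities, kernel.weights, mode="same")
    return s.with_intensities(blurred)


def generate_dataset(
    n_channels: int = 1000,
    sigma: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate truth components, target spectra and IPSF-blurred test spectra.

    Optional i.i.d. Gaussian noise of standard deviation ``noise_sigma``
    is added to the test spectra only (the default benchmark is
    noiseless).
    """
    axis = np.arange(n_channels, dtype=float)
    schedule = build_stage_schedule()
    kernel = gaussian_kernel(sigma=sigma)
    truth_stages = []
    targets = np.zeros((N_STAGES, n_channels))
    tests = np.zeros((N_STAGES, n_channels))
    for stage in range(N_STAGES):
        components = []
        for i in range(N_PEAKS):
            peak = PeakSpec(
                position=PEAK_POSITIONS[i],
                hwhm=PEAK_HWHMS[i],
                amplitude=schedule.amplitudes[i, stage],
            )
            comp = lorentzian_profile(peak, axis)
            components.append(comp)
            targets[stage] += comp.intensities
            tests[stage] += convolve_ipsf(comp, kernel).intensities
        truth_stages.append(tuple(components))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        tests = tests + rng.normal(0.0, noise_sigma, size=tests.shape)
    return SyntheticDataset(
        truth=tuple(truth_stages),
        targets=SpectrumSet(axis, targets),
        tests=SpectrumSet(axis, tests),
        schedule=schedule,
        kernel=kernel,
        noise_sigma=noise_sigma,
    )
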