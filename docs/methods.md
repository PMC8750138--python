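# Methods

## The problem

A dispersive Raman spectrometer records, per channel, the intrinsic
spectrum *s* blurred by the instrument point-spread function and
corrupted by noise:

    m = s * ipsf + n

With a wide slit the IPSF is broad, adjacent bands fuse, and everything
downstream that depends on sparse, well-separated peaks — 2D correlation
spectroscopy, curve resolution, chemical contrast imaging of cells —
degrades.  This package implements six software resolution-enhancement
routes and the apparatus to compare them quantitatively: a fully
specified synthetic benchmark, eight figures of merit, synchronous
2D-COS maps and band-intensity imaging.

All methods are scikit-learn transformers over arrays of shape
(n_spectra, n_channels); thin functions expose the same operations on
`Spectrum` objects.

## The synthetic benchmark

Nine Lorentzian peaks on a 1000-channel axis at channels 340, 465, 532,
584, 618, 645, 656, 800 and 813 (P1..P9); P1 has HWHM 6 channels, all
others 3.  Heights evolve over ten stages:

| peak | schedule |
|------|----------|
| P1   | geometric, 0.15 x 1.5 per stage (raw max 5.77), row normalized to max 1 |
| P2   | arithmetic, 0.10 + 0.10 per stage |
| P3   | linear 1.00 -> 0.95 |
| P4   | 0.50 through stage 5, then linear to 1.00 |
| P5   | identical to P1 |
| P6   | linear 1.00 -> 0 |
| P7, P8, P9 | constant 1.00 |

P7–P9 heights are not uniquely pinned down by the benchmark's
description beyond P8 = P9; all three are set to 1.00, which matches the
separated-doublet observations the benchmark is designed to probe
(equal-height P8/P9; P7 constant underneath the decaying P6).

The per-stage single-peak spectra are the **truth** set; their sums the
**targets**; each truth peak convolved with a discrete Gaussian IPSF
(sigma = 5 channels, truncated at +-3 sigma, renormalized, zero-padded
"same" convolution) and summed gives the **tests**.  By linearity,
blurring peak-by-peak equals blurring the summed target; the test suite
asserts this to 1e-9.  The generator is noiseless by default (the
benchmark spectra contain no added noise); `noise_sigma > 0` with a seed
adds i.i.d. Gaussian noise to the tests for robustness experiments.

What this emulates — and what it does not: the benchmark reproduces
peak fusion under a known Gaussian blur with exactly Lorentzian
lineshapes, a flat zero baseline and no noise.  Real Raman spectra have
baselines, spikes, Poisson-ish noise, Voigt-like shapes and IPSFs that
are neither exactly Gaussian nor shift-invariant; passing the benchmark
therefore demonstrates correctness of the algorithms under their design
assumptions, not field performance.  Baseline flattening, spike removal
and smoothing are presumed done upstream.

## The methods

### Node narrowing (`NodeNarrower`)

A multiplicative filter from the spectrum's first and second
derivatives.  The coefficient implemented is

    f(v) = exp[ -alpha * (1 + (a''/a) / (lambda*(a'/a)^2 + |a''/a| + eps)) ]

The published formula's fraction was typeset flattened and its exact
grouping is ambiguous; this reconstruction was chosen because it is the
one that produces the described behavior and it is intensity-scale
invariant.  At a sharp maximum (a' = 0, a''/a strongly negative) the
ratio tends to -1 and f -> 1: peak tops are untouched.  In convex wings
(a'' > 0) the ratio tends to +1 and f -> exp(-2 alpha).  On flat
stretches and steep flanks (where the lambda term dominates) f ≈
exp(-alpha).  Hence f is bounded in [exp(-2 alpha), 1]: the output never
exceeds the input and never goes negative, and as alpha -> 0 the filter
tends to the identity.  Defaults alpha = lambda = 1 (the recommended
operating point); eps = 1e-6 stabilizes the division, and spectra whose
minimum is below 1e-6 are offset before filtering because the intensity
appears in denominators.

Node narrowing cannot split a fused band with no interior minimum — a
multiplicative filter preserves monotone bridges — which is exactly its
observed failure on the P6–P7 pair.

### Envelope-shaped pseudospectra (`PseudospectrumSharpener`)

One pass: take the first derivative; split it into positive lobes and
absolute negative lobes; shift the negative part by the integer lag that
maximizes its overlap with the positive part and sum; smooth with a
moving average whose window is the declared spectral resolution; rescale
to the parent's total area; realign to the parent by a second lag
search.  Each peak's two derivative lobes collapse into one narrower
bump, so a pass roughly halves peak widths.  Two passes (the default
"degree") approximate second-derivative sharpening and can split bands
fused into a single maximum, because the fused band's derivative still
carries two-lobe substructure.  Envelope shaping finally rescales each
pseudo-peak (the segment between its flanking minima) so its maximum
equals the parent intensity at that channel, constraining the result to
the parent's envelope.

Numerical choices: the lobe-matching lag is searched over
+-resolution — the two lobes of one feature sit about a feature width
apart, and a wider search window lets the broadest fused feature
capture the global score; the parent alignment is searched over
+-3 x resolution; ties break toward zero lag; integer shifts repeat the
edge value rather than zero-filling (zero cliffs at the ends otherwise
seed artefactual lobes on the second pass); the area is rescaled exactly
after the final shift; ripples with prominence below 1e-6 of the
maximum are not treated as peaks.  Defaults: resolution 9 channels,
alignment 0 — the benchmark operating point, at which the method
resolves both the P6–P7 and P8–P9 doublets and returns the correct nine
peaks.  Resolutions of four channels or less over-sharpen and
manufacture artefactual peaks; the parameter sweep reproduces the
separation-vs-resolution trade-off.

### Blind Richardson–Lucy deconvolution (`BlindDeconvolver`)

Damped RL with joint PSF estimation.  The signal update is the standard
multiplicative step x <- x . (psf' * (s / (x * psf))); the PSF update is
the symmetric step (correlate the residual ratio against the current
signal, restricted to the PSF support, renormalized to unit sum each
iteration).  The PSF starts uniform over `psf_size` channels — the only
prior the method assumes is a support size.  The damping argument
defines a dead band: channels whose reconvolution residual is smaller
than the damping level contribute a ratio of 1 (no update), which
suppresses ringing at the cost of sharpening.  Iterations are fixed at
ten per pass.  `passes=2` reruns the whole procedure on the restored
spectrum; the second pass estimates a visibly narrower PSF (smaller
second moment) and splits the fused P6–P7 pair, but also rings —
satellite peaks appear and are tolerated.  Outputs are clipped
nonnegative; RL with a normalized PSF conserves flux away from the
edges and monotonically decreases the Kullback–Leibler divergence
between the data and the reconvolved estimate (asserted in tests).

### Weighted over-deconvolution (`OverDeconvolver`)

Deconvolution recast as a bound-constrained least-squares problem with a
kernel deliberately *broader* than the instrument blur, so that the
solution's peaks are narrower than the intrinsic ones.  The restored
spectrum minimizes

    || (s - x * g) . w ||_2,   x >= 0,

where g is a Gaussian of support `psf_size` (sigma = psf_size/6, the
support spanning +-3 sigma) and the weights w = s / max(s) concentrate
the penalty under the tall peaks, tolerating (then damping) satellite
bands in low-intensity regions.  The start value is the squared input
envelope-shaped back to the input intensities — squaring narrows peaks,
envelope shaping restores their heights — which is already close to a
deconvolved shape.  The optimizer is L-BFGS-B with the analytic
gradient -2 g' * (w^2 . (s - x * g)), cost evaluated on interior
channels only (half the kernel support trimmed at each end), up to 500
iterations with ftol 1e-8; non-convergence is flagged in the
estimator's `diagnostics_`, never silent.  After convergence, channels
below `damping_threshold` x max (default 2%) are zeroed.  At the
benchmark operating point (psf_size 39) the method splits P6–P7 with
near-equal heights, but small true peaks (the stage-1 P1 and P5) can be
suppressed along with the satellites — the documented trade-off.

### Moving-window peak fitting (`MovingWindowFitter`)

Parametric decomposition by bounded nonlinear least squares (lmfit,
Levenberg–Marquardt, tolerances 1e-10).  Starting peaks come from the
envelope-shaped once-repeated pseudospectrum: each local maximum seeds a
peak with the spectrum's intensity there and HWHM of half the declared
spectral resolution.  Seven consecutive peaks are fitted simultaneously
over the sub-axis spanning them padded by three times the largest
starting width (limits leakage from out-of-window peaks); the first
window records its first four peaks, every subsequent window only its
center peak, and the last window the center plus all remaining peaks,
so each starting peak is recorded exactly once.  With seven or fewer
starting peaks a single whole-spectrum fit records everything.
Constraints: positions within `max_shift` channels of their start
(default 2), HWHM in [1, `width_max`] channels (default 7.5 = 1.25x the
P1 FWHM), amplitudes free but peaks below 0.001 units discarded; the
lineshape is pseudo-Voigt (linear Lorentzian/Gaussian mix, mixing free
in [0, 1]) by default, Pearson VII optionally.  A non-convergent window
keeps its starting values and logs a warning.  `transform` returns the
reconstruction with widths reduced to `width_fraction` (default 0.33)
of the fitted widths and heights raised by the inverse factor —
"commensurate" is interpreted as area preservation, consistent with
narrowed spectra overshooting the input envelope.

### Fit-and-subtract (`IterativePeakFitter`)

While the residual's tallest point exceeds `height_threshold` (default
0.015): seed a Pearson VII peak there (amplitude = residual height,
HWHM = `initial_width`, default 8 channels), fit that single peak to
the residual over the whole axis, subtract it, repeat; a `max_peaks`
cap (default 60) guards against stalling and truncation is flagged.
Pearson VII interpolates Lorentzian (m = 1) to near-Gaussian (large m)
while keeping its maximum at the amplitude and its half-maximum at one
HWHM for every exponent.  Characteristic failure modes — a broad
initial width absorbing a fused pair into one peak, small peaks hidden
under fitted tails going missing — are reproduced and tested rather
than patched, since they are diagnostic of the method.

## Figures of merit

Computed against the regenerated benchmark (see `evaluation`): region
RMSE over channels 200–900 (the featureless ends are excluded); the
P8–P9 separation score (smallest flank minus valley, resolved over
target, zero when no interior valley exists); the P1 width-reduction
ratio with HWHM measured on a 10x linearly interpolated grid; peak
count difference, wrong-position count and mean position deviation from
greedy nearest-neighbor matching (tolerance 5 channels, a match beyond
1 channel counts as wrongly positioned), counting local maxima above
0.1% of the spectrum maximum inside the 200–900 region; and the
P6/P7 stage-profile Pearson correlations, read at the resolved maxima
when a stage resolves the pair and at the true positions otherwise.
The true P7 profile is constant, so its correlation against the truth
is undefined; the resolved-P6-vs-resolved-P7 correlation is reported
instead, and any zero-variance series yields an explicit undefined
flag, never NaN propagation.  `parameter_sweep` clones an estimator
over a 2-D grid and fills one surface per metric, recording failed grid
points as missing cells.

## 2D-COS and imaging

The synchronous map is the Pearson correlation-coefficient matrix
between per-channel intensity series across a spectrum set, after
normalizing each spectrum to its tallest peak (making the map invariant
to per-spectrum scaling); it is symmetric with unit diagonal, and
zero-variance channels are flagged undefined.  Correlation coefficients
(not Noda's covariance-scaled synchronous intensity) are used
throughout.  Chemical contrast images reduce a raster-scanned set to
the maximum (or mean) intensity within band_center +- band_halfwidth
per (row, col) position; missing raster positions are NaN and no
interpolation is performed.

## Problem sizes and determinism

Everything is exercised on the 1000-channel, ten-stage benchmark — the
full problem size; nothing is scaled down.  All fits and optimizations
are deterministic (no random restarts); the only randomness in the
package is the optional test-set noise, driven by an explicit seed.

## Known limitations

* Node narrowing and the pseudospectra locate features with
  derivatives, so their resolving power is capped by derivative
  signal-to-noise; neither is tested here under noise by default.
* Blind deconvolution's damping semantics follow the common dead-band
  convention; they are behavioral, not bit-compatible with any vendor
  implementation.
* The moving-window fitter refits already-recorded neighbors inside
  each window from their starting values (only the designated peaks are
  recorded); windows are defined in peak index order, so pathological
  starting lists (near-coincident seeds) degrade gracefully rather
  than optimally.
* Peak counting thresholds for artefact assessment are configurable
  defaults (0.1% relative height, 1e-6 relative prominence), not
  uniquely determined quantities.
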