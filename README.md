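# ramansharp

Software resolution enhancement for Raman spectra, for spectroscopists
who need overlapping bands separated before downstream analysis —
two-dimensional correlation spectroscopy (2D-COS), curve resolution, or
chemical contrast imaging of cells — and who need to know *which*
enhancement method to trust for a given task.

A measured spectrum is modeled as the intrinsic spectrum blurred by the
instrument point-spread function (IPSF) plus noise, m = s ∗ ipsf + n.
The package implements six routes from m back toward s, each as a
scikit-learn transformer:

| method | class | idea |
|---|---|---|
| node narrowing | `NodeNarrower` | multiplicative derivative filter; preserves peak tops, suppresses wings |
| envelope-shaped pseudospectra | `PseudospectrumSharpener` | derivative-lobe recombination, twice, rescaled to the input envelope |
| blind deconvolution (1x/2x) | `BlindDeconvolver` | damped Richardson–Lucy with joint PSF estimation |
| weighted over-deconvolution | `OverDeconvolver` | nonnegative least squares against a deliberately broad Gaussian kernel, weighted by the input |
| moving-window peak fitting | `MovingWindowFitter` | seven-peak sliding simultaneous pseudo-Voigt fits, then narrowed re-rendering |
| fit-and-subtract | `IterativePeakFitter` | iterative tallest-peak Pearson VII fitting |

Alongside the methods: the synthetic nine-peak benchmark that makes
them comparable (ten stages of evolving Lorentzian peaks, blurred by a
Gaussian IPSF with sigma = 5 channels), eight figures of merit,
synchronous 2D-COS correlation maps, band-intensity contrast images,
and a command-line interface.  See `docs/methods.md` for the science
and the numerical choices.

## Worked example

```python
import ramansharp as rs

ds = rs.generate_dataset()              # truth, targets, tests (10 stages)
test1 = ds.tests[0]                     # stage-1 blurred spectrum

# the blurred spectrum fuses P6 (ch 645) and P7 (ch 656) into one band,
# hides the tiny P5, and pulls the P8-P9 maxima together
print(rs.detect_peaks(test1, lo=200, hi=900))
# [340. 465. 532. 584. 650. 803. 810.]   <- 7 bands instead of 9

enhanced = rs.ep_enhance(test1, resolution=9, alignment=0)
print(rs.detect_peaks(enhanced, lo=200, hi=900))
# [340. 465. 532. 584. 617. 642. 659. 797. 816.]  <- 9 bands, doublet split

est = rs.PseudospectrumSharpener(resolution=9)
resolved = est.fit(ds.tests.intensities).transform(ds.tests.intensities)
metrics = rs.evaluate_set(rs.SpectrumSet(ds.axis, resolved), ds)
print(metrics)
# ResolutionMetrics(rmse_all=0.1022, sep2=0.6404, red_w=0.9759,
#                   n_peaks_delta=0, n_wrong_positions=4,
#                   mean_position_deviation=1.44,
#                   corr_p6_truth=0.9745, corr_p6_p7=0.5820)
```

Reading the numbers: the enhanced set counts the correct nine peaks
(`n_peaks_delta=0`) and recovers 64% of the target's P8–P9 valley depth
(`sep2`); widths shrink only slightly versus the target (`red_w` near
1 means the resolved P1 is nearly as narrow as the unblurred one); four
peaks land more than one channel from their true positions, but only by
~1.4 channels on average; and the stage profile of the decaying P6
correlates at 0.97 with its ground truth while remaining partially
coupled to its constant neighbor P7 (0.58).

The same comparison across methods reproduces their characteristic
trade-offs: node narrowing narrows P1 but cannot split the fused P6–P7
band; a single blind deconvolution pass leaves it fused while a second
pass splits it at the cost of satellite peaks; over-deconvolution
splits it with near-equal heights but suppresses the smallest peaks;
the moving-window fitter records all nine peaks and can be re-rendered
at one-third width.

From the shell:

```sh
ramansharp generate --outdir bench/
ramansharp enhance --method ep --resolution 9 --input spectrum.csv --output enhanced.csv
ramansharp sweep --method nn --param1 alpha --values1 0.5,1,2 \
                 --param2 lam --values2 0.5,1,2 --out surfaces.csv
ramansharp twodcos --input bench/tests.csv --lo 300 --hi 700 --out sync.csv
```

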