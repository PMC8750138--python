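"""Lineshapes, starting-peak detection, both fitters, narrowed rendering."""

import numpy as np
import pytest

from ramansharp import (
    FittedPeak,
    PeakList,
    PeakSpec,
    Spectrum,
    fit_and_subtract,
    initial_peaks,
    lorentzian_profile,
    moving_window_fit,
    pearson7_profile,
    pseudo_voigt_profile,
    reconstruct_narrowed,
)


class TestPearson7:
    def test_m1_equals_lorentzian(self, axis):
        p7 = pearson7_profile(FittedPeak(500, 1.0, 6.0, 1.0, "pearson7"), axis)
        lor = lorentzian_profile(PeakSpec(500, 6.0, 1.0), axis)
        assert np.allclose(p7.intensities, lor.intensities, atol=1e-12)

    @pytest.mark.parametrize("m", [0.6, 1.0, 2.0, 10.0, 50.0])
    def test_half_maximum_at_hwhm_for_any_exponent(self, axis, m):
        p7 = pearson7_profile(FittedPeak(500, 1.0, 6.0, m, "pearson7"), axis)
        assert p7.intensities[500] == pytest.approx(1.0)
        assert p7.intensities[506] == pytest.approx(0.5)
        assert p7.intensities[494] == pytest.approx(0.5)

    def test_large_m_close_to_gaussian(self, axis):
        p7 = pearson7_profile(FittedPeak(500, 1.0, 6.0, 50.0, "pearson7"), axis)
        gauss = np.exp(-np.log(2.0) * ((axis - 500) / 6.0) ** 2)
        assert np.max(np.abs(p7.intensities - gauss)) < 0.01

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            FittedPeak(500, 1.0, 6.0, 0.3, "pearson7")

    def test_pseudo_voigt_limits(self, axis):
        peak_l = pseudo_voigt_profile(FittedPeak(500, 1.0, 6.0, 1.0), axis)
        lor = lorentzian_profile(PeakSpec(500, 6.0, 1.0), axis)
        assert np.allclose(peak_l.intensities, lor.intensities)
        peak_g = pseudo_voigt_profile(FittedPeak(500, 1.0, 6.0, 0.0), axis)
        assert peak_g.intensities[506] == pytest.approx(0.5)


class TestInitialPeaks:
    def test_two_separated_lorentzians(self, axis):
        a = lorentzian_profile(PeakSpec(300, 3, 1.0), axis)
        b = lorentzian_profile(PeakSpec(700, 3, 0.8), axis)
        s = Spectrum(axis, a.intensities + b.intensities)
        pl = initial_peaks(s, spectral_resolution=9)
        big = [p for p in pl if p.amplitude > 0.1]
        assert len(big) == 2
        assert abs(big[0].position - 300) <= 2
        assert abs(big[1].position - 700) <= 2

    def test_starting_width_is_half_resolution(self, axis):
        s = lorentzian_profile(PeakSpec(500, 3, 1.0), axis)
        pl = initial_peaks(s, spectral_resolution=9)
        assert all(p.hwhm == 4.5 for p in pl)

    def test_flat_spectrum_gives_empty_list(self):
        pl = initial_peaks(Spectrum.from_channels(np.ones(200)), 9)
        assert len(pl) == 0


class TestMovingWindowFit:
    @pytest.mark.parametrize("amp,pos,hwhm",
                             [(1.0, 500.0, 3.0), (0.5, 300.0, 6.0),
                              (2.0, 700.0, 9.0)])
    def test_single_peak_recovery(self, axis, amp, pos, hwhm):
        s = lorentzian_profile(PeakSpec(pos, hwhm, amp), axis)
        pl = moving_window_fit(s, width_max=30.0, max_shift=5.0)
        peak = max(pl, key=lambda p: p.amplitude)
        assert peak.amplitude == pytest.approx(amp, rel=1e-3)
        assert peak.position == pytest.approx(pos, abs=pos * 1e-3)
        assert peak.hwhm == pytest.approx(hwhm, rel=1e-3)

    def test_benchmark_stage1_records_nine_peaks(self, dataset):
        pl = moving_window_fit(dataset.tests[0])
        assert len(pl) == 9

    def test_each_starting_peak_recorded_once(self, dataset):
        # nine starting peaks -> window protocol must record nine results
        pl = moving_window_fit(dataset.tests[0], amplitude_floor=0.0)
        starts = initial_peaks(dataset.tests[0], 9)
        assert len(pl) == len(starts)

    def test_exactly_seven_starting_peaks_single_fit(self, axis):
        positions = np.arange(150, 850, 100, dtype=float)  # 7 peaks
        total = np.zeros_like(axis)
        for p in positions:
            total += lorentzian_profile(PeakSpec(p, 4, 1.0), axis).intensities
        pl = moving_window_fit(Spectrum(axis, total), width_max=30.0,
                               max_shift=5.0)
        assert len(pl) == 7
        assert np.allclose(pl.positions, positions, atol=0.5)


class TestFitAndSubtract:
    def test_single_peak_terminates_below_threshold(self, axis):
        s = lorentzian_profile(PeakSpec(500, 6, 1.0), axis)
        pl = fit_and_subtract(s, height_threshold=0.01)
        assert len(pl) == 1
        residual = s.intensities - pearson7_profile(pl[0], axis).intensities
        assert residual.max() < 0.01

    @pytest.mark.parametrize("amp,pos,hwhm",
                             [(1.0, 500.0, 3.0), (0.5, 300.0, 6.0),
                              (2.0, 700.0, 9.0)])
    def test_single_peak_recovery(self, axis, amp, pos, hwhm):
        s = lorentzian_profile(PeakSpec(pos, hwhm, amp), axis)
        pl = fit_and_subtract(s, height_threshold=0.01)
        peak = max(pl, key=lambda p: p.amplitude)
        assert peak.amplitude == pytest.approx(amp, rel=1e-3)
        assert peak.position == pytest.approx(pos, abs=pos * 1e-3)
        assert peak.hwhm == pytest.approx(hwhm, rel=1e-3)

    def test_all_zero_spectrum_empty_list(self):
        pl = fit_and_subtract(Spectrum.from_channels(np.zeros(100)))
        assert len(pl) == 0

    def test_large_initial_width_can_merge_fused_pair(self, axis):
        a = lorentzian_profile(PeakSpec(495, 6, 1.0), axis)
        b = lorentzian_profile(PeakSpec(505, 6, 1.0), axis)
        s = Spectrum(axis, a.intensities + b.intensities)
        pl = fit_and_subtract(s, height_threshold=0.2, initial_width=25.0)
        # the fused pair is typically absorbed into fewer peaks
        assert len(pl) <= 2


class TestReconstructNarrowed:
    def test_fraction_one_is_sum_of_profiles(self, axis):
        pl = PeakList([FittedPeak(400, 1.0, 5.0, 1.0),
                       FittedPeak(600, 0.5, 3.0, 0.3)])
        out = reconstruct_narrowed(pl, 1.0, axis)
        direct = (pseudo_voigt_profile(pl[0], axis).intensities
                  + pseudo_voigt_profile(pl[1], axis).intensities)
        assert np.allclose(out.intensities, direct)

    def test_area_parameter_invariance(self):
        # Lorentzian area pi*A*hwhm: (A/f) * (hwhm*f) == A * hwhm
        peak = FittedPeak(500, 1.0, 9.0, 1.0)
        f = 1 / 3
        narrowed = FittedPeak(peak.position, peak.amplitude / f,
                              peak.hwhm * f, peak.shape)
        assert narrowed.amplitude * narrowed.hwhm == pytest.approx(
            peak.amplitude * peak.hwhm)

    def test_gaussian_area_conserved_numerically(self, axis):
        # Gaussian tails vanish fast, so the discrete sum tracks the integral
        pl = PeakList([FittedPeak(500, 1.0, 9.0, 0.0)])
        a1 = reconstruct_narrowed(pl, 1.0, axis).intensities.sum()
        a3 = reconstruct_narrowed(pl, 1 / 3, axis).intensities.sum()
        assert a3 == pytest.approx(a1, rel=1e-9)

    def test_narrowing_deepens_valley(self, axis):
        pl = PeakList([FittedPeak(495, 1.0, 3.0, 1.0),
                       FittedPeak(506, 1.0, 3.0, 1.0)])
        wide = reconstruct_narrowed(pl, 1.0, axis).intensities
        narrow = reconstruct_narrowed(pl, 1 / 3, axis).intensities
        valley_wide = wide[495:507].min() / wide.max()
        valley_narrow = narrow[495:507].min() / narrow.max()
        assert valley_narrow < valley_wide

    def test_invalid_fraction(self, axis):
        with pytest.raises(ValueError):
            reconstruct_narrowed(PeakList([FittedPeak(5, 1, 1)]), 0.0, axis)
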