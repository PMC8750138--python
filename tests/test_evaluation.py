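"""Figures of merit and parameter sweeps."""

import numpy as np
import pytest

from ramansharp import (
    NodeNarrower,
    PeakSpec,
    Spectrum,
    SpectrumSet,
    detect_peaks,
    evaluate_set,
    lorentzian_profile,
    match_peaks,
    measure_hwhm,
    parameter_sweep,
    profile_correlations,
    rmse_region,
    separation_score,
    width_reduction_ratio,
)


class TestRmseRegion:
    def test_identity_is_zero(self, dataset):
        t = dataset.targets[0]
        assert rmse_region(t, t) == 0.0

    def test_constant_offset(self, axis):
        a = Spectrum(axis, np.zeros(1000))
        b = Spectrum(axis, np.full(1000, 0.25))
        assert rmse_region(a, b) == pytest.approx(0.25)

    def test_region_bounds_respected(self, axis):
        a = Spectrum(axis, np.zeros(1000))
        outside = np.zeros(1000)
        outside[:200] = 5.0
        outside[901:] = 5.0
        assert rmse_region(a, Spectrum(axis, outside)) == 0.0

    def test_axis_mismatch_rejected(self, axis):
        a = Spectrum(axis, np.zeros(1000))
        b = Spectrum(axis[:-1], np.zeros(999))
        with pytest.raises(ValueError):
            rmse_region(a, b)


class TestSeparationScore:
    def test_identity_is_one(self, dataset):
        t = dataset.targets[0]
        assert separation_score(t, t, 800, 813) == pytest.approx(1.0)

    def test_unresolved_bridge_is_zero(self, dataset):
        # the blurred test spectrum fuses P6-P7 into a monotone bridge
        assert separation_score(dataset.tests[0], dataset.targets[0],
                                645, 656) == 0.0

    def test_direct_arithmetic(self, axis):
        def bumps(h1, h2, valley):
            y = np.zeros(1000)
            y[395:400] = np.linspace(valley, h1, 5)
            y[400:431] = np.linspace(h1, valley, 31)
            y[430:461] = np.linspace(valley, h2, 31)
            y[460:466] = np.linspace(h2, valley, 6)
            return Spectrum(axis, y)
        resolved = bumps(0.8, 0.9, 0.2)
        target = bumps(1.0, 1.0, 0.5)
        score = separation_score(resolved, target, 400, 460)
        assert score == pytest.approx((0.8 - 0.2) / (1.0 - 0.5))


class TestMeasureHwhm:
    def test_lorentzian_definition(self, axis):
        s = lorentzian_profile(PeakSpec(500, 6, 1.0), axis)
        assert measure_hwhm(s, 500) == pytest.approx(6.0, abs=0.1)

    def test_gaussian_closed_form(self, axis):
        sigma = 8.0
        s = Spectrum(axis, np.exp(-0.5 * ((axis - 500) / sigma) ** 2))
        assert measure_hwhm(s, 500) == pytest.approx(
            sigma * np.sqrt(2 * np.log(2)), abs=0.1)

    def test_truth_p1_fwhm_is_twelve_channels(self, dataset):
        p1 = dataset.truth[0][0]
        assert 2 * measure_hwhm(p1, 340) == pytest.approx(12.0, abs=0.2)

    def test_width_reduction_identity(self, dataset):
        t = dataset.targets[0]
        assert width_reduction_ratio(t, t) == pytest.approx(1.0)

    def test_width_reduction_arithmetic(self, axis):
        narrow = lorentzian_profile(PeakSpec(340, 3, 1.0), axis)
        wide = lorentzian_profile(PeakSpec(340, 6, 1.0), axis)
        assert width_reduction_ratio(narrow, wide) == pytest.approx(0.5,
                                                                    abs=0.02)


class TestMatchPeaks:
    def test_identical_lists(self):
        pos = np.array([10.0, 20.0, 30.0])
        assert match_peaks(pos, pos) == (0, 0, 0.0)

    def test_fused_pair_counted_once(self):
        truth = np.arange(9, dtype=float) * 50 + 100
        resolved = np.delete(truth, 5)  # one of a fused pair missing
        n_delta, n_wrong, _ = match_peaks(resolved, truth)
        assert n_delta == -1
        assert n_wrong == 1  # the missing partner counts as wrong

    def test_single_shifted_peak(self):
        n_delta, n_wrong, mean_dev = match_peaks(
            np.array([103.0]), np.array([100.0]),
            tolerance=5, position_tol=1)
        assert (n_delta, n_wrong, mean_dev) == (0, 1, 3.0)


class TestProfileCorrelations:
    def test_perfect_p6_recovery(self, dataset):
        # spectra that contain only the true P6 and P7 components
        stacks = []
        for stage in range(10):
            y = (dataset.truth[stage][5].intensities
                 + dataset.truth[stage][6].intensities)
            stacks.append(y)
        sset = SpectrumSet(dataset.axis, np.vstack(stacks))
        corr_truth, _ = profile_correlations(sset, dataset.schedule)
        assert corr_truth == pytest.approx(1.0, abs=1e-3)

    def test_blurred_tests_keep_p6_p7_coupled(self, dataset):
        _, corr_pair = profile_correlations(dataset.tests, dataset.schedule)
        assert corr_pair > 0.9

    def test_reversed_series_anticorrelated(self, dataset):
        stacks = [dataset.targets.intensities[9 - k] for k in range(10)]
        sset = SpectrumSet(dataset.axis, np.vstack(stacks))
        corr_truth, _ = profile_correlations(sset, dataset.schedule)
        assert corr_truth == pytest.approx(-1.0, abs=0.01)

    def test_constant_series_undefined_not_nan(self, dataset):
        stacks = [dataset.targets.intensities[0]] * 10
        sset = SpectrumSet(dataset.axis, np.vstack(stacks))
        corr_truth, corr_pair = profile_correlations(sset, dataset.schedule)
        assert corr_truth is None and corr_pair is None


class TestEvaluateSetAndSweep:
    def test_identity_method_scores(self, dataset):
        metrics = evaluate_set(dataset.targets, dataset)
        assert metrics.rmse_all == 0.0
        assert metrics.sep2 == pytest.approx(1.0)
        assert metrics.red_w == pytest.approx(1.0)
        assert metrics.n_peaks_delta == 0
        assert metrics.n_wrong_positions == 0

    def test_detect_peaks_region_and_threshold(self, dataset):
        pos = detect_peaks(dataset.targets[0], lo=200, hi=900)
        assert np.array_equal(pos, [340, 465, 532, 584, 618, 645, 656,
                                    800, 813])

    def test_degenerate_grid_equals_single_run(self, dataset):
        grid = parameter_sweep(NodeNarrower(), "alpha", [1.0], "lam", [1.0],
                               dataset)
        out = NodeNarrower().fit(dataset.tests.intensities).transform(
            dataset.tests.intensities)
        single = evaluate_set(SpectrumSet(dataset.axis, out), dataset)
        assert grid.surfaces["rmse_all"][0, 0] == pytest.approx(
            single.rmse_all)
        assert grid.surfaces["sep2"][0, 0] == pytest.approx(single.sep2)

    def test_nn_separation_increases_with_alpha(self, dataset):
        grid = parameter_sweep(NodeNarrower(), "alpha", [0.5, 1.0, 2.0],
                               "lam", [1.0], dataset)
        sep = grid.surfaces["sep2"][:, 0]
        assert sep[0] < sep[1] < sep[2]

    def test_long_format_export(self, dataset):
        grid = parameter_sweep(NodeNarrower(), "alpha", [0.5, 1.0],
                               "lam", [1.0], dataset)
        records = grid.to_long_records()
        assert len(records) == 2 * len(grid.surfaces)
        assert {"alpha", "lam", "metric", "value"} <= set(records[0])
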