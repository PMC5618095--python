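import numpy as np
import pandas as pd
import pytest

from chromval.calibration import CalibrationModel
from chromval.exceptions import DegenerateDesignError, InvalidArgumentError
from chromval.synthetic import (DEFAULT_CALIBRATION_LEVELS, ResponseModel,
                                StudyDesign, generate_calibration_set,
                                generate_chromatogram, generate_qc_series,
                                generate_validation_study)


class TestGenerateChromatogram:
    def test_zero_input_gives_flat_zero_trace(self):
        model = ResponseModel(slope=50.0, intercept=0.0, injection_cv=0.0)
        result = generate_chromatogram(0.0, model, noise_sd=0.0)
        assert result.true_area == 0.0
        np.testing.assert_allclose(result.chromatogram.signal, 0.0)

    def test_linear_model_identity(self, clean_response):
        result = generate_chromatogram(100.0, clean_response, noise_sd=0.0)
        assert result.true_area == pytest.approx(5000.0)

    def test_monte_carlo_mean_area_matches_generative_model(self, clean_response):
        model = ResponseModel(slope=50.0, intercept=0.0, injection_cv=0.02)
        rng = np.random.default_rng(7)
        areas = [generate_chromatogram(100.0, model, rng=rng, duration=0.5,
                                       sampling_rate=10.0).true_area
                 for _ in range(1000)]
        se = 5000.0 * 0.02 / np.sqrt(len(areas))
        assert abs(np.mean(areas) - 5000.0) < 3.0 * se

    def test_argument_validation(self, clean_response):
        with pytest.raises(InvalidArgumentError):
            generate_chromatogram(100.0, clean_response, sampling_rate=0.0)
        with pytest.raises(InvalidArgumentError):
            generate_chromatogram(100.0, clean_response, sampling_rate=1.0)  # too sparse
        with pytest.raises(InvalidArgumentError):
            generate_chromatogram(-5.0, clean_response)


class TestGenerateCalibrationSet:
    def test_noise_free_responses_exactly_on_line(self):
        model = ResponseModel(slope=50.0, intercept=10.0, injection_cv=0.0)
        table = generate_calibration_set((10, 50, 100, 500, 1000), model, seed=0)
        np.testing.assert_allclose(table["response"], 50.0 * table["conc_mg_L"] + 10.0)

    def test_fixed_seed_is_bit_identical(self):
        model = ResponseModel(injection_cv=0.02)
        a = generate_calibration_set(DEFAULT_CALIBRATION_LEVELS, model, seed=42)
        b = generate_calibration_set(DEFAULT_CALIBRATION_LEVELS, model, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_refit_recovers_slope_within_three_true_se(self):
        # oracle: under multiplicative noise the slope estimator's sampling SD
        # is sqrt(sum(((x_i - xbar)/Sxx)^2 * (cv * slope * x_i)^2))
        model = ResponseModel(slope=50.0, intercept=0.0, injection_cv=0.01)
        x = np.asarray(DEFAULT_CALIBRATION_LEVELS)
        w = (x - x.mean()) / np.sum((x - x.mean()) ** 2)
        se_true = np.sqrt(np.sum(w ** 2 * (0.01 * 50.0 * x) ** 2))
        table = generate_calibration_set(DEFAULT_CALIBRATION_LEVELS, model, seed=11)
        fit = CalibrationModel.from_dataframe(table).fit()
        assert abs(fit.slope - 50.0) < 3.0 * se_true

    def test_degenerate_and_sparse_designs_rejected(self):
        model = ResponseModel()
        with pytest.raises(DegenerateDesignError):
            generate_calibration_set([100.0] * 6, model, seed=0)
        with pytest.raises(InvalidArgumentError):
            generate_calibration_set([10, 20, 30, 40], model, seed=0)


class TestGenerateValidationStudy:
    def test_noise_free_full_recovery_is_exact(self, prep):
        design = StudyDesign(true_recovery_per_level=(1.0, 1.0, 1.0),
                             within_day_cv=0.0, between_day_cv=0.0, seed=0)
        study = generate_validation_study(design, prep)
        for spike in (0.5, 1.0, 2.0):
            np.testing.assert_allclose(study.subset(spike)["measured_pct"],
                                       1.3 + spike)

    def test_partial_recovery_spike_contribution(self, prep):
        # 93.5% recovery of a 0.5 %w/w spike contributes exactly 0.4675 %w/w
        design = StudyDesign(spike_levels=(0.5,), true_recovery_per_level=(0.935,),
                             within_day_cv=0.0, between_day_cv=0.0, seed=0)
        study = generate_validation_study(design, prep)
        np.testing.assert_allclose(study.data["measured_pct"], 1.3 + 0.4675)

    def test_ground_truth_recorded(self, default_design, prep):
        study = generate_validation_study(default_design, prep, seed=1)
        assert study.truth["background_content"] == 1.3
        assert study.truth["true_content_per_level"][0] == pytest.approx(1.3 + 0.935 * 0.5)

    def test_invalid_designs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StudyDesign(spike_levels=(0.5, -1.0, 2.0))
        with pytest.raises(InvalidArgumentError):
            StudyDesign(replicates_per_day=1)
        with pytest.raises(InvalidArgumentError):
            StudyDesign(true_recovery_per_level=(2.5, 1.0, 1.0))

    def test_empirical_cv_converges_to_configured(self, prep):
        # single level, many days: moments of the simulated sample approach
        # the configured variance components (3/sqrt(n) relative tolerance)
        design = StudyDesign(spike_levels=(1.0,), true_recovery_per_level=(1.0,),
                             within_day_cv=0.03, between_day_cv=0.0,
                             days=50, replicates_per_day=10, seed=5)
        study = generate_validation_study(design, prep)
        values = study.data["measured_pct"]
        cv = values.std(ddof=1) / values.mean()
        n = len(values)
        assert abs(cv - 0.03) / 0.03 < 3.0 / np.sqrt(n)


class TestGenerateQCSeries:
    def test_zero_cv_constant_series(self):
        series = generate_qc_series(10, true_mean=2.3, cv=0.0, seed=0)
        np.testing.assert_allclose(series["measured_pct"], 2.3)
        np.testing.assert_array_equal(series["run_index"],
                                      np.arange(5, 55, 5))

    def test_fixed_seed_reproducible(self):
        a = generate_qc_series(20, seed=9)
        b = generate_qc_series(20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_gaussian_two_sigma_tail_fraction(self):
        series = generate_qc_series(10000, true_mean=2.3, cv=0.03, seed=3)
        z = (series["measured_pct"] - 2.3) / (2.3 * 0.03)
        frac = np.mean(np.abs(z) > 2.0)
        assert frac == pytest.approx(0.0455, abs=0.007)  # 2*Phi(-2)

    def test_injected_outliers_recorded_and_applied(self):
        series = generate_qc_series(10, true_mean=2.3, cv=0.02,
                                    outlier_spec={4: 4.0}, seed=1)
        clean = generate_qc_series(10, true_mean=2.3, cv=0.02, seed=1)
        shift = series["measured_pct"][4] - clean["measured_pct"][4]
        assert shift == pytest.approx(4.0 * 2.3 * 0.02)
        assert series.attrs["truth"]["outliers"] == {4: 4.0}
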