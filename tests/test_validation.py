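import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromval.exceptions import InvalidArgumentError
from chromval.sample_prep import PrepProtocol
from chromval.synthetic import StudyDesign, generate_validation_study
from chromval.validation import (ValidationStudy, ValidationStudyModel,
                                 horrat, horwitz_prsd, precision_summary,
                                 recovery)


def study_from_rows(rows):
    df = pd.DataFrame(rows, columns=["level_pct", "day", "replicate", "measured_pct"])
    return ValidationStudy(data=df, prep=PrepProtocol())


class TestHorwitz:
    @pytest.mark.parametrize("c, expected", [
        (0.01, 4.0),      # 2^(1 - 0.5*(-2)) = 2^2
        (1.0, 2.0),       # 2^1
        (0.013, 3.845),   # high-precision closed form
    ])
    def test_reproducibility_closed_form(self, c, expected):
        assert horwitz_prsd(c) == pytest.approx(expected, abs=5e-4)

    def test_repeatability_is_two_thirds_rule(self):
        assert horwitz_prsd(0.01, "repeatability") == pytest.approx(0.66 * 4.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=1e-6, max_value=0.99))
    def test_strictly_decreasing_in_concentration(self, c):
        assert horwitz_prsd(c) > horwitz_prsd(c * 1.01)

    @pytest.mark.parametrize("c", [0.0, -0.1, 1.5])
    def test_domain_enforced(self, c):
        with pytest.raises(InvalidArgumentError):
            horwitz_prsd(c)


class TestHorrat:
    def test_zero_observed_passes(self):
        result = horrat(0.0, 0.018)
        assert result.value == 0.0 and result.passes

    def test_table_value_at_total_content(self):
        # observed RSD_R 4.5% at total content 1.8 %w/w (c = 0.018)
        assert horrat(4.5, 0.018).value == pytest.approx(1.23, abs=0.01)

    def test_boundary_is_strict(self):
        limit = 2.0 * horwitz_prsd(0.02)
        result = horrat(limit, 0.02)
        assert result.value == pytest.approx(2.0)
        assert not result.passes


class TestPrecision:
    def test_identical_measurements_give_zero_rsds(self):
        study = study_from_rows([(1.0, d, r, 2.3) for d in (1, 2) for r in (1, 2, 3)])
        res = precision_summary(study, 1.0)
        assert res.rsd_r == pytest.approx(0.0)
        assert res.rsd_R == pytest.approx(0.0)

    def test_single_day_sample_sd(self):
        # replicates {9, 10, 11}: SD 1, mean 10 -> RSDr 10%, RSD_R undefined
        study = study_from_rows([(1.0, 1, r, v) for r, v in enumerate((9.0, 10.0, 11.0))])
        res = precision_summary(study, 1.0)
        assert res.rsd_r == pytest.approx(10.0)
        assert res.rsd_R is None
        assert res.n_days == 1

    def test_reproducibility_never_below_repeatability(self, rng):
        for _ in range(20):
            vals = rng.normal(10.0, 1.0, size=6)
            rows = [(1.0, d, r, vals[3 * (d - 1) + r - 1])
                    for d in (1, 2) for r in (1, 2, 3)]
            res = precision_summary(study_from_rows(rows), 1.0)
            assert res.rsd_R >= res.rsd_r - 1e-12

    def test_variance_components_recovered_from_generator(self, prep):
        design = StudyDesign(spike_levels=(1.0,), true_recovery_per_level=(1.0,),
                             within_day_cv=0.03, between_day_cv=0.02,
                             days=200, replicates_per_day=10, seed=4)
        study = generate_validation_study(design, prep)
        res = precision_summary(study, 1.0)
        assert res.rsd_r == pytest.approx(3.0, rel=0.1)
        assert res.rsd_R == pytest.approx(np.sqrt(0.03 ** 2 + 0.02 ** 2) * 100, rel=0.1)

    def test_insufficient_replication_rejected(self):
        study = study_from_rows([(1.0, 1, 1, 2.3), (1.0, 2, 1, 2.4)])
        with pytest.raises(InvalidArgumentError):
            precision_summary(study, 1.0)


class TestRecovery:
    def test_exact_fortification_gives_hundred_percent(self):
        study = study_from_rows([(0.5, 1, r, 1.8) for r in range(1, 7)])
        res = recovery(study, 0.5, background=1.3)
        assert res.mean_recovery == pytest.approx(100.0)
        assert res.sd_recovery == pytest.approx(0.0)
        assert res.acceptable

    def test_partial_recovery(self):
        # spike 0.5, recovered contribution 0.4675 -> 93.5%
        study = study_from_rows([(0.5, 1, r, 1.3 + 0.4675) for r in range(1, 7)])
        assert recovery(study, 0.5, background=1.3).mean_recovery == pytest.approx(93.5)

    def test_acceptance_band(self):
        low = study_from_rows([(1.0, 1, r, 1.3 + 0.79) for r in range(1, 4)])
        assert not recovery(low, 1.0, background=1.3).acceptable
        edge = study_from_rows([(1.0, 1, r, 1.3 + 0.80) for r in range(1, 4)])
        assert recovery(edge, 1.0, background=1.3).acceptable

    def test_zero_spike_rejected(self):
        study = study_from_rows([(0.5, 1, 1, 1.8), (0.5, 1, 2, 1.8)])
        with pytest.raises(InvalidArgumentError):
            recovery(study, 0.0, background=1.3)

    def test_estimator_unbiased_on_generator(self, prep):
        # mean of estimates over repeated studies approaches configured truth
        design = StudyDesign(seed=None)
        rng = np.random.default_rng(12)
        means = np.zeros(3)
        reps = 300
        for _ in range(reps):
            study = generate_validation_study(design, prep, rng=rng)
            model = ValidationStudyModel(study, background=1.3)
            means += np.array([r.mean_recovery for r in model.fit().recovery])
        means /= reps
        for est, truth in zip(means, (93.5, 96.7, 102.0)):
            assert est == pytest.approx(truth, abs=1.5)


class TestValidationStudyModel:
    def test_background_estimated_from_blanks(self, prep):
        design = StudyDesign(within_day_cv=0.0, between_day_cv=0.0,
                             n_blank_replicates=3, seed=0)
        study = generate_validation_study(design, prep)
        model = ValidationStudyModel(study)
        assert model.background == pytest.approx(1.3)

    def test_missing_background_rejected(self):
        study = study_from_rows([(1.0, d, r, 2.3) for d in (1, 2) for r in (1, 2, 3)])
        with pytest.raises(InvalidArgumentError):
            ValidationStudyModel(study)

    def test_spike_basis_uses_spike_concentration(self, prep):
        design = StudyDesign(within_day_cv=0.0, between_day_cv=0.0, seed=0)
        study = generate_validation_study(design, prep)
        total = ValidationStudyModel(study, background=1.3, horwitz_basis="total").fit()
        spike = ValidationStudyModel(study, background=1.3, horwitz_basis="spike").fit()
        assert total.precision[0].total_content == pytest.approx(1.8)
        assert spike.precision[0].total_content == pytest.approx(0.5)

    def test_summary_and_frames(self, prep, default_design):
        study = generate_validation_study(default_design, prep, seed=2)
        res = ValidationStudyModel(study, background=1.3).fit()
        assert len(res.precision_frame()) == 3
        assert len(res.recovery_frame()) == 3
        assert "Recovery" in res.summary()
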