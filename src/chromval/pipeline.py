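"""End-to-end orchestration of the validation study.

``run_pipeline`` sequences the full exercise behind one configuration:
simulate chromatograms for the calibration series, integrate them, fit the
external and standard-addition calibrations and test for a matrix effect,
derive LOD/LOQ in both mg/L and mg/kg, run the fortified validation study
(precision, HORRAT, recovery), build and evaluate the IQC chart, assemble
one uncertainty budget per fortification level, compute the intake
scenario, and aggregate everything into a ValidationReport with an overall
fit-for-purpose verdict.

All randomness derives from one seed through spawned substreams, so the
report is byte-identical across runs of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .calibration import CalibrationModel, CalibrationResults, compare_slopes
from .chromatogram import analyte_area
from .exceptions import ChromvalError
from .intake import IntakeScenario, daily_intake, label_check, weekly_intake
from .qc import build_chart, evaluate
from .sample_prep import PrepProtocol, extract_to_sample, sample_to_extract
from .synthetic import (DEFAULT_CALIBRATION_LEVELS, ResponseModel, StudyDesign,
                        generate_calibration_set, generate_chromatogram,
                        generate_qc_series, generate_validation_study)
from .uncertainty import (combine, u_bias, u_calibration, u_mass, u_precision,
                          u_volume)
from .validation import ValidationStudyModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ValidationReport", "run_pipeline"]


class PrepConfig(BaseModel):
    sample_mass_g: float = 0.5
    extraction_volume_ml: float = 10.0
    back_extraction_volume_ml: float = 10.0
    dilution_factor: float = 1.0

    def build(self) -> PrepProtocol:
        return PrepProtocol(**self.model_dump())


class ResponseConfig(BaseModel):
    slope: float = 45.0
    intercept: float = 0.0
    injection_cv: float = 0.01
    retention_time: float = 9.5
    peak_sigma: float = 0.05

    def build(self) -> ResponseModel:
        return ResponseModel(**self.model_dump())


class StudyConfig(BaseModel):
    background_content: float = 1.3
    spike_levels: list[float] = [0.5, 1.0, 2.0]
    days: int = 2
    replicates_per_day: int = 3
    true_recovery_per_level: list[float] = [0.935, 0.967, 1.020]
    within_day_cv: list[float] = [0.041, 0.025, 0.020]
    between_day_cv: list[float] = [0.018547236990991407,
                                   0.02304343384929307,
                                   0.009165151389911681]
    n_blank_replicates: int = 0
    horwitz_basis: str = "total"

    def build(self) -> StudyDesign:
        return StudyDesign(**self.model_dump(exclude={"horwitz_basis"}))


class CalibrationConfig(BaseModel):
    levels: list[float] = list(DEFAULT_CALIBRATION_LEVELS)
    noise_sd: float = 0.5            # baseline noise, signal units
    sampling_rate_hz: float = 10.0
    baseline_window_min: float = 0.5
    rt_tolerance_min: float = 0.1
    alpha: float = 0.05              # slope-comparison test level
    matrix_bias: float = 0.0         # relative slope change in matrix
    m_replicates: int = 1


class QCConfig(BaseModel):
    n_baseline: int = 12
    n_monitor: int = 20
    cv: float = 0.034
    true_mean: Optional[float] = None   # default: background + 1.0 %w/w spike
    fixed_sd: Optional[float] = None    # fixed-spec chart SD; bypasses baseline
    outliers: dict[int, float] = Field(default_factory=dict)


class UncertaintyConfig(BaseModel):
    balance_tolerance_g: float = 0.0005
    glassware_tolerance_ml: float = 0.02
    temp_coefficient_per_c: float = 2.1e-4   # water volumetric expansion
    temp_range_c: float = 4.0
    coverage_factor: float = 2.0
    bias_variant: str = "bias_plus_se"
    stock_standard_u_pct: float = 0.0


class IntakeConfig(BaseModel):
    content_pct: float = 1.3
    coffee_mass_per_cup_mg: float = 80.0
    cups_per_day: float = 1.0
    days_per_week: int = 7

    def build(self) -> IntakeScenario:
        return IntakeScenario(**self.model_dump())


class RunConfig(BaseModel):
    """Complete, self-consistent configuration of one pipeline run."""

    seed: int = 0
    prep: PrepConfig = Field(default_factory=PrepConfig)
    response: ResponseConfig = Field(default_factory=ResponseConfig)
    study: StudyConfig = Field(default_factory=StudyConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    uncertainty: UncertaintyConfig = Field(default_factory=UncertaintyConfig)
    intake: IntakeConfig = Field(default_factory=IntakeConfig)
    make_plots: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    """Aggregated results of one full validation run."""

    calibration: dict
    validation: dict
    qc: dict
    budgets: list[dict]
    intake: dict
    fit_for_purpose: bool
    provenance: dict

    def to_dict(self) -> dict:
        return {"calibration": self.calibration, "validation": self.validation,
                "qc": self.qc, "uncertainty_budgets": self.budgets,
                "intake": self.intake, "fit_for_purpose": self.fit_for_purpose,
                "provenance": self.provenance}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self, path=None) -> str:
        c, v, q = self.calibration, self.validation, self.qc
        lines = [
            "# Method validation report",
            "",
            f"Overall verdict: **{'fit for purpose' if self.fit_for_purpose else 'NOT fit for purpose'}**",
            "",
            "## 1. Calibration",
            f"- external slope {c['external']['slope']:.4g} "
            f"(SE {c['external']['se_slope']:.3g}), R^2 = {c['external']['r_squared']:.5f}",
            f"- slope comparison vs standard addition: t = {c['slope_comparison']['t_statistic']:.3f}, "
            f"p = {c['slope_comparison']['p_value']:.3f} -> "
            f"{'matrix effect' if c['slope_comparison']['matrix_effect'] else 'no matrix effect'}; "
            f"quantification by external calibration",
            "",
            "## 2. Detection and quantification limits",
            f"- LOD {c['lod_mg_L']:.3g} mg/L = {c['lod_mg_kg']:.3g} mg/kg",
            f"- LOQ {c['loq_mg_L']:.3g} mg/L = {c['loq_mg_kg']:.3g} mg/kg",
            "",
            "## 3. Precision (HORRAT)",
        ]
        for p in v["precision"]:
            lines.append(
                f"- level {p['level_pct']:g} %w/w: RSDr {p['rsd_r_pct']:.2f}%, "
                f"RSD_R {p['rsd_R_pct']:.2f}%, HORRAT_r {p['horrat_r']:.2f}, "
                f"HORRAT_R {p['horrat_R']:.2f} -> "
                f"{'pass' if p['acceptable'] else 'fail'}")
        lines += ["", "## 4. Recovery"]
        for r in v["recovery"]:
            lines.append(
                f"- level {r['level_pct']:g} %w/w: {r['mean_recovery_pct']:.1f}% "
                f"(SD {r['sd_recovery_pct']:.1f}, n={r['n']}) -> "
                f"{'pass' if r['acceptable'] else 'fail'}")
        lines += [
            "", "## 5. Internal quality control",
            f"- {len(q['points'])} QC results: {100 * q['warning_fraction']:.1f}% beyond warning, "
            f"{q['n_action']} beyond action, trend: {q['trend']} -> "
            f"{'under control' if q['in_control'] else 'OUT OF CONTROL'}",
            "", "## 6. Uncertainty budgets",
        ]
        for b in self.budgets:
            lines.append(f"- level {b['level_pct']:g} %w/w: u_c = {b['combined_pct']:.2f}%, "
                         f"U (k={b['coverage_factor']:g}) = {b['expanded_pct']:.2f}%")
        lines += [
            "", "## 7. Intake scenario",
            f"- daily intake {self.intake['daily_mg']:.3g} mg/day, "
            f"weekly {self.intake['weekly_reported_mg']:g} mg/week "
            f"(exact {self.intake['weekly_exact_mg']:.4g})",
            f"- extract at mean content: {self.intake['extract_conc_mg_L']:.3g} mg/L, "
            f"high-caffeine threshold exceeded: {self.intake['high_caffeine']} "
            f"(coffee exempt from labeling rule)",
            "",
            f"Provenance: config {self.provenance['config_hash']}, "
            f"seed {self.provenance['seed']}, chromval {self.provenance['version']}",
        ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _calibrate_from_chromatograms(config: RunConfig, model: ResponseModel,
                                  rng: np.random.Generator,
                                  outdir: Optional[Path]) -> CalibrationResults:
    cal = config.calibration
    areas = []
    for i, level in enumerate(cal.levels):
        result = generate_chromatogram(level, model, noise_sd=cal.noise_sd,
                                       sampling_rate=cal.sampling_rate_hz, rng=rng)
        if outdir is not None and config.make_plots:
            result.chromatogram.to_csv(outdir / f"chromatogram_cal_{i}.csv")
        areas.append(analyte_area(result.chromatogram, model.retention_time,
                                  baseline_window=cal.baseline_window_min,
                                  rt_tolerance=cal.rt_tolerance_min))
    import pandas as pd
    table = pd.DataFrame({"conc_mg_L": cal.levels, "response": areas})
    if outdir is not None:
        table.to_csv(outdir / "calibration_table.csv", index=False)
    return CalibrationModel.from_dataframe(table, mode="external").fit()


def run_pipeline(config: RunConfig, outdir=None) -> ValidationReport:
    """Execute every validation stage and aggregate the report.

    When ``outdir`` is given, all stage intermediates (CSV tables, fit and
    chart JSON, the report in Markdown and JSON) are written there; partial
    outputs are retained if a later stage fails.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(4)]
    rng_cal, rng_addn, rng_study, rng_qc = streams
    prep = config.prep.build()
    model = config.response.build()
    design = config.study.build()

    # -- stage 1: simulate + integrate + calibrate ------------------------
    stage = "calibration"
    try:
        ext_fit = _calibrate_from_chromatograms(config, model, rng_cal, outdir)
        logger.info("calibration: %d levels, slope %.4g", ext_fit.n_points, ext_fit.slope)
        addn_model = ResponseModel(
            slope=model.slope * (1.0 + config.calibration.matrix_bias),
            intercept=model.intercept, injection_cv=model.injection_cv,
            retention_time=model.retention_time, peak_sigma=model.peak_sigma)
        addn_table = generate_calibration_set(config.calibration.levels,
                                              addn_model, rng=rng_addn)
        if outdir is not None:
            addn_table.to_csv(outdir / "standard_addition_table.csv", index=False)
        addn_fit = CalibrationModel.from_dataframe(
            addn_table, mode="standard_addition").fit()
        slope_cmp = compare_slopes(ext_fit, addn_fit, alpha=config.calibration.alpha)

        lod_mg_l, loq_mg_l = ext_fit.lod(), ext_fit.loq()
        lod_sample = extract_to_sample(lod_mg_l, prep)
        loq_sample = extract_to_sample(loq_mg_l, prep)
        calibration_section = {
            "external": ext_fit.to_dict(),
            "standard_addition": addn_fit.to_dict(),
            "slope_comparison": {
                "t_statistic": slope_cmp.t_statistic, "df": slope_cmp.df,
                "p_value": slope_cmp.p_value,
                "matrix_effect": slope_cmp.matrix_effect},
            "lod_mg_L": lod_mg_l, "lod_mg_kg": lod_sample.mg_per_kg,
            "loq_mg_L": loq_mg_l, "loq_mg_kg": loq_sample.mg_per_kg,
        }
        if outdir is not None:
            ext_fit.to_json(outdir / "calibration_fit.json")

        # -- stage 2: validation study ---------------------------------
        stage = "validation"
        study = generate_validation_study(design, prep, model, rng=rng_study)
        if outdir is not None:
            study.to_csv(outdir / "validation_study.csv")
        vres = ValidationStudyModel(study, background=design.background_content,
                                    horwitz_basis=config.study.horwitz_basis).fit()
        if outdir is not None:
            vres.to_json(outdir / "validation_results.json")
            vres.precision_frame().to_csv(outdir / "precision.csv", index=False)
            vres.recovery_frame().to_csv(outdir / "recovery.csv", index=False)

        # -- stage 3: QC chart -----------------------------------------
        stage = "qc_chart"
        qc_mean = config.qc.true_mean if config.qc.true_mean is not None \
            else design.background_content + 1.0
        monitor = generate_qc_series(config.qc.n_monitor, true_mean=qc_mean,
                                     cv=config.qc.cv,
                                     outlier_spec=config.qc.outliers, rng=rng_qc)
        if config.qc.fixed_sd is not None:
            base_chart = build_chart(center=qc_mean, sd=config.qc.fixed_sd)
        else:
            baseline = generate_qc_series(config.qc.n_baseline, true_mean=qc_mean,
                                          cv=config.qc.cv, rng=rng_qc)
            base_chart = build_chart(baseline["measured_pct"])
        chart = evaluate(base_chart, monitor["measured_pct"])
        if outdir is not None:
            monitor.to_csv(outdir / "qc_series.csv", index=False)
            chart.to_json(outdir / "qc_chart.json")
            if config.make_plots:
                chart.plot(outdir / "qc_chart.png")

        # -- stage 4: uncertainty budgets ------------------------------
        stage = "uncertainty"
        ucfg = config.uncertainty
        budgets = []
        for prec, rec in zip(vres.precision, vres.recovery):
            conc = sample_to_extract(prec.total_content, prep)
            components = {
                "mass": u_mass(ucfg.balance_tolerance_g, prep.sample_mass_g),
                "volume": u_volume(ucfg.glassware_tolerance_ml,
                                   prep.back_extraction_volume_ml,
                                   ucfg.temp_coefficient_per_c, ucfg.temp_range_c),
                "calibration": u_calibration(ext_fit, conc,
                                             config.calibration.m_replicates),
                "bias": u_bias(rec, variant=ucfg.bias_variant),
                "precision": u_precision(prec),
            }
            if ucfg.stock_standard_u_pct > 0:
                components["stock_standard"] = ucfg.stock_standard_u_pct
            budget = combine(components, k=ucfg.coverage_factor)
            budgets.append({"level_pct": prec.level, **budget.to_dict()})
        if outdir is not None:
            with open(outdir / "uncertainty_budgets.json", "w") as fh:
                json.dump(budgets, fh, indent=2)

        # -- stage 5: intake -------------------------------------------
        stage = "intake"
        scenario = config.intake.build()
        weekly = weekly_intake(scenario)
        extract_conc = sample_to_extract(scenario.content_pct, prep)
        label = label_check(extract_conc)
        intake_section = {
            "daily_mg": daily_intake(scenario),
            "weekly_exact_mg": weekly.exact_mg,
            "weekly_reported_mg": weekly.reported_mg,
            "extract_conc_mg_L": extract_conc,
            "high_caffeine": label.high_caffeine,
            "label_note": label.note,
        }
    except ChromvalError as err:
        raise ChromvalError(f"pipeline stage '{stage}' failed: {err}") from err

    fit_for_purpose = (vres.all_recovery_acceptable
                       and vres.all_precision_acceptable
                       and chart.in_control)
    report = ValidationReport(
        calibration=calibration_section,
        validation=vres.to_dict(),
        qc=chart.to_dict(),
        budgets=budgets,
        intake=intake_section,
        fit_for_purpose=fit_for_purpose,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
    )
    if outdir is not None:
        report.to_json(outdir / "report.json")
        report.to_markdown(outdir / "report.md")
    return report
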