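"""Synthetic data generation with known ground truth.

Everything the validation pipeline consumes can be generated here:
chromatograms (Gaussian analyte peak on a white-noise baseline), external
calibration series, fortified validation studies with within-/between-day
variance components, and periodic QC series.

The error model is multiplicative (CV-based) throughout, because the
performance characteristics being validated are all relative SDs: an
injected response is its expectation times (1 + eps) with eps ~ N(0, cv),
and a measured content at level l on day d is

    (background + recovery_l * spike_l) * (1 + delta_{l,d}) * (1 + eps_{l,d,r})

with delta ~ N(0, between_day_cv_l) drawn once per (level, day) and eps
~ N(0, within_day_cv_l) per replicate; negative draws are truncated at
zero since content cannot be negative. Default study conditions follow the
published coffee validation design: ~1.3 %w/w background, spikes of
0.5/1.0/2.0 %w/w, triplicates on each of two days, true recoveries of
93.5/96.7/102.0% and CV pairs reproducing repeatability/reproducibility
RSDs of 4.1/4.5, 2.5/3.4 and 2.0/2.2% per level.

All generators are deterministic for a fixed seed; independent substreams
are derived with ``numpy.random.SeedSequence`` spawning so stages can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram
from .exceptions import DegenerateDesignError, InvalidArgumentError
from .sample_prep import PrepProtocol
from .validation import ValidationStudy

__all__ = [
    "ResponseModel",
    "StudyDesign",
    "ChromatogramResult",
    "generate_chromatogram",
    "generate_calibration_set",
    "generate_validation_study",
    "generate_qc_series",
    "DEFAULT_CALIBRATION_LEVELS",
]

# Six levels spanning the linear range 10-1000 mg/L.
DEFAULT_CALIBRATION_LEVELS = (10.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


@dataclass(frozen=True)
class ResponseModel:
    """Linear FID response model for the analyte.

    slope/intercept map concentration (mg/L) to peak area; injection_cv is
    the relative SD of the injected response (injection + detector
    repeatability); retention_time and peak_sigma shape the synthetic peak.
    """

    slope: float = 45.0           # area units per mg/L
    intercept: float = 0.0        # area units
    injection_cv: float = 0.01
    retention_time: float = 9.5   # minutes
    peak_sigma: float = 0.05      # minutes

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidArgumentError("slope must be positive")
        if self.injection_cv < 0:
            raise InvalidArgumentError("injection_cv must be non-negative")
        if self.peak_sigma <= 0:
            raise InvalidArgumentError("peak_sigma must be positive")

    def expected_area(self, conc_mg_l: float) -> float:
        return self.slope * conc_mg_l + self.intercept


def _per_level(value: Union[float, Sequence[float]], n: int, name: str) -> tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),) * n
    out = tuple(float(v) for v in value)
    if len(out) != n:
        raise InvalidArgumentError(f"{name} must be scalar or length {n}")
    return out


@dataclass(frozen=True)
class StudyDesign:
    """Design of a fortified validation study (defaults: the coffee study).

    between_day_cv defaults are derived per level from the target
    repeatability/reproducibility split as sqrt(RSD_R^2 - RSDr^2).
    """

    background_content: float = 1.3                     # %w/w
    spike_levels: tuple[float, ...] = (0.5, 1.0, 2.0)   # %w/w
    days: int = 2
    replicates_per_day: int = 3
    true_recovery_per_level: tuple[float, ...] = (0.935, 0.967, 1.020)
    within_day_cv: Union[float, tuple[float, ...]] = (0.041, 0.025, 0.020)
    between_day_cv: Union[float, tuple[float, ...]] = (
        0.018547236990991407, 0.02304343384929307, 0.009165151389911681)
    n_blank_replicates: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spike_levels):
            raise InvalidArgumentError("spike levels must be positive")
        if self.days < 1:
            raise InvalidArgumentError("need at least 1 day")
        if self.replicates_per_day < 2:
            raise InvalidArgumentError("need at least 2 replicates per day")
        if self.background_content < 0:
            raise InvalidArgumentError("background content must be non-negative")
        k = len(self.spike_levels)
        object.__setattr__(self, "true_recovery_per_level",
                           _per_level(self.true_recovery_per_level, k, "true_recovery_per_level"))
        object.__setattr__(self, "within_day_cv",
                           _per_level(self.within_day_cv, k, "within_day_cv"))
        object.__setattr__(self, "between_day_cv",
                           _per_level(self.between_day_cv, k, "between_day_cv"))
        if any(not 0 < r < 2 for r in self.true_recovery_per_level):
            raise InvalidArgumentError("recoveries must lie in (0, 2)")
        if any(v < 0 for v in self.within_day_cv + self.between_day_cv):
            raise InvalidArgumentError("CVs must be non-negative")


class ChromatogramResult(NamedTuple):
    chromatogram: Chromatogram
    true_area: float


def generate_chromatogram(true_conc: float, model: ResponseModel, *,
                          noise_sd: float = 0.0, sampling_rate: float = 10.0,
                          seed: Optional[int] = None,
                          duration: Optional[float] = None,
                          rng: Optional[np.random.Generator] = None) -> ChromatogramResult:
    """Simulate one injection of the analyte at ``true_conc`` mg/L.

    The analyte peak is Gaussian at the model retention time; its area is
    the linear response times a multiplicative injection error; white
    Gaussian baseline noise of SD ``noise_sd`` is added. The realised
    ground-truth area is returned alongside the trace.
    """
    if true_conc < 0:
        raise InvalidArgumentError("true_conc must be non-negative")
    if sampling_rate <= 0:
        raise InvalidArgumentError("sampling_rate must be positive")
    if sampling_rate * 60.0 * model.peak_sigma < 20:
        raise InvalidArgumentError(
            "sampling_rate too low: need >= 20 points across peak_sigma")
    rng = rng if rng is not None else np.random.default_rng(seed)
    duration = duration if duration is not None else model.retention_time + 1.0
    n = int(round(duration * 60.0 * sampling_rate)) + 1
    time = np.arange(n) / (60.0 * sampling_rate)
    eps = rng.normal(0.0, model.injection_cv) if model.injection_cv > 0 else 0.0
    true_area = max(0.0, model.expected_area(true_conc) * (1.0 + eps))
    amplitude = true_area / (model.peak_sigma * np.sqrt(2.0 * np.pi))
    signal = amplitude * np.exp(-0.5 * ((time - model.retention_time) / model.peak_sigma) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    chrom = Chromatogram(time=time, signal=signal,
                         metadata={"true_conc_mg_L": true_conc,
                                   "true_area": true_area})
    return ChromatogramResult(chromatogram=chrom, true_area=true_area)


def generate_calibration_set(levels: Sequence[float], model: ResponseModel,
                             seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate an external calibration series: one response per level.

    Responses follow the linear model with multiplicative injection noise.
    Deterministic for a fixed seed.
    """
    levels = np.asarray(levels, dtype=float)
    if np.unique(levels).size == 1:
        raise DegenerateDesignError("calibration levels are all identical")
    if np.unique(levels).size < 5:
        raise InvalidArgumentError("need at least 5 distinct calibration levels")
    rng = rng if rng is not None else np.random.default_rng(seed)
    eps = rng.normal(0.0, model.injection_cv, size=levels.size) if model.injection_cv > 0 \
        else np.zeros(levels.size)
    response = (model.slope * levels + model.intercept) * (1.0 + eps)
    return pd.DataFrame({"conc_mg_L": levels, "response": response})


def generate_validation_study(design: StudyDesign,
                              prep: Optional[PrepProtocol] = None,
                              model: Optional[ResponseModel] = None,
                              seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None) -> ValidationStudy:
    """Simulate a fortified validation study under ``design``.

    Measured content at (level, day, replicate) is the true fortified
    content times independent day-level and replicate-level relative
    errors; negative values are truncated at zero. Ground truth (including
    the exact expected content per level) is stored on the study.

    ``model`` is accepted for interface symmetry with the instrument-level
    generators; content-level noise already subsumes injection error here.
    """
    prep = prep or PrepProtocol()
    if rng is None:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for i, spike in enumerate(design.spike_levels):
        true_content = design.background_content + design.true_recovery_per_level[i] * spike
        delta = rng.normal(0.0, design.between_day_cv[i], size=design.days) \
            if design.between_day_cv[i] > 0 else np.zeros(design.days)
        for d in range(design.days):
            eps = rng.normal(0.0, design.within_day_cv[i], size=design.replicates_per_day) \
                if design.within_day_cv[i] > 0 else np.zeros(design.replicates_per_day)
            measured = true_content * (1.0 + delta[d]) * (1.0 + eps)
            for r in range(design.replicates_per_day):
                rows.append((spike, d + 1, r + 1, max(0.0, measured[r])))
    if design.n_blank_replicates > 0:
        cv = float(np.mean(design.within_day_cv))
        eps = rng.normal(0.0, cv, size=design.n_blank_replicates) if cv > 0 \
            else np.zeros(design.n_blank_replicates)
        for r in range(design.n_blank_replicates):
            rows.append((0.0, 1, r + 1,
                         max(0.0, design.background_content * (1.0 + eps[r]))))
    data = pd.DataFrame(rows, columns=["level_pct", "day", "replicate", "measured_pct"])
    truth = {
        "background_content": design.background_content,
        "spike_levels": list(design.spike_levels),
        "true_recovery_per_level": list(design.true_recovery_per_level),
        "within_day_cv": list(design.within_day_cv),
        "between_day_cv": list(design.between_day_cv),
        "true_content_per_level": [
            design.background_content + r * s
            for r, s in zip(design.true_recovery_per_level, design.spike_levels)],
    }
    return ValidationStudy(data=data, prep=prep, truth=truth)


def generate_qc_series(n_runs: int, true_mean: float = 2.3, cv: float = 0.034,
                       outlier_spec: Optional[dict[int, float]] = None,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       run_spacing: int = 5) -> pd.DataFrame:
    """Simulate the periodic QC sample, measured after every ``run_spacing``
    analytical runs.

    The default mean is the total content of the 1.0 %w/w internal QC spike
    (1.3 background + 1.0 spike) and the default CV its reproducibility RSD.
    ``outlier_spec`` maps 0-based series positions to shifts in multiples of
    the in-control SD; injected shifts are recorded in ``DataFrame.attrs``
    as ground truth.
    """
    if n_runs < 1:
        raise InvalidArgumentError("n_runs must be >= 1")
    if true_mean <= 0 or cv < 0:
        raise InvalidArgumentError("true_mean must be positive and cv non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sd = true_mean * cv
    values = true_mean + (rng.normal(0.0, sd, size=n_runs) if sd > 0 else np.zeros(n_runs))
    outliers = dict(outlier_spec or {})
    for pos, shift_sd in outliers.items():
        if not 0 <= pos < n_runs:
            raise InvalidArgumentError(f"outlier position {pos} outside series")
        values[pos] += shift_sd * sd
    out = pd.DataFrame({
        "run_index": run_spacing * np.arange(1, n_runs + 1),
        "measured_pct": values,
    })
    out.attrs["truth"] = {"true_mean": true_mean, "cv": cv,
                          "outliers": {int(k): float(v) for k, v in outliers.items()}}
    return out
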