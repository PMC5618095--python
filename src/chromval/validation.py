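"""Precision and trueness statistics for a fortified-sample validation study.

The study design is the classical one for a method without certified
reference material: coffee samples fortified at several spike levels above
the native background, each level measured in replicate within a day and
across days. From the (level, day, replicate) table this module computes

* repeatability and reproducibility RSDs via one-way ANOVA with day as the
  factor (within-day mean square -> RSDr; within + between-day variance
  components -> RSD_R, negative between-day components truncated at zero);
* the Horwitz-predicted reproducibility RSD, PRSD_R = 2^(1 - 0.5*log10 c)
  percent for analyte mass fraction c, with the repeatability prediction
  PRSD_r = 0.66 * PRSD_R;
* HORRAT ratios (observed/predicted), acceptable when strictly below 2;
* spike recovery in percent, acceptable when the mean lies in [80, 120].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .sample_prep import PrepProtocol

__all__ = [
    "ValidationStudy",
    "ValidationStudyModel",
    "ValidationResults",
    "PrecisionResult",
    "RecoveryResult",
    "HorratResult",
    "horwitz_prsd",
    "horrat",
    "precision_summary",
    "recovery",
]

HORRAT_LIMIT = 2.0
RECOVERY_BOUNDS = (80.0, 120.0)

Basis = Literal["repeatability", "reproducibility"]

_STUDY_COLUMNS = ("level_pct", "day", "replicate", "measured_pct")


@dataclass
class ValidationStudy:
    """Measurement table of a fortified-sample study plus its prep protocol.

    ``data`` is tidy with columns level_pct (spike level, %w/w; 0 for
    unspiked), day, replicate, measured_pct (measured total content, %w/w).
    ``truth`` optionally records the generating ground truth for synthetic
    studies.
    """

    data: pd.DataFrame
    prep: PrepProtocol = field(default_factory=PrepProtocol)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        missing = [c for c in _STUDY_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidArgumentError(f"study table missing columns {missing}")
        if (self.data["measured_pct"] < 0).any():
            raise InvalidArgumentError("measured contents must be non-negative")

    @property
    def spike_levels(self) -> list[float]:
        return sorted(float(v) for v in self.data["level_pct"].unique() if v > 0)

    def subset(self, level: float) -> pd.DataFrame:
        return self.data[np.isclose(self.data["level_pct"], level)]

    @classmethod
    def from_csv(cls, path, prep: Optional[PrepProtocol] = None) -> "ValidationStudy":
        return cls(data=pd.read_csv(path), prep=prep or PrepProtocol())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def horwitz_prsd(c: float, basis: Basis = "reproducibility") -> float:
    """Horwitz-predicted %RSD at analyte mass fraction ``c`` (0 < c <= 1).

    PRSD_R = 2^(1 - 0.5 * log10 c); the repeatability prediction applies the
    empirical r = 0.66 R relation. No low-concentration (Thompson) plateau is
    applied: the contents here are far above the regime where it matters.
    """
    if not 0 < c <= 1:
        raise InvalidArgumentError("mass fraction must be in (0, 1]")
    prsd_R = 2.0 ** (1.0 - 0.5 * np.log10(c))
    if basis == "reproducibility":
        return float(prsd_R)
    if basis == "repeatability":
        return float(0.66 * prsd_R)
    raise InvalidArgumentError(f"unknown basis {basis!r}")


@dataclass(frozen=True)
class HorratResult:
    value: float
    passes: bool
    basis: Basis
    mass_fraction: float


def horrat(observed_rsd: float, c: float, basis: Basis = "reproducibility") -> HorratResult:
    """HORRAT ratio: observed %RSD over the Horwitz prediction.

    Passes (precision acceptable) if and only if the ratio is strictly
    below 2.
    """
    if observed_rsd < 0:
        raise InvalidArgumentError("observed RSD must be non-negative")
    value = observed_rsd / horwitz_prsd(c, basis)
    return HorratResult(value=float(value), passes=bool(value < HORRAT_LIMIT),
                        basis=basis, mass_fraction=c)


@dataclass(frozen=True)
class PrecisionResult:
    """Per-level precision summary with HORRAT verdicts."""

    level: float            # spike level, %w/w
    total_content: float    # content used for the Horwitz prediction, %w/w
    rsd_r: float
    rsd_R: Optional[float]
    horrat_r: Optional[float]
    horrat_R: Optional[float]
    n_within: int
    n_days: int
    grand_mean: float

    @property
    def acceptable(self) -> Optional[bool]:
        if self.horrat_r is None:
            return None
        if self.horrat_R is None:
            return bool(self.horrat_r < HORRAT_LIMIT)
        return bool(self.horrat_r < HORRAT_LIMIT and self.horrat_R < HORRAT_LIMIT)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-level spike recovery summary."""

    level: float            # spike level, %w/w
    mean_recovery: float    # percent
    sd_recovery: float      # percent
    n: int

    @property
    def acceptable(self) -> bool:
        lo, hi = RECOVERY_BOUNDS
        return bool(lo <= self.mean_recovery <= hi)


def _anova_components(values_by_day: list[np.ndarray]) -> tuple[float, float, int, int]:
    """Balanced one-way variance components (within, between, n_within, days)."""
    groups = [g for g in values_by_day if g.size > 0]
    n_within = max(g.size for g in groups)
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    within_df = sum(g.size - 1 for g in groups)
    if within_df < 1:
        raise InvalidArgumentError("need >= 2 replicates within at least one day")
    msw = within_ss / within_df
    if len(groups) < 2:
        return msw, np.nan, n_within, len(groups)
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    msb = sum(g.size * (g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
    n0 = np.mean([g.size for g in groups])  # balanced designs: common size
    between = max(0.0, (msb - msw) / n0)
    return msw, between, n_within, len(groups)


def precision_summary(study: ValidationStudy, level: float,
                      total_content: Optional[float] = None) -> PrecisionResult:
    """Intra/inter-day precision at one spike level.

    ``total_content`` (background + spike, %w/w) sets the concentration for
    the Horwitz prediction; when omitted the grand mean of the measurements
    is used, which for an unbiased method is the same quantity.
    """
    sub = study.subset(level)
    if sub.empty:
        raise InvalidArgumentError(f"no measurements at level {level}")
    groups = [g["measured_pct"].to_numpy(dtype=float)
              for _, g in sub.groupby("day")]
    msw, between, n_within, n_days = _anova_components(groups)
    grand_mean = float(sub["measured_pct"].mean())
    if grand_mean <= 0:
        raise InvalidArgumentError("grand mean must be positive for an RSD")
    rsd_r = 100.0 * np.sqrt(msw) / grand_mean
    rsd_R = None if np.isnan(between) else 100.0 * np.sqrt(msw + between) / grand_mean
    content = total_content if total_content is not None else grand_mean
    c = content / 100.0  # %w/w -> mass fraction
    h_r = horrat(rsd_r, c, "repeatability").value
    h_R = None if rsd_R is None else horrat(rsd_R, c, "reproducibility").value
    return PrecisionResult(level=level, total_content=content,
                           rsd_r=float(rsd_r), rsd_R=rsd_R,
                           horrat_r=h_r, horrat_R=h_R,
                           n_within=n_within, n_days=n_days,
                           grand_mean=grand_mean)


def recovery(study: ValidationStudy, level: float, background: float) -> RecoveryResult:
    """Spike recovery at one fortification level against a background estimate.

    Per-replicate recovery is 100 * (measured_total - background) / spike;
    the mean must fall within +/-20% of the theoretical fortified content
    (i.e. in [80, 120]%) to be acceptable.
    """
    if level <= 0:
        raise InvalidArgumentError("recovery needs a positive spike level")
    if background < 0:
        raise InvalidArgumentError("background must be non-negative")
    sub = study.subset(level)
    if len(sub) < 2:
        raise InvalidArgumentError("recovery needs at least 2 measurements")
    recs = 100.0 * (sub["measured_pct"].to_numpy(dtype=float) - background) / level
    return RecoveryResult(level=level, mean_recovery=float(np.mean(recs)),
                          sd_recovery=float(np.std(recs, ddof=1)), n=len(recs))


class ValidationStudyModel:
    """Model object computing the full precision/recovery summary of a study.

    Parameters
    ----------
    study : ValidationStudy
    background : float, optional
        Native (unspiked) content, %w/w. When omitted it is estimated from
        the study's level-0 rows; a study without blanks requires an
        explicit value.
    horwitz_basis : {"total", "spike"}
        Concentration basis for the Horwitz prediction: total content
        (background + spike; the standard HORRAT convention) or the spike
        alone (robustness option for an ambiguous fortification-level
        convention).
    """

    def __init__(self, study: ValidationStudy, background: Optional[float] = None,
                 horwitz_basis: str = "total") -> None:
        if horwitz_basis not in ("total", "spike"):
            raise InvalidArgumentError("horwitz_basis must be 'total' or 'spike'")
        self.study = study
        self.horwitz_basis = horwitz_basis
        if background is None:
            blanks = study.subset(0.0)
            if blanks.empty:
                if study.truth and "background_content" in study.truth:
                    background = float(study.truth["background_content"])
                else:
                    raise InvalidArgumentError(
                        "no unspiked rows and no explicit background given")
            else:
                background = float(blanks["measured_pct"].mean())
        self.background = float(background)

    def fit(self) -> "ValidationResults":
        precision, recoveries = [], []
        for level in self.study.spike_levels:
            total = self.background + level
            content = total if self.horwitz_basis == "total" else level
            precision.append(precision_summary(self.study, level,
                                               total_content=content))
            recoveries.append(recovery(self.study, level, self.background))
        return ValidationResults(precision=precision, recovery=recoveries,
                                 background=self.background,
                                 horwitz_basis=self.horwitz_basis)


@dataclass
class ValidationResults:
    precision: list[PrecisionResult]
    recovery: list[RecoveryResult]
    background: float
    horwitz_basis: str

    @property
    def all_precision_acceptable(self) -> bool:
        return all(p.acceptable for p in self.precision)

    @property
    def all_recovery_acceptable(self) -> bool:
        return all(r.acceptable for r in self.recovery)

    def precision_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "level_pct": p.level, "total_content_pct": p.total_content,
            "rsd_r_pct": p.rsd_r, "rsd_R_pct": p.rsd_R,
            "horrat_r": p.horrat_r, "horrat_R": p.horrat_R,
            "n_within": p.n_within, "n_days": p.n_days,
            "acceptable": p.acceptable,
        } for p in self.precision])

    def recovery_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "level_pct": r.level, "mean_recovery_pct": r.mean_recovery,
            "sd_recovery_pct": r.sd_recovery, "n": r.n,
            "acceptable": r.acceptable,
        } for r in self.recovery])

    def summary(self) -> str:
        lines = [f"Validation study (background {self.background:.3g} %w/w, "
                 f"Horwitz basis: {self.horwitz_basis})",
                 "", "Precision:", self.precision_frame().to_string(index=False),
                 "", "Recovery:", self.recovery_frame().to_string(index=False)]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "background_pct": self.background,
            "horwitz_basis": self.horwitz_basis,
            "precision": self.precision_frame().to_dict(orient="records"),
            "recovery": self.recovery_frame().to_dict(orient="records"),
            "all_precision_acceptable": self.all_precision_acceptable,
            "all_recovery_acceptable": self.all_recovery_acceptable,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
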