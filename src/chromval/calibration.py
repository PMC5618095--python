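"""External and standard-addition calibration.

The calibration line is an ordinary least-squares fit of detector response
(peak area) on concentration. From it derive:

* LOD = 3.3 * SE(intercept) / slope and LOQ = 10 * SE(intercept) / slope,
  both in mg/L — the regression-based detection/quantification limits, so
  LOQ/LOD == 10/3.3 identically;
* inverse predictions with the standard s_x0 uncertainty,
  s_x0 = (s_resid/b) * sqrt(1/m + 1/n + (x0 - x_bar)^2 / Sxx);
* a two-line slope t-test used to decide whether external calibration and
  standard addition differ, i.e. whether the matrix biases the response.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateDesignError, InvalidArgumentError, InvalidFitError

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "QuantificationResult",
    "SlopeComparison",
    "fit_line",
    "compare_slopes",
]

logger = logging.getLogger(__name__)

Mode = Literal["external", "standard_addition"]


class CalibrationModel:
    """Least-squares calibration model: response ~ intercept + slope * conc.

    Parameters
    ----------
    conc : array-like
        Concentrations, mg/L. At least 3 distinct levels are required.
    response : array-like
        Detector responses (peak areas), same length.
    mode : {"external", "standard_addition"}
        Whether the standards are in pure solvent or spiked into the matrix.
    weights : {"none", "1/x"}
        Optional 1/x weighting for heteroscedastic responses; unweighted by
        default.
    """

    def __init__(self, conc, response, mode: Mode = "external",
                 weights: str = "none") -> None:
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape or conc.ndim != 1:
            raise InvalidArgumentError("conc and response must be equal-length 1-D")
        if np.unique(conc).size < 2:
            raise DegenerateDesignError("all concentrations identical")
        if np.unique(conc).size < 3 or conc.size < 3:
            raise InvalidArgumentError("need at least 3 distinct concentration levels")
        if mode not in ("external", "standard_addition"):
            raise InvalidArgumentError(f"unknown mode {mode!r}")
        if weights not in ("none", "1/x"):
            raise InvalidArgumentError("weights must be 'none' or '1/x'")
        self.conc = conc
        self.response = response
        self.mode = mode
        self.weights = weights

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, conc_col: str = "conc_mg_L",
                       response_col: str = "response", **kwargs) -> "CalibrationModel":
        return cls(table[conc_col], table[response_col], **kwargs)

    def fit(self) -> "CalibrationResults":
        X = sm.add_constant(self.conc)
        if self.weights == "1/x":
            if np.any(self.conc <= 0):
                raise InvalidArgumentError("1/x weighting requires positive conc")
            res = sm.WLS(self.response, X, weights=1.0 / self.conc).fit()
        else:
            res = sm.OLS(self.response, X).fit()
        residual_sd = float(np.sqrt(res.mse_resid))  # n-2 degrees of freedom
        with np.errstate(invalid="ignore"):  # flat response: centered TSS = 0
            rsq = float(res.rsquared)
        if not np.isfinite(rsq):  # flat response: zero total variation
            rsq = 1.0 if np.allclose(res.resid, 0.0) else 0.0
        return CalibrationResults(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            se_slope=float(res.bse[1]),
            se_intercept=float(res.bse[0]),
            residual_sd=residual_sd,
            n_points=int(self.conc.size),
            r_squared=min(max(rsq, 0.0), 1.0),
            mode=self.mode,
            conc=self.conc.copy(),
        )


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted calibration line with parameter standard errors."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    residual_sd: float
    n_points: int
    r_squared: float
    mode: Mode
    conc: np.ndarray = field(repr=False)

    @property
    def mean_conc(self) -> float:
        return float(np.mean(self.conc))

    @property
    def sxx(self) -> float:
        return float(np.sum((self.conc - self.mean_conc) ** 2))

    @property
    def conc_range(self) -> tuple[float, float]:
        return float(np.min(self.conc)), float(np.max(self.conc))

    def predict(self, conc) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(conc, dtype=float)

    def lod(self) -> float:
        """Limit of detection, mg/L: 3.3 * SE(intercept) / slope."""
        if self.slope <= 0:
            raise InvalidFitError("LOD requires a positive slope")
        return 3.3 * self.se_intercept / self.slope

    def loq(self) -> float:
        """Limit of quantification, mg/L: 10 * SE(intercept) / slope."""
        if self.slope <= 0:
            raise InvalidFitError("LOQ requires a positive slope")
        return 10.0 * self.se_intercept / self.slope

    def quantify(self, response: float, m_replicates: int = 1) -> "QuantificationResult":
        """Inverse prediction of the concentration giving ``response``.

        ``m_replicates`` is the number of averaged injections behind the
        response; it enters the 1/m leverage term of s_x0. Responses mapping
        outside the calibrated range are flagged as extrapolated, not
        rejected.
        """
        if self.mode != "external":
            raise InvalidArgumentError("quantification uses the external calibration")
        if m_replicates < 1:
            raise InvalidArgumentError("m_replicates must be >= 1")
        if self.slope == 0:
            raise InvalidFitError("cannot invert a zero slope")
        conc = (response - self.intercept) / self.slope
        s_x0 = (self.residual_sd / abs(self.slope)) * np.sqrt(
            1.0 / m_replicates + 1.0 / self.n_points
            + (conc - self.mean_conc) ** 2 / self.sxx)
        lo, hi = self.conc_range
        extrapolated = bool(conc < lo or conc > hi)
        if extrapolated:
            logger.warning("inverse prediction %.3g mg/L outside calibrated range [%g, %g]",
                           conc, lo, hi)
        return QuantificationResult(conc_mg_l=float(conc), s_x0=float(s_x0),
                                    extrapolated=extrapolated)

    def summary(self) -> str:
        lo, hi = self.conc_range
        lines = [
            f"Calibration ({self.mode}), n = {self.n_points}, "
            f"range {lo:g}-{hi:g} mg/L",
            f"  slope      {self.slope:12.5g}  (SE {self.se_slope:.4g})",
            f"  intercept  {self.intercept:12.5g}  (SE {self.se_intercept:.4g})",
            f"  residual SD {self.residual_sd:.5g}   R^2 = {self.r_squared:.6f}",
        ]
        if self.slope > 0:
            lines.append(f"  LOD = {self.lod():.4g} mg/L   LOQ = {self.loq():.4g} mg/L")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("slope", "intercept", "se_slope", "se_intercept",
              "residual_sd", "n_points", "r_squared", "mode")}
        d["conc_range"] = list(self.conc_range)
        if self.slope > 0:
            d["lod_mg_L"] = self.lod()
            d["loq_mg_L"] = self.loq()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class QuantificationResult:
    conc_mg_l: float
    s_x0: float
    extrapolated: bool


@dataclass(frozen=True)
class SlopeComparison:
    """Two-line slope comparison (matrix-effect test)."""

    t_statistic: float
    df: float
    p_value: float
    matrix_effect: bool
    alpha: float
    note: Optional[str] = None


def fit_line(table: pd.DataFrame, mode: Mode = "external",
             weights: str = "none") -> CalibrationResults:
    """Convenience wrapper: fit a calibration table (conc_mg_L, response)."""
    return CalibrationModel.from_dataframe(table, mode=mode, weights=weights).fit()


def compare_slopes(fit_a: CalibrationResults, fit_b: CalibrationResults,
                   alpha: float = 0.05, welch: bool = False) -> SlopeComparison:
    """t-test for equality of two calibration slopes.

    t = (b_a - b_b) / sqrt(SE_a^2 + SE_b^2) with df = n_a + n_b - 4 by
    default, or a Welch-Satterthwaite df when ``welch`` is set. A matrix
    effect is declared when the two-sided p-value falls below ``alpha``.
    Perfect fits (both SEs zero) cannot support a finite test; they are
    reported with an infinite-precision caveat.
    """
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    diff = fit_a.slope - fit_b.slope
    var = fit_a.se_slope ** 2 + fit_b.se_slope ** 2
    note = None
    floor = 1e-10 * max(abs(fit_a.slope), abs(fit_b.slope), 1.0)
    if np.sqrt(var) < floor:
        note = "both slope SEs are zero (perfect fits); test degenerate"
        t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
        p = 1.0 if diff == 0 else 0.0
        df = float(fit_a.n_points + fit_b.n_points - 4)
    else:
        t = diff / np.sqrt(var)
        if welch:
            df = var ** 2 / (fit_a.se_slope ** 4 / (fit_a.n_points - 2)
                             + fit_b.se_slope ** 4 / (fit_b.n_points - 2))
        else:
            df = float(fit_a.n_points + fit_b.n_points - 4)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return SlopeComparison(t_statistic=float(t), df=float(df), p_value=p,
                           matrix_effect=bool(p < alpha), alpha=alpha, note=note)
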