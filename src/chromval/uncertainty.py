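"""Eurachem/CITAC-style measurement uncertainty budget.

Five relative standard-uncertainty components are combined in quadrature:
mass (balance tolerance), dilution volume (glassware tolerance plus thermal
expansion), calibration (inverse-prediction s_x0), bias (recovery tests)
and precision (reproducibility RSD). Tolerance-type inputs are converted
with the rectangular-distribution divisor sqrt(3). The combined relative
uncertainty u_c is the root-sum-of-squares; the expanded uncertainty is
U = k * u_c with k = 2 (approximately 95% confidence).

The default bias component is u_bias = sqrt(bias^2 + SE(recovery)^2),
combining the bias magnitude with the standard error of its estimate; the
guide permits alternatives (bias magnitude alone, SE alone), selectable via
``variant``. An optional sixth component for the stock-standard reference
value is accepted and defaults to zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

from .calibration import CalibrationResults
from .exceptions import InvalidArgumentError
from .validation import PrecisionResult, RecoveryResult

__all__ = [
    "UncertaintyBudget",
    "u_mass",
    "u_volume",
    "u_calibration",
    "u_bias",
    "u_precision",
    "combine",
]

SQRT3 = math.sqrt(3.0)


def u_mass(balance_tolerance: float, sample_mass: float) -> float:
    """Relative mass uncertainty, %: rectangular balance tolerance over mass."""
    if balance_tolerance < 0 or sample_mass <= 0:
        raise InvalidArgumentError("tolerance >= 0 and mass > 0 required")
    return 100.0 * (balance_tolerance / SQRT3) / sample_mass


def u_volume(glassware_tolerance: float, volume: float,
             temp_coefficient: float = 0.0, temp_range: float = 0.0) -> float:
    """Relative dilution-volume uncertainty, %.

    Root-sum-of-squares of the rectangular glassware tolerance and a
    rectangular thermal-expansion term volume * temp_coefficient *
    temp_range, both relative to ``volume``.
    """
    if volume <= 0 or glassware_tolerance < 0:
        raise InvalidArgumentError("volume > 0 and tolerance >= 0 required")
    if temp_coefficient < 0 or temp_range < 0:
        raise InvalidArgumentError("thermal terms must be non-negative")
    glass = glassware_tolerance / SQRT3
    thermal = volume * temp_coefficient * temp_range / SQRT3
    return 100.0 * math.hypot(glass, thermal) / volume


def u_calibration(fit: CalibrationResults, conc: float, m_replicates: int = 1) -> float:
    """Relative calibration uncertainty, %: 100 * s_x0 / conc at ``conc`` mg/L."""
    if conc <= 0:
        raise InvalidArgumentError("conc must be positive")
    return 100.0 * fit.quantify(fit.predict(conc), m_replicates=m_replicates).s_x0 / conc


def u_bias(rec: RecoveryResult, variant: str = "bias_plus_se") -> float:
    """Relative bias uncertainty, %, from the recovery tests.

    Variants: 'bias_plus_se' (default) sqrt(bias^2 + SE^2) with
    bias = 100 - mean recovery and SE = sd/sqrt(n); 'bias_only' |bias|;
    'se_only' SE alone (for a bias-corrected result).
    """
    bias = 100.0 - rec.mean_recovery
    se = rec.sd_recovery / math.sqrt(rec.n)
    if variant == "bias_plus_se":
        return math.hypot(bias, se)
    if variant == "bias_only":
        return abs(bias)
    if variant == "se_only":
        return se
    raise InvalidArgumentError(f"unknown u_bias variant {variant!r}")


def u_precision(prec: PrecisionResult) -> float:
    """Relative precision uncertainty, %: the reproducibility RSD unchanged."""
    if prec.rsd_R is None:
        raise InvalidArgumentError("rsd_R undefined (single-day study)")
    return float(prec.rsd_R)


@dataclass(frozen=True)
class UncertaintyBudget:
    """Named relative uncertainty components with their quadrature combination."""

    components: dict[str, float]
    combined: float          # u_c, %
    coverage_factor: float   # k
    expanded: float          # U = k * u_c, %

    def contributions(self) -> dict[str, float]:
        """Fractional share of each component in the combined variance."""
        if self.combined == 0:
            return {k: 0.0 for k in self.components}
        return {k: (v / self.combined) ** 2 for k, v in self.components.items()}

    @property
    def mass_volume_negligible(self) -> bool:
        """True when mass + volume jointly contribute < 1% of the variance."""
        c = self.contributions()
        return c.get("mass", 0.0) + c.get("volume", 0.0) < 0.01

    def summary(self) -> str:
        shares = self.contributions()
        lines = ["Uncertainty budget (relative, %):"]
        for name, value in self.components.items():
            lines.append(f"  {name:<12} {value:7.3f}   ({100 * shares[name]:5.1f}% of variance)")
        lines.append(f"  combined u_c {self.combined:7.3f}")
        lines.append(f"  expanded U   {self.expanded:7.3f}   (k = {self.coverage_factor:g})")
        if self.mass_volume_negligible:
            lines.append("  note: mass and volume contributions are negligible (<1% jointly)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"components": dict(self.components),
                "contributions": self.contributions(),
                "combined_pct": self.combined,
                "coverage_factor": self.coverage_factor,
                "expanded_pct": self.expanded,
                "mass_volume_negligible": self.mass_volume_negligible}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def combine(components: Mapping[str, float], k: float = 2.0) -> UncertaintyBudget:
    """Combine named relative uncertainties in quadrature.

    combined = sqrt(sum of squares); expanded = k * combined.
    """
    if k <= 0:
        raise InvalidArgumentError("coverage factor k must be positive")
    comps = {str(name): float(v) for name, v in components.items()}
    if any(v < 0 for v in comps.values()):
        raise InvalidArgumentError("components must be non-negative")
    combined = math.sqrt(sum(v * v for v in comps.values()))
    return UncertaintyBudget(components=comps, combined=combined,
                             coverage_factor=float(k), expanded=float(k) * combined)
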