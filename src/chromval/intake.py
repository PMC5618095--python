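"""Dietary caffeine-intake arithmetic and the EU labeling-threshold check.

Intake follows directly from the measured grain content: a cup brewed from
``coffee_mass_per_cup`` mg of coffee at ``content`` %w/w caffeine delivers
content/100 * mass per cup. The per-cup coffee mass defaults to 80 mg —
the figure used in the source intake scenario, unusually small for a real
cup (a typical serving uses several grams of grounds) — and is overridable.

Beverages over 150 mg/L caffeine must be labeled "high caffeine content";
coffee itself is exempt from that rule, which the result annotates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .exceptions import InvalidArgumentError

__all__ = [
    "IntakeScenario",
    "WeeklyIntake",
    "LabelCheck",
    "daily_intake",
    "weekly_intake",
    "label_check",
    "round_sig",
]

LABEL_THRESHOLD_MG_L = 150.0


@dataclass(frozen=True)
class IntakeScenario:
    """Consumption scenario for intake arithmetic."""

    content_pct: float = 1.3           # caffeine in grains, %w/w
    coffee_mass_per_cup_mg: float = 80.0
    cups_per_day: float = 1.0
    days_per_week: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.content_pct <= 100:
            raise InvalidArgumentError("content must be in (0, 100] %w/w")
        for name in ("coffee_mass_per_cup_mg", "cups_per_day", "days_per_week"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be positive")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (7.28 -> 7.3 at sig=2)."""
    if x == 0:
        return 0.0
    return round(x, sig - int(math.floor(math.log10(abs(x)))) - 1)


def daily_intake(scenario: IntakeScenario) -> float:
    """Caffeine intake in mg/day: content fraction x cup mass x cups."""
    return (scenario.content_pct / 100.0) * scenario.coffee_mass_per_cup_mg \
        * scenario.cups_per_day


class WeeklyIntake(NamedTuple):
    exact_mg: float
    reported_mg: float  # rounded to 2 significant figures


def weekly_intake(scenario: IntakeScenario) -> WeeklyIntake:
    """Caffeine intake in mg/week, exact and rounded to 2 s.f. for reporting."""
    exact = daily_intake(scenario) * scenario.days_per_week
    return WeeklyIntake(exact_mg=exact, reported_mg=round_sig(exact, 2))


class LabelCheck(NamedTuple):
    high_caffeine: bool
    note: str


def label_check(beverage_conc_mg_l: float) -> LabelCheck:
    """EU high-caffeine labeling rule: strictly over 150 mg/L triggers it.

    Coffee, tea and cocoa are exempt from the rule; the annotation records
    this so the flag is not misread as a coffee labeling requirement.
    """
    if beverage_conc_mg_l < 0:
        raise InvalidArgumentError("concentration must be non-negative")
    return LabelCheck(
        high_caffeine=bool(beverage_conc_mg_l > LABEL_THRESHOLD_MG_L),
        note="threshold applies to energy drinks; coffee, tea and cocoa are exempt")
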