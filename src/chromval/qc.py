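"""Shewhart internal-quality-control (IQC) chart for the periodic QC sample.

The chart carries a center line with warning limits at +/-2 SD and action
limits at +/-3 SD. The system is declared in control when no more than 5%
of the evaluated values exceed the warning limits AND none exceed the
action limits. A 7-point run rule (consecutive points on one side of
center) is reported as an advisory trend flag only; it does not enter the
verdict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (DegenerateBaselineError, InsufficientBaselineError,
                         InvalidArgumentError)

__all__ = ["ControlChart", "build_chart", "evaluate"]

WARNING_MULTIPLE = 2.0
ACTION_MULTIPLE = 3.0
WARNING_FRACTION_LIMIT = 0.05
TREND_RUN_LENGTH = 7
MIN_BASELINE_POINTS = 8


@dataclass
class ControlChart:
    """Shewhart chart state: limits, evaluated points and per-point flags."""

    center: float
    sd: float
    points: np.ndarray = field(default_factory=lambda: np.array([]))
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DegenerateBaselineError("chart SD must be positive")
        self.points = np.asarray(self.points, dtype=float)

    @property
    def warning_limits(self) -> tuple[float, float]:
        return (self.center - WARNING_MULTIPLE * self.sd,
                self.center + WARNING_MULTIPLE * self.sd)

    @property
    def action_limits(self) -> tuple[float, float]:
        return (self.center - ACTION_MULTIPLE * self.sd,
                self.center + ACTION_MULTIPLE * self.sd)

    @property
    def warning_fraction(self) -> float:
        """Fraction of evaluated points beyond the warning limits."""
        if not self.flags:
            return 0.0
        return sum(f != "ok" for f in self.flags) / len(self.flags)

    @property
    def n_action(self) -> int:
        return sum(f == "action" for f in self.flags)

    @property
    def in_control(self) -> bool:
        """Two-rule verdict: <= 5% beyond warning AND none beyond action."""
        return (self.warning_fraction <= WARNING_FRACTION_LIMIT
                and self.n_action == 0)

    @property
    def trend(self) -> bool:
        """Advisory: >= 7 consecutive points strictly on one side of center."""
        run = 0
        last = 0
        for x in self.points:
            side = 1 if x > self.center else (-1 if x < self.center else 0)
            if side != 0 and side == last:
                run += 1
            else:
                run = 1 if side != 0 else 0
            last = side
            if run >= TREND_RUN_LENGTH:
                return True
        return False

    def _flag(self, x: float) -> str:
        dev = abs(x - self.center)
        if dev > ACTION_MULTIPLE * self.sd:
            return "action"
        if dev > WARNING_MULTIPLE * self.sd:
            return "warning"
        return "ok"

    def plot(self, path=None, ax=None):
        """Render the chart with center/warning/action lines (matplotlib)."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        x = np.arange(1, len(self.points) + 1)
        ax.plot(x, self.points, "o-", color="tab:blue", label="QC results")
        ax.axhline(self.center, color="black", label="center")
        for lim in self.warning_limits:
            ax.axhline(lim, color="tab:orange", linestyle="--", label="warning")
        for lim in self.action_limits:
            ax.axhline(lim, color="tab:red", linestyle=":", label="action")
        handles, labels = ax.get_legend_handles_labels()
        seen: dict[str, object] = {}
        for h, l in zip(handles, labels):
            seen.setdefault(l, h)
        ax.legend(seen.values(), seen.keys(), loc="best", fontsize=8)
        ax.set_xlabel("QC measurement")
        ax.set_ylabel("content (%w/w)")
        ax.set_title(f"IQC chart ({'in control' if self.in_control else 'OUT OF CONTROL'})")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax

    def to_dict(self) -> dict:
        return {"center": self.center, "sd": self.sd,
                "warning_limits": list(self.warning_limits),
                "action_limits": list(self.action_limits),
                "points": self.points.tolist(), "flags": list(self.flags),
                "warning_fraction": self.warning_fraction,
                "n_action": self.n_action,
                "in_control": self.in_control, "trend": self.trend}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_chart(baseline_points: Optional[Sequence[float]] = None,
                center: Optional[float] = None,
                sd: Optional[float] = None) -> ControlChart:
    """Build a chart from baseline QC data or a fixed (center, sd) spec.

    Estimating from data requires at least 8 baseline points with non-zero
    spread; a fixed spec bypasses the baseline requirement.
    """
    if center is not None and sd is not None:
        return ControlChart(center=float(center), sd=float(sd))
    if baseline_points is None:
        raise InvalidArgumentError("need baseline points or a fixed center/sd spec")
    pts = np.asarray(baseline_points, dtype=float)
    if pts.size < MIN_BASELINE_POINTS:
        raise InsufficientBaselineError(
            f"need >= {MIN_BASELINE_POINTS} baseline points, got {pts.size}")
    est_sd = float(np.std(pts, ddof=1))
    if est_sd == 0:
        raise DegenerateBaselineError("baseline has zero spread")
    return ControlChart(center=float(np.mean(pts)), sd=est_sd)


def evaluate(chart: ControlChart, new_points: Sequence[float]) -> ControlChart:
    """Flag each new point against the chart limits and update the verdict.

    Returns a new chart carrying all evaluated points, their flags, and the
    in-control verdict over the full evaluated series.
    """
    pts = np.asarray(new_points, dtype=float)
    all_points = np.concatenate([chart.points, pts])
    updated = ControlChart(center=chart.center, sd=chart.sd, points=all_points,
                           flags=list(chart.flags))
    updated.flags.extend(updated._flag(x) for x in pts)
    return updated
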