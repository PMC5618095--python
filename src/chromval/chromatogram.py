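"""Chromatogram handling: baseline estimation, peak detection, trapezoidal
integration and retention-time matching.

A chromatogram is a time/signal trace from one injection. The quantification
chain is: estimate and subtract the baseline, detect candidate peaks, match
the analyte peak by retention time, integrate it by the trapezoid rule. The
integrated area is the response the calibration consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .exceptions import InvalidArgumentError

__all__ = [
    "Chromatogram",
    "Peak",
    "estimate_baseline",
    "subtract_baseline",
    "detect_peaks",
    "integrate_peak",
    "match_analyte",
    "analyte_area",
]

logger = logging.getLogger(__name__)


@dataclass
class Chromatogram:
    """A single-injection time/signal trace.

    time is in minutes and must be strictly increasing; signal is in
    detector units. At least 10 points are required.
    """

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise InvalidArgumentError("time and signal must be 1-D")
        if self.time.size != self.signal.size:
            raise InvalidArgumentError("time and signal must have equal length")
        if self.time.size < 10:
            raise InvalidArgumentError("chromatogram needs at least 10 points")
        if not np.all(np.diff(self.time) > 0):
            raise InvalidArgumentError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def sampling_interval(self) -> float:
        """Median spacing between samples, minutes."""
        return float(np.median(np.diff(self.time)))

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    @classmethod
    def from_csv(cls, path) -> "Chromatogram":
        df = pd.read_csv(path)
        if not {"time_min", "signal"} <= set(df.columns):
            raise InvalidArgumentError(
                f"{path}: expected columns time_min, signal; got {list(df.columns)}")
        return cls(time=df["time_min"].to_numpy(), signal=df["signal"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "signal": self.signal}).to_csv(path, index=False)


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak (times in minutes, area in signal*min)."""

    apex_time: float
    start_time: float
    end_time: float
    height: float
    area: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start_time < self.apex_time < self.end_time):
            raise InvalidArgumentError("peak bounds must bracket the apex")
        if self.area < 0:
            raise InvalidArgumentError("peak area must be non-negative")


def estimate_baseline(chrom: Chromatogram, window: float = 0.5) -> np.ndarray:
    """Estimate the baseline by morphological opening followed by smoothing.

    A rolling minimum of width ``window`` (minutes) erases peaks narrower
    than the window, a rolling maximum restores ramps and slow drift, and a
    rolling mean smooths the residual staircase. The result never exceeds
    the signal by more than the smoothing tolerance.

    Parameters
    ----------
    chrom : Chromatogram
    window : float
        Structuring width in minutes; must exceed the sampling interval and
        comfortably exceed the analyte peak width, while staying below the
        trace span.
    """
    dt = chrom.sampling_interval
    if window <= dt:
        raise InvalidArgumentError("baseline window must exceed the sampling interval")
    if window > chrom.span:
        raise InvalidArgumentError("baseline window exceeds the trace span")
    n = max(3, int(round(window / dt)))
    opened = ndimage.maximum_filter1d(
        ndimage.minimum_filter1d(chrom.signal, size=n, mode="nearest"),
        size=n, mode="nearest")
    return ndimage.uniform_filter1d(opened, size=n, mode="nearest")


def subtract_baseline(chrom: Chromatogram, window: float = 0.5) -> Chromatogram:
    """Return a baseline-corrected copy of the chromatogram."""
    corrected = chrom.signal - estimate_baseline(chrom, window=window)
    return Chromatogram(time=chrom.time.copy(), signal=corrected,
                        metadata={**chrom.metadata, "baseline_corrected": True})


def _walk_to_boundary(y: np.ndarray, apex: int, step: int, limit: int, floor: float) -> int:
    """Walk from the apex toward ``limit`` until the signal returns to
    baseline (drops to ``floor``) or a valley between peaks is reached."""
    j = apex
    half = 0.5 * y[apex]
    while j != limit:
        nxt = j + step
        if y[nxt] <= floor:
            return nxt
        if y[nxt] > y[j] and y[j] < half:  # rising again past half-height
            return j
        j = nxt
    return limit


def detect_peaks(chrom: Chromatogram, min_height: float,
                 boundary_fraction: float = 0.01) -> list[Peak]:
    """Detect local maxima above ``min_height`` on a baseline-corrected trace.

    Peak boundaries are placed where the signal returns to the local
    baseline (falls below ``boundary_fraction`` of the apex height) or at
    the valley separating adjacent peaks. Peaks are returned sorted by apex
    time with their trapezoid areas pre-computed.
    """
    y = chrom.signal
    idx, _ = sps.find_peaks(y, height=min_height)
    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        left_limit = int(idx[k - 1]) if k > 0 else 0
        right_limit = int(idx[k + 1]) if k + 1 < len(idx) else len(y) - 1
        floor = boundary_fraction * y[apex]
        lo = _walk_to_boundary(y, apex, -1, left_limit, floor)
        hi = _walk_to_boundary(y, apex, +1, right_limit, floor)
        if not (lo < apex < hi):
            continue
        peak = Peak(apex_time=float(chrom.time[apex]),
                    start_time=float(chrom.time[lo]),
                    end_time=float(chrom.time[hi]),
                    height=float(y[apex]))
        peaks.append(Peak(apex_time=peak.apex_time, start_time=peak.start_time,
                          end_time=peak.end_time, height=peak.height,
                          area=integrate_peak(chrom, peak)))
    return peaks


def integrate_peak(chrom: Chromatogram, peak: Peak) -> float:
    """Trapezoid-rule area of ``peak`` on a baseline-corrected trace.

    Negative samples are clipped at zero before integration so the area is
    non-negative by construction.
    """
    if peak.start_time < chrom.time[0] or peak.end_time > chrom.time[-1]:
        raise InvalidArgumentError("peak bounds fall outside the trace")
    mask = (chrom.time >= peak.start_time) & (chrom.time <= peak.end_time)
    y = np.clip(chrom.signal[mask], 0.0, None)
    return float(np.trapezoid(y, chrom.time[mask]))


def match_analyte(peaks: list[Peak], expected_rt: float,
                  tolerance: float = 0.1) -> Optional[Peak]:
    """Pick the peak whose apex is nearest ``expected_rt`` within ``tolerance``.

    Returns None when no peak qualifies. When two candidates are equidistant
    the larger-area peak wins (logged), since the analyte is assumed to be
    the dominant peak near its retention time.
    """
    if tolerance <= 0:
        raise InvalidArgumentError("tolerance must be positive")
    candidates = [p for p in peaks if abs(p.apex_time - expected_rt) <= tolerance]
    if not candidates:
        return None
    best_dist = min(abs(p.apex_time - expected_rt) for p in candidates)
    nearest = [p for p in candidates
               if abs(abs(p.apex_time - expected_rt) - best_dist) < 1e-9]
    if len(nearest) > 1:
        logger.info("retention-time tie at %.3f min; choosing larger area", expected_rt)
        return max(nearest, key=lambda p: p.area)
    return nearest[0]


def analyte_area(chrom: Chromatogram, expected_rt: float, *,
                 baseline_window: float = 0.5, min_height: float = 0.0,
                 rt_tolerance: float = 0.1) -> float:
    """Full trace-to-area chain for one injection.

    Baseline-correct, detect, match by retention time, and return the
    analyte peak area; 0.0 when no peak is found (signal below detection).
    """
    corrected = subtract_baseline(chrom, window=baseline_window)
    floor = min_height if min_height > 0 else 3.0 * _noise_sd(corrected.signal)
    peaks = detect_peaks(corrected, min_height=floor)
    peak = match_analyte(peaks, expected_rt, tolerance=rt_tolerance)
    return peak.area if peak is not None else 0.0


def _noise_sd(y: np.ndarray) -> float:
    # robust noise scale from first differences; 1.4826*MAD/sqrt(2)
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)) or 1e-12
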