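"""Longitudinal bookkeeping for monthly energy-constancy QA.

Each monthly measurement is reduced to percent deviations from the
commissioning baseline for both the slope and the ratio statistic, assigned
a pass / warning / action status against configurable thresholds (defaults
2% and 4% on the absolute slope change), screened for statistical outliers
with Z-scores, and summarized per energy so the stability of the two
methods can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .slope import (
    ACTION_LEVEL,
    WARNING_LEVEL,
    SlopePoints,
    SlopeReading,
    ratio_method,
    relative_change,
)

__all__ = [
    "Baseline",
    "QARecord",
    "TrendSummary",
    "status_for_change",
    "evaluate_record",
    "zscore_screen",
    "summarize",
    "detect_drift",
]

#: |Z| above which a point is flagged as a statistical outlier
Z_FLAG = 2.0


@dataclass(frozen=True)
class Baseline:
    """Commissioning baseline for one beam energy."""

    energy_label: float  # MeV nominal
    points: SlopePoints
    i50_depth: float  # cm, commissioned I50 (the ratio method's deep point)
    slope_m: float  # %/cm, baseline slope
    ratio: float  # baseline d_max / I50-depth reading ratio

    def __post_init__(self):
        if self.slope_m >= 0:
            raise InvalidInputError("baseline slope must be negative")
        if self.ratio <= 0:
            raise InvalidInputError("baseline ratio must be positive")


@dataclass(frozen=True)
class QARecord:
    """One dated constancy measurement with its baseline deviations."""

    date: str  # ISO calendar date or month label
    energy_label: float  # MeV nominal
    slope_m: float  # %/cm
    ratio: float
    slope_change: float  # % from baseline
    ratio_change: float  # % from baseline
    status: str  # pass | warning | action
    z_score: float = float("nan")  # filled in by zscore_screen over a series


@dataclass(frozen=True)
class TrendSummary:
    """Spread statistics of one method's % changes over a QA series."""

    method: str  # slope | ratio
    mean: float  # %
    sd: float  # %, sample (n-1) standard deviation
    count: int
    outlier_indices: tuple[int, ...] = ()

    def __post_init__(self):
        if self.count < 2:
            raise InvalidInputError("a trend summary needs at least 2 records")


def status_for_change(
    slope_change: float,
    warning: float = WARNING_LEVEL,
    action: float = ACTION_LEVEL,
) -> str:
    """Classify an absolute slope change into pass / warning / action.

    The bands partition the real line: |x| < warning is a pass,
    warning <= |x| < action a warning, |x| >= action an action.
    """
    if not 0 < warning < action:
        raise ConfigurationError("thresholds must satisfy 0 < warning < action")
    x = abs(slope_change)
    if x < warning:
        return "pass"
    if x < action:
        return "warning"
    return "action"


def evaluate_record(
    date: str,
    reading_ref: float,
    reading_70: float,
    reading_30: float,
    reading_i50depth: float,
    baseline: Baseline | None,
    warning: float = WARNING_LEVEL,
    action: float = ACTION_LEVEL,
) -> QARecord:
    """Reduce one month's raw readings to a QA record.

    The three slope-method readings (reference, 70%, 30% depths) yield the
    monthly slope; the reference (d_max) and I50-depth readings yield the
    traditional ratio.  Both are compared to the baseline and the record is
    flagged on the slope change.
    """
    if baseline is None:
        raise ConfigurationError("no baseline configured for this energy")
    sr = SlopeReading.from_readings(reading_ref, reading_70, reading_30, baseline.points)
    slope_change = relative_change(sr.slope_m, baseline.slope_m)
    ratio_change = ratio_method(reading_ref, reading_i50depth, baseline.ratio)
    return QARecord(
        date=date,
        energy_label=baseline.energy_label,
        slope_m=sr.slope_m,
        ratio=reading_ref / reading_i50depth,
        slope_change=slope_change,
        ratio_change=ratio_change,
        status=status_for_change(slope_change, warning, action),
    )


def zscore_screen(
    changes: Sequence[float], flag_at: float = Z_FLAG
) -> tuple[np.ndarray, np.ndarray]:
    """Z-scores of a series of % changes and outlier flags at |Z| > flag_at.

    Uses the sample (n-1) standard deviation.  A constant series has zero
    spread; its Z-scores are defined as 0 and nothing is flagged.
    """
    x = np.asarray(changes, dtype=float)
    if x.size < 3:
        raise InvalidInputError("Z screening needs at least 3 points")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return z, np.abs(z) > flag_at


def summarize(
    changes: Sequence[float],
    method: str,
    exclude: Sequence[int] = (),
) -> TrendSummary:
    """Mean and sample SD of a method's % changes, with Z outlier flags.

    ``exclude`` lists record indices to drop before summarizing — e.g. a
    known drift period that would otherwise dominate the spread.  Excluded
    indices are dropped from the outlier screen as well; reported outlier
    indices refer to positions in the original series.
    """
    x = np.asarray(changes, dtype=float)
    excl = set(int(i) for i in exclude)
    bad = [i for i in excl if not 0 <= i < x.size]
    if bad:
        raise InvalidInputError(f"exclude indices out of range: {bad}")
    keep = np.array([i for i in range(x.size) if i not in excl], dtype=int)
    kept = x[keep]
    if kept.size < 2:
        raise InvalidInputError("fewer than 2 records left after exclusions")
    if kept.size >= 3:
        _, flags = zscore_screen(kept)
        outliers = tuple(int(keep[i]) for i in np.flatnonzero(flags))
    else:
        outliers = ()
    return TrendSummary(
        method=method,
        mean=float(kept.mean()),
        sd=float(np.std(kept, ddof=1)),
        count=int(kept.size),
        outlier_indices=outliers,
    )


def detect_drift(
    changes: Sequence[float],
    window: int = 3,
    level: float = WARNING_LEVEL,
) -> tuple[bool, int | None]:
    """Flag a sustained drift: ``window`` consecutive records beyond the
    warning level with a common sign.

    Returns ``(flag, onset_index)`` where the onset is the first record of
    the earliest qualifying run, or ``(False, None)``.
    """
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    x = np.asarray(changes, dtype=float)
    run_start, run_sign, run_len = None, 0, 0
    for i, v in enumerate(x):
        s = 1 if v >= level else (-1 if v <= -level else 0)
        if s != 0 and s == run_sign:
            run_len += 1
        elif s != 0:
            run_start, run_sign, run_len = i, s, 1
        else:
            run_start, run_sign, run_len = None, 0, 0
        if run_len >= window:
            return True, run_start
    return False, None
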