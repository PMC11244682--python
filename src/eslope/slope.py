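"""The slope method for electron beam energy constancy.

The monthly statistic is the secant slope of the percent-depth-ionization
curve between the commissioned 70% and 30% depths,

    M = (Ion70% - Ion30%) / (d70 - d30)      [%/cm]

where the two readings are normalized (x100) to a reference reading taken on
the flat portion of the curve, usually at d_max.  Because the descent is
effectively straight around I50, M is insensitive to a common setup offset
of the chamber depth — the property that makes it more stable than the
traditional ratio of readings at d_max and the I50 depth.

Across a linac's beams, slope maps to beam quality through exponential
calibrations of the form ``target = A * exp(B * M)`` fitted to commissioning
data, one with the mean energy as target and one with I50.  The I50
calibration converts a relative slope change directly into a millimetre
shift of I50, which is what tolerance levels act on: a relative slope change
of about 2% corresponds to a 1 mm I50 shift (warning), 4% to 2 mm (action).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "SlopePoints",
    "SlopeReading",
    "CalibrationModel",
    "ToleranceEntry",
    "slope",
    "relative_change",
    "fit_exponential",
    "predict",
    "slope_from_prediction",
    "i50_shift",
    "slope_tolerance_for_shift",
    "tolerance_entry",
    "ratio_method",
    "energy_change_from_slope",
]

#: default constancy thresholds on |relative slope change|, percent
WARNING_LEVEL = 2.0
ACTION_LEVEL = 4.0


@dataclass(frozen=True)
class SlopePoints:
    """Commissioned measurement depths for one beam energy.

    ``d_ref`` is the normalization reference depth on the flat portion of the
    curve (usually d_max); ``d70``/``d30`` are the commissioned depths of the
    70% and 30% ionization levels.
    """

    d70: float  # cm
    d30: float  # cm
    d_ref: float  # cm

    def __post_init__(self):
        if not self.d_ref < self.d70 < self.d30:
            raise InvalidInputError(
                f"expected d_ref < d70 < d30, got {self.d_ref}, {self.d70}, {self.d30}"
            )


@dataclass(frozen=True)
class SlopeReading:
    """One monthly slope measurement: normalized readings and the slope."""

    ion70: float  # % of reference reading
    ion30: float  # % of reference reading
    slope_m: float  # %/cm

    def __post_init__(self):
        if not self.ion70 > self.ion30 >= 0:
            raise InvalidInputError(
                f"expected ion70 > ion30 >= 0, got {self.ion70}, {self.ion30}"
            )
        if self.slope_m >= 0:
            raise InvalidInputError("slope must be negative on a descending curve")

    @classmethod
    def from_readings(
        cls,
        reading_ref: float,
        reading_70: float,
        reading_30: float,
        points: SlopePoints,
    ) -> "SlopeReading":
        """Build a reading from three raw electrometer signals."""
        if reading_ref <= 0:
            raise InvalidInputError("reference reading must be positive")
        ion70 = 100.0 * reading_70 / reading_ref
        ion30 = 100.0 * reading_30 / reading_ref
        return cls(ion70, ion30, slope(ion70, ion30, points.d70, points.d30))


def slope(ion70: float, ion30: float, d70: float, d30: float) -> float:
    """Two-point secant slope (%/cm) between the commissioned depths."""
    if d70 == d30:
        raise InvalidInputError("d70 and d30 must differ")
    return (ion70 - ion30) / (d70 - d30)


def relative_change(m: float, m_ref: float) -> float:
    """Relative slope change from baseline, percent.

    ``100 * (m - m_ref) / |m_ref|``: with both slopes negative, a steeper
    (more negative) slope — an energy decrease — gives a negative result.
    """
    if m_ref == 0:
        raise InvalidInputError("reference slope must be nonzero")
    return 100.0 * (m - m_ref) / abs(m_ref)


@dataclass(frozen=True)
class CalibrationModel:
    """Exponential map ``target = amplitude_a * exp(rate_b * slope)``.

    ``kind`` records what the target is: beam energy in MeV (``"energy"``)
    or the I50 depth in cm (``"i50"``).  ``r_squared`` is the coefficient of
    determination of the fit on the original (linear) target scale.
    """

    amplitude_a: float  # MeV or cm
    rate_b: float  # per (%/cm)
    kind: str = "i50"
    r_squared: float = 1.0

    def __post_init__(self):
        if self.amplitude_a <= 0:
            raise InvalidInputError("amplitude must be positive")
        if self.rate_b <= 0:
            raise InvalidInputError(
                "rate must be positive: shallower (less negative) slopes "
                "correspond to higher energies and deeper I50"
            )
        if self.kind not in ("energy", "i50"):
            raise InvalidInputError("kind must be 'energy' or 'i50'")
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidInputError("r_squared must lie in [0, 1]")


def fit_exponential(
    slopes: Sequence[float], targets: Sequence[float], kind: str = "i50"
) -> CalibrationModel:
    """Fit ``target = A * exp(B * slope)`` by least squares on log(target).

    The fit is linear in ``ln(target) = ln(A) + B * slope``; the reported
    r_squared is computed on the linear scale against the fitted exponential,
    so a perfect exponential dataset yields exactly 1.
    """
    m = np.asarray(slopes, dtype=float)
    y = np.asarray(targets, dtype=float)
    if m.size != y.size or m.size < 2:
        raise InvalidInputError("need at least 2 (slope, target) pairs of equal length")
    if np.any(y <= 0):
        raise InvalidInputError("targets must be positive for an exponential fit")
    if np.unique(m).size < 2:
        raise InvalidInputError("slopes must not all coincide")
    b, log_a = np.polyfit(m, np.log(y), 1)
    fitted = np.exp(log_a + b * m)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationModel(
        amplitude_a=float(np.exp(log_a)),
        rate_b=float(b),
        kind=kind,
        r_squared=min(r2, 1.0),
    )


def predict(model: CalibrationModel, slope_m: float) -> float:
    """Target (MeV or cm) predicted for a slope value."""
    return model.amplitude_a * math.exp(model.rate_b * slope_m)


def slope_from_prediction(model: CalibrationModel, target: float) -> float:
    """Slope (%/cm) whose calibration prediction equals ``target``."""
    if target <= 0:
        raise InvalidInputError("target must be positive")
    return math.log(target / model.amplitude_a) / model.rate_b


def i50_shift(model_i50: CalibrationModel, m_ref: float, m: float) -> float:
    """I50 shift (mm) implied by a slope change, via the I50 calibration.

    Positive means I50 moved deeper (energy increase); negative, shallower.
    """
    return 10.0 * (predict(model_i50, m) - predict(model_i50, m_ref))


def slope_tolerance_for_shift(
    model_i50: CalibrationModel, m_ref: float, shift_mm: float
) -> float:
    """|relative slope change| (%) corresponding to an I50 shift in mm.

    Inverts the I50 calibration at the baseline I50 displaced by
    ``shift_mm`` and reports the absolute relative slope change.  This is
    how warning/action levels in percent are derived from millimetre
    tolerances on I50.
    """
    if shift_mm == 0:
        raise InvalidInputError("shift must be nonzero")
    if m_ref == 0:
        raise InvalidInputError("reference slope must be nonzero")
    i50_ref = predict(model_i50, m_ref)
    shifted = i50_ref + shift_mm / 10.0
    if shifted <= 0:
        raise InvalidInputError(
            f"shift of {shift_mm} mm drives I50 nonpositive ({shifted:.4f} cm)"
        )
    m_shifted = slope_from_prediction(model_i50, shifted)
    return abs(m_shifted - m_ref) / abs(m_ref) * 100.0


@dataclass(frozen=True)
class ToleranceEntry:
    """Per-energy slope-change tolerances for 1 mm and 2 mm I50 shifts."""

    energy_label: float  # MeV nominal
    pct_per_1mm: float  # % slope change for a 1 mm I50 shift
    pct_per_2mm: float  # % for 2 mm

    def __post_init__(self):
        if self.pct_per_1mm > 0:
            ratio = self.pct_per_2mm / self.pct_per_1mm
            if abs(ratio - 2.0) > 0.3:
                raise InvalidInputError(
                    f"2 mm tolerance should be about twice the 1 mm one, "
                    f"got ratio {ratio:.2f}"
                )


def tolerance_entry(
    energy_label: float,
    model_i50: CalibrationModel,
    m_ref: float,
    decimals: int = 1,
) -> ToleranceEntry:
    """Tolerance-table row for one beam: % slope change per 1 mm and 2 mm.

    Uses a deeper (positive) I50 displacement; values rounded to ``decimals``
    places for presentation.
    """
    return ToleranceEntry(
        energy_label=energy_label,
        pct_per_1mm=round(slope_tolerance_for_shift(model_i50, m_ref, 1.0), decimals),
        pct_per_2mm=round(slope_tolerance_for_shift(model_i50, m_ref, 2.0), decimals),
    )


def ratio_method(
    reading_dmax: float, reading_i50depth: float, baseline_ratio: float
) -> float:
    """Traditional constancy check: % change of the d_max / I50-depth
    reading ratio from its baseline.

    Convention: the numerator is the d_max reading, the denominator the deep
    reading near the I50 depth.
    """
    if reading_dmax <= 0 or reading_i50depth <= 0 or baseline_ratio <= 0:
        raise InvalidInputError("readings and baseline ratio must be positive")
    ratio = reading_dmax / reading_i50depth
    return 100.0 * (ratio - baseline_ratio) / baseline_ratio


def energy_change_from_slope(
    model_energy: CalibrationModel, m_ref: float, m: float
) -> float:
    """Relative beam-energy change (%) implied by a slope change.

    With an exponential calibration the predicted relative change depends
    only on the slope difference: ``100 * (exp(B * (m - m_ref)) - 1)``.
    """
    return 100.0 * (math.exp(model_energy.rate_b * (m - m_ref)) - 1.0)
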