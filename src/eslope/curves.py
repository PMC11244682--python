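"""Depth-ionization curve analysis for electron beams.

An electron percent-depth-ionization (PDI) curve in water rises through a
build-up region to a maximum at ``d_max``, falls almost linearly through the
50% depth ``I50``, and levels off in a low bremsstrahlung tail.  This module
represents measured (or simulated) scans, normalizes them to percent of
maximum, and extracts the classical range metrics:

* ``I50`` — depth of the 50% ionization level, the standard beam-quality
  specifier;
* ``Rp`` — practical range, where the extrapolated linear descent meets the
  bremsstrahlung tail;
* the depths of arbitrary ionization levels on the descending limb; and
* the 70%/30% secant gradient of the descent, the quantity the slope method
  monitors month to month.

Interpolation between samples is linear throughout: the method's premise is
that the descent is effectively straight between the 70% and 30% levels, and
linear interpolation is exact there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
    LevelNotFoundError,
    StateError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScanCurve",
    "PercentCurve",
    "CurveMetrics",
    "normalize",
    "apply_epom_shift",
    "depth_at_level",
    "i50",
    "practical_range",
    "descent_gradient",
    "analyze",
]

#: minimum number of samples for a meaningful curve
_MIN_SAMPLES = 8


@dataclass(frozen=True)
class ScanCurve:
    """A raw depth-ionization scan.

    Parameters
    ----------
    depths :
        Strictly increasing depths in cm.
    readings :
        Non-negative ionization readings, arbitrary units.
    epom_shifted :
        Whether the effective-point-of-measurement shift (0.5 x chamber
        radius toward the surface) has already been applied.
    meta :
        Free-form labels (energy label, date, chamber radius ...).
    """

    depths: np.ndarray
    readings: np.ndarray
    epom_shifted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        readings = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "readings", readings)
        if depths.ndim != 1 or readings.ndim != 1 or depths.size != readings.size:
            raise InvalidInputError("depths and readings must be 1-D and equal length")
        if depths.size < _MIN_SAMPLES:
            raise InvalidInputError(
                f"a scan needs at least {_MIN_SAMPLES} samples, got {depths.size}"
            )
        if not np.all(np.diff(depths) > 0):
            raise InvalidInputError("depths must be strictly increasing")
        if np.any(readings < 0):
            raise InvalidInputError("readings must be non-negative")
        if readings.max() <= 0:
            raise InvalidInputError("all readings are zero")
        lo, hi = _max_region(readings)
        if not np.all(readings[lo : hi + 1] == readings.max()):
            # _max_region raises if non-contiguous; this is a belt-and-braces check
            raise InvalidInputError("maximal region must be contiguous")

    def __len__(self) -> int:
        return int(self.depths.size)


@dataclass(frozen=True)
class PercentCurve:
    """A depth-ionization curve normalized to 100% at its maximum."""

    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)
        if not np.all(np.diff(depths) > 0):
            raise InvalidInputError("depths must be strictly increasing")
        if np.any(values < 0):
            raise InvalidInputError("percent values must be non-negative")
        if values.max() != 100.0:
            raise InvalidInputError("a PercentCurve must peak at exactly 100")

    @property
    def d_max(self) -> float:
        """Depth of maximum; midpoint of the maximal plateau if there is one."""
        lo, hi = _max_region(self.values)
        return float(0.5 * (self.depths[lo] + self.depths[hi]))


@dataclass(frozen=True)
class CurveMetrics:
    """Range metrics extracted from one percent-depth-ionization curve."""

    d_max: float  # cm
    i50_depth: float  # cm
    r_p: float  # cm, practical range
    level_depths: dict  # percent level -> depth cm
    descent_gradient: float  # %/cm, 70/30 secant; negative

    def __post_init__(self):
        if not (self.d_max < self.i50_depth < self.r_p):
            raise InvalidInputError(
                f"expected d_max < i50 < Rp, got {self.d_max}, "
                f"{self.i50_depth}, {self.r_p}"
            )
        if self.descent_gradient >= 0:
            raise InvalidInputError("descent gradient must be negative")


def _max_region(values: np.ndarray) -> tuple[int, int]:
    """Indices (first, last) of the maximal region; error if non-contiguous."""
    idx = np.flatnonzero(values == values.max())
    if idx[-1] - idx[0] != idx.size - 1:
        raise InvalidInputError("curve has more than one maximal region")
    return int(idx[0]), int(idx[-1])


def normalize(curve: ScanCurve | PercentCurve) -> PercentCurve:
    """Convert a raw scan to percent of its maximum reading.

    Idempotent: normalizing an already-percent curve changes nothing.
    """
    readings = curve.values if isinstance(curve, PercentCurve) else curve.readings
    peak = readings.max()
    if peak <= 0:
        raise InvalidInputError("cannot normalize an all-zero scan")
    if peak == 100.0:
        return PercentCurve(curve.depths, readings)
    # divide first: x/x == 1 exactly, so the peak lands on 100 exactly
    return PercentCurve(curve.depths, readings / peak * 100.0)


def apply_epom_shift(curve: ScanCurve, chamber_radius: float) -> ScanCurve:
    """Shift a scan toward the surface by half the chamber cavity radius.

    A cylindrical chamber's effective point of measurement sits upstream of
    its axis, so recorded depths are reduced by ``0.5 * chamber_radius`` (cm).
    Refuses to shift twice.
    """
    if curve.epom_shifted:
        raise StateError("EPOM shift already applied to this curve")
    if chamber_radius < 0:
        raise InvalidInputError("chamber radius must be >= 0")
    shifted = curve.depths - 0.5 * chamber_radius
    if shifted[0] < 0:
        logger.warning(
            "EPOM shift moved %d sample(s) above the water surface "
            "(shallowest depth %.4f cm)",
            int(np.sum(shifted < 0)),
            float(shifted[0]),
        )
    meta = dict(curve.meta)
    meta["chamber_radius_cm"] = chamber_radius
    return replace(curve, depths=shifted, epom_shifted=True, meta=meta)


def depth_at_level(pcurve: PercentCurve, level: float) -> float:
    """Depth of the first descending crossing of ``level`` (percent).

    Only the descending limb (depths beyond ``d_max``) is searched; build-up
    crossings of the same level are ignored.  Linear interpolation between
    bracketing samples; an exact grid hit returns that sample's depth.
    """
    if not 0 < level < 100:
        raise InvalidInputError("level must be strictly between 0 and 100")
    depths, values = pcurve.depths, pcurve.values
    _, hi = _max_region(values)
    for i in range(hi, len(values) - 1):
        v0, v1 = values[i], values[i + 1]
        if v0 == level:
            return float(depths[i])
        if v0 > level >= v1:
            # linear interpolation on the bracketing segment
            t = (v0 - level) / (v0 - v1)
            return float(depths[i] + t * (depths[i + 1] - depths[i]))
    if values[-1] == level:
        return float(depths[-1])
    raise LevelNotFoundError(
        f"level {level}% is never crossed on the descending limb "
        f"(tail ends at {values[-1]:.3f}%)"
    )


def i50(pcurve: PercentCurve) -> float:
    """Depth of the 50% ionization level (cm)."""
    return depth_at_level(pcurve, 50.0)


def _fit_line(depths: np.ndarray, values: np.ndarray, label: str) -> tuple[float, float]:
    if depths.size < 2:
        raise InsufficientDataError(
            f"{label} window holds {depths.size} sample(s); need at least 2"
        )
    slope, intercept = np.polyfit(depths, values, 1)
    return float(slope), float(intercept)


def practical_range(
    pcurve: PercentCurve,
    descent_window: tuple[float, float] = (70.0, 30.0),
    tail_bounds: tuple[float, float] | None = None,
) -> float:
    """Practical range Rp: intersection of the extrapolated linear descent
    with the bremsstrahlung tail (cm).

    A least-squares line is fitted through the samples between the
    ``descent_window`` level crossings (default 70%-30%), and another through
    the tail samples.  By default the tail window starts half a
    build-up-to-I50 distance beyond the 5% level crossing, deep enough to be
    clear of the electron descent; pass explicit ``tail_bounds`` (cm) to
    override when the tail level exceeds 5%.
    """
    high, low = descent_window
    if not (100 > high > low > 0):
        raise InvalidInputError("descent window must satisfy 100 > high > low > 0")
    d_hi = depth_at_level(pcurve, high)
    d_lo = depth_at_level(pcurve, low)

    depths, values = pcurve.depths, pcurve.values
    in_descent = (depths >= d_hi) & (depths <= d_lo)
    m_d, b_d = _fit_line(depths[in_descent], values[in_descent], "descent")

    if tail_bounds is None:
        d5 = depth_at_level(pcurve, 5.0)
        start = d5 + 0.5 * (i50(pcurve) - pcurve.d_max)
        in_tail = depths >= start
    else:
        in_tail = (depths >= tail_bounds[0]) & (depths <= tail_bounds[1])
    m_t, b_t = _fit_line(depths[in_tail], values[in_tail], "tail")

    if abs(m_d - m_t) <= 1e-9 * max(abs(m_d), abs(m_t), 1.0):
        raise DegenerateFitError("descent and tail fits are parallel")
    rp = (b_t - b_d) / (m_d - m_t)
    if rp <= d_lo:
        raise DegenerateFitError(
            f"descent/tail intersection at {rp:.4f} cm is not beyond the "
            f"{low:.0f}% depth ({d_lo:.4f} cm)"
        )
    return float(rp)


def descent_gradient(
    pcurve: PercentCurve, levels: tuple[float, float] = (70.0, 30.0)
) -> float:
    """Secant gradient of the descending limb between two levels (%/cm).

    Default levels 70/30 give the slope tangent to the curve at I50; always
    negative on a physical curve.
    """
    high, low = levels
    d_hi = depth_at_level(pcurve, high)
    d_lo = depth_at_level(pcurve, low)
    if d_hi == d_lo:
        raise InvalidInputError("level depths coincide; gradient undefined")
    return float((high - low) / (d_hi - d_lo))


def analyze(
    curve: ScanCurve | PercentCurve,
    levels: tuple[float, ...] = (70.0, 50.0, 30.0),
    tail_bounds: tuple[float, float] | None = None,
) -> CurveMetrics:
    """Extract all range metrics from a scan in one call."""
    pcurve = normalize(curve) if isinstance(curve, ScanCurve) else curve
    level_depths = {lv: depth_at_level(pcurve, lv) for lv in levels}
    return CurveMetrics(
        d_max=pcurve.d_max,
        i50_depth=i50(pcurve),
        r_p=practical_range(pcurve, tail_bounds=tail_bounds),
        level_depths=level_depths,
        descent_gradient=descent_gradient(pcurve),
    )
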