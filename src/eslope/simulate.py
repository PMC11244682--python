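"""Phenomenological electron depth-ionization beam simulator.

Generates noiseless percent-depth-ionization curves with *known* analytic
range metrics, so every extraction routine can be checked against closed
forms, and simulates the monthly two-depth QA procedure with realistic
measurement noise:

* a quadratic build-up from the surface value to 100% at ``d_max``;
* an exactly linear descent through ``(r50, 50%)`` with gradient
  ``g = (tail_level - 50) / (rp - r50)`` — so the line reaches the tail
  level precisely at ``rp``, and the 70%/30% crossings sit at
  ``r50 ± 20/|g|``;
* a smooth monotone blend joining build-up to descent; and
* a flat bremsstrahlung tail beyond ``rp``.

The default beam family is laid out from nominal energy alone using the
classical range relations (R50 = E/2.33) plus clinically proportioned
defaults for Rp, d_max and the tail, reproducing the textbook behaviour
that higher energy means a shallower descent.

Noise model
-----------
Monthly QA noise has two distinct parts.  The chamber is *set up* once per
session, with a depth uncertainty of a few tenths of a millimetre that is
common to every depth visited that session (the mechanical stepper's
relative moves are an order of magnitude more precise).  Each electrometer
reading additionally carries independent sub-percent reproducibility noise.
``simulate_series`` therefore draws one depth offset per monthly session
and independent multiplicative reading noise per measurement.  This is
exactly the regime in which the slope statistic is robust — a common depth
offset slides both readings along the straight descent, leaving their
difference unchanged — while the ratio statistic is not, because its deep
reading sits on the steep limb where a depth offset translates directly
into signal change.

Energy drift is modelled two ways.  ``mode="rigid"`` translates the whole
curve, which moves I50/Rp exactly but — a mathematical fact worth noting —
is invisible to the fixed-depth slope statistic on a straight limb.
``mode="energy"`` (the default for drift studies) re-derives the beam at
the nominal energy whose R50 equals the shifted one, which both shifts and
steepens the curve, as a physical energy change does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import curves as pc
from .curves import PercentCurve, ScanCurve, normalize
from .energy import r50_from_e0
from .errors import InvalidInputError
from .slope import (
    CalibrationModel,
    SlopePoints,
    SlopeReading,
    fit_exponential,
    relative_change,
)
from .tracking import TrendSummary, summarize

__all__ = [
    "BeamSpec",
    "NoiseModel",
    "MonthlySample",
    "baseline_from_curve",
    "generate_curve",
    "drift_beam",
    "measure_at",
    "simulate_series",
    "compare_methods",
    "commissioned_points",
    "calibration_from_drifts",
]

DEFAULT_ENERGIES = (6.0, 9.0, 12.0, 15.0)


@dataclass(frozen=True)
class BeamSpec:
    """Geometric specification of one simulated electron beam."""

    nominal_energy: float  # MeV
    r50: float  # cm, depth of the 50% level
    rp: float  # cm, practical range
    d_max: float  # cm, depth of maximum
    surface_level: float = 80.0  # % at zero depth
    tail_level: float = None  # % bremsstrahlung tail
    grid_step: float = 0.05  # cm

    def __post_init__(self):
        if self.tail_level is None:
            object.__setattr__(self, "tail_level", 1.0 + 0.2 * self.nominal_energy)
        if not 0 < self.d_max < self.r50 < self.rp:
            raise InvalidInputError(
                f"need 0 < d_max < r50 < rp, got {self.d_max}, {self.r50}, {self.rp}"
            )
        if not 0 < self.tail_level < 30:
            raise InvalidInputError("tail level must lie in (0, 30)%")
        if not 0 < self.surface_level < 100:
            raise InvalidInputError("surface level must lie in (0, 100)%")
        if self.grid_step <= 0:
            raise InvalidInputError("grid step must be positive")
        # the 85% end of the linear segment must lie beyond d_max so the
        # blend region is non-degenerate
        if self.blend_end <= self.d_max:
            raise InvalidInputError(
                "blend region degenerate: 85% crossing not deeper than d_max"
            )
        if self.grid_step >= 15.0 / abs(self.gradient):
            raise InvalidInputError(
                "grid step too coarse to bracket the 70% crossing on the "
                "linear segment"
            )

    @classmethod
    def from_energy(
        cls,
        nominal_energy: float,
        grid_step: float = 0.05,
        surface_level: float = 80.0,
    ) -> "BeamSpec":
        """Default clinical-beam geometry from nominal energy alone.

        R50 = E/2.33 (TG-25), Rp = 1.25*R50, d_max = 0.6*R50, tail level =
        1 + 0.2*E percent.  The d_max proportion matches clinical electron
        beams (d_max/R50 of roughly 0.55-0.6 from 6 to 15 MeV) and leaves a
        broad flat shoulder around the peak — the premise of normalizing
        monthly readings at a reference depth "on a flat portion" of the
        curve.
        """
        if nominal_energy <= 0:
            raise InvalidInputError("nominal energy must be positive")
        r50 = r50_from_e0(nominal_energy, "tg25")
        rp = 1.25 * r50
        d_max = 0.6 * r50
        return cls(
            nominal_energy=nominal_energy,
            r50=r50,
            rp=rp,
            d_max=d_max,
            grid_step=grid_step,
            surface_level=surface_level,
        )

    @property
    def gradient(self) -> float:
        """Analytic descent gradient g = (tail - 50)/(rp - r50), %/cm."""
        return (self.tail_level - 50.0) / (self.rp - self.r50)

    @property
    def blend_end(self) -> float:
        """Depth of the 85% crossing, where the exactly-linear segment begins."""
        return self.r50 + 35.0 / self.gradient

    def depth_of_level(self, level: float) -> float:
        """Analytic depth of a level on the linear descent (tail < level <= 85)."""
        if not self.tail_level < level <= 85.0:
            raise InvalidInputError(
                f"level {level}% is outside the linear segment "
                f"({self.tail_level:.2f}, 85]"
            )
        return self.r50 + (level - 50.0) / self.gradient


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: fractional reading SD and depth-positioning SD."""

    reading_sd: float = 0.005  # fractional, per reading
    depth_sd: float = 0.03  # cm, per chamber positioning
    seed: int | None = None

    def __post_init__(self):
        if self.reading_sd < 0 or self.depth_sd < 0:
            raise InvalidInputError("noise SDs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: convenience zero-noise model
NO_NOISE = NoiseModel(reading_sd=0.0, depth_sd=0.0)


def _percent_value(spec: BeamSpec, z: np.ndarray) -> np.ndarray:
    """Closed-form curve value at depths z."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    g = spec.gradient
    z85 = spec.blend_end

    build = z <= spec.d_max
    out[build] = 100.0 - (100.0 - spec.surface_level) * (
        (z[build] - spec.d_max) / spec.d_max
    ) ** 2

    blend = (z > spec.d_max) & (z < z85)
    h = z85 - spec.d_max
    t = (z[blend] - spec.d_max) / h
    # cubic Hermite shoulder: value 100, slope 0 at d_max; value 85 at the
    # 85% crossing with junction slope clamped to 3x the secant so the
    # blend is monotone (and the peak flat) for any geometry
    hm = max(h * g, -45.0)
    out[blend] = (
        100.0
        + (85.0 - 100.0) * (3.0 * t**2 - 2.0 * t**3)
        + hm * (t**3 - t**2)
    )

    lin = (z >= z85) & (z <= spec.rp)
    out[lin] = 50.0 + g * (z[lin] - spec.r50)

    tail = z > spec.rp
    out[tail] = spec.tail_level
    return out


def generate_curve(spec: BeamSpec) -> ScanCurve:
    """Noiseless scan for a beam spec, on a uniform grid plus ``d_max``.

    The exact peak depth is inserted into the grid so the maximum reading is
    exactly 100 and normalization is the identity; all level crossings
    between 85% and the tail then interpolate exactly on the linear segment.
    """
    z_end = spec.rp + max(1.0, spec.rp - spec.r50)
    grid = np.arange(0.0, z_end + 0.5 * spec.grid_step, spec.grid_step)
    if np.min(np.abs(grid - spec.d_max)) > 1e-9:
        grid = np.sort(np.append(grid, spec.d_max))
    readings = _percent_value(spec, grid)
    meta = {
        "nominal_energy_mev": spec.nominal_energy,
        "r50_cm": spec.r50,
        "rp_cm": spec.rp,
        "source": "synthetic",
    }
    return ScanCurve(depths=grid, readings=readings, meta=meta)


def drift_beam(spec: BeamSpec, delta_i50_mm: float, mode: str = "rigid") -> BeamSpec:
    """Beam after an energy drift that moves I50 by ``delta_i50_mm`` mm.

    ``mode="rigid"`` translates r50, rp and d_max together (descending limb
    shape unchanged); ``mode="energy"`` rescales the descending limb to the
    nominal energy whose R50 equals the shifted one, so the limb steepens or
    relaxes as a true energy change does.  The energy mode keeps ``d_max``
    (and the build-up) fixed: for millimetre-scale drifts the depth of
    maximum is insensitive, and what drifts is the descending portion.
    """
    delta_cm = delta_i50_mm / 10.0
    if mode == "rigid":
        return replace(
            spec,
            r50=spec.r50 + delta_cm,
            rp=spec.rp + delta_cm,
            d_max=spec.d_max + delta_cm,
        )
    if mode == "energy":
        new_r50 = spec.r50 + delta_cm
        if new_r50 <= 0:
            raise InvalidInputError("drift drives R50 nonpositive")
        new_energy = 2.33 * new_r50
        return replace(
            spec,
            nominal_energy=new_energy,
            r50=new_r50,
            rp=spec.rp / spec.r50 * new_r50,
            tail_level=1.0 + 0.2 * new_energy,
        )
    raise InvalidInputError(f"unknown drift mode {mode!r}")


def interpolate_reading(curve: ScanCurve, depth: float) -> float:
    """Linearly interpolated reading at a depth (clamped at the scan ends)."""
    return float(np.interp(depth, curve.depths, curve.readings))


def measure_at(
    curve: ScanCurve,
    depth: float,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> float:
    """One noisy point measurement: position the chamber, read the signal.

    The chamber lands at ``depth`` plus a Gaussian positioning error
    (SD ``depth_sd``); the reading carries independent multiplicative
    Gaussian noise (SD ``reading_sd``).  The generator state advances
    deterministically (two draws per call), so a fixed seed reproduces the
    sequence bit for bit.
    """
    z = depth + rng.normal(0.0, noise.depth_sd)
    value = interpolate_reading(curve, z)
    return value * (1.0 + rng.normal(0.0, noise.reading_sd))


@dataclass(frozen=True)
class MonthlySample:
    """One simulated monthly QA session."""

    month: int
    slope_reading: SlopeReading
    ratio: float  # d_max reading / I50-depth reading
    drift_mm: float  # cumulative scheduled I50 drift in effect
    readings: dict = field(default_factory=dict)  # raw signals by depth role


def commissioned_points(spec: BeamSpec) -> SlopePoints:
    """Commissioning depths (d_ref at d_max, 70%/30% crossings) for a beam."""
    return SlopePoints(
        d70=spec.depth_of_level(70.0),
        d30=spec.depth_of_level(30.0),
        d_ref=spec.d_max,
    )


def _current_drift(schedule: Mapping[int, float] | None, month: int) -> float:
    """Cumulative drift (mm) in effect at a month: latest scheduled entry
    with index <= month."""
    if not schedule:
        return 0.0
    applicable = [m for m in schedule if m <= month]
    return schedule[max(applicable)] if applicable else 0.0


def simulate_series(
    spec: BeamSpec,
    points: SlopePoints | None = None,
    months: int = 36,
    drift_schedule: Mapping[int, float] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
    i50_depth: float | None = None,
    drift_mode: str = "energy",
) -> list[MonthlySample]:
    """Simulate a monthly QA series for one beam.

    Per month: the scheduled cumulative drift (``{month: mm}``, effective
    from that month onward) is applied to the beam; the chamber is set up
    once with a common Gaussian depth offset (SD ``noise.depth_sd``); the
    reference, 70%, 30% and I50-depth signals are read with independent
    multiplicative reading noise.  Returns the slope reading and the
    d_max/I50-depth ratio for each month.
    """
    if months < 1:
        raise InvalidInputError("need at least one month")
    points = points if points is not None else commissioned_points(spec)
    d_i50 = i50_depth if i50_depth is not None else spec.r50
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    curve_cache: dict[float, ScanCurve] = {}
    out: list[MonthlySample] = []
    for month in range(months):
        delta = _current_drift(drift_schedule, month)
        if delta not in curve_cache:
            bspec = drift_beam(spec, delta, drift_mode) if delta else spec
            curve_cache[delta] = generate_curve(bspec)
        curve = curve_cache[delta]

        session_offset = rng.normal(0.0, noise.depth_sd)
        raw = {}
        for role, depth in (
            ("ref", points.d_ref),
            ("d70", points.d70),
            ("d30", points.d30),
            ("i50", d_i50),
        ):
            value = interpolate_reading(curve, depth + session_offset)
            raw[role] = value * (1.0 + rng.normal(0.0, noise.reading_sd))

        sr = SlopeReading.from_readings(raw["ref"], raw["d70"], raw["d30"], points)
        out.append(
            MonthlySample(
                month=month,
                slope_reading=sr,
                ratio=raw["ref"] / raw["i50"],
                drift_mm=delta,
                readings=raw,
            )
        )
    return out


def baseline_from_curve(
    curve: ScanCurve, points: SlopePoints, i50_depth: float
) -> tuple[float, float]:
    """Noiseless baseline slope and ratio read off a commissioning scan."""
    r_ref = interpolate_reading(curve, points.d_ref)
    sr = SlopeReading.from_readings(
        r_ref,
        interpolate_reading(curve, points.d70),
        interpolate_reading(curve, points.d30),
        points,
    )
    return sr.slope_m, r_ref / interpolate_reading(curve, i50_depth)


def compare_methods(
    specs: Sequence[BeamSpec] | None = None,
    months: int = 36,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict[float, dict[str, TrendSummary]]:
    """Slope-vs-ratio stability study across a beam family, no drift.

    For each beam, simulates ``months`` QA sessions, converts both
    statistics to % changes from their noiseless baselines, and summarizes.
    Returns ``{nominal_energy: {"slope": TrendSummary, "ratio": TrendSummary}}``.
    """
    if specs is None:
        specs = [BeamSpec.from_energy(e) for e in DEFAULT_ENERGIES]
    rng = np.random.default_rng(seed)
    out: dict[float, dict[str, TrendSummary]] = {}
    for spec in specs:
        points = commissioned_points(spec)
        baseline_slope, baseline_ratio = baseline_from_curve(
            generate_curve(spec), points, spec.r50
        )
        series = simulate_series(
            spec, points, months=months, noise=noise, seed=rng, i50_depth=spec.r50
        )
        slope_changes = [
            relative_change(s.slope_reading.slope_m, baseline_slope) for s in series
        ]
        ratio_changes = [
            100.0 * (s.ratio - baseline_ratio) / baseline_ratio for s in series
        ]
        out[spec.nominal_energy] = {
            "slope": summarize(slope_changes, "slope"),
            "ratio": summarize(ratio_changes, "ratio"),
        }
    return out


def calibration_from_drifts(
    spec: BeamSpec,
    shifts_mm: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    kind: str = "i50",
) -> CalibrationModel:
    """Slope calibration fitted from commissioning-style scans around a beam.

    Generates energy-mode drifted beams spanning the clinically relevant I50
    range, measures each scan's descent gradient and I50 (or energy) with
    the curve-analysis routines, and fits the exponential calibration.  The
    narrow span makes the exponential locally exact, which is what converting
    small slope changes into millimetre I50 shifts requires.
    """
    slopes, targets = [], []
    for shift in shifts_mm:
        bspec = drift_beam(spec, shift, mode="energy")
        pcurve = normalize(generate_curve(bspec))
        slopes.append(pc.descent_gradient(pcurve))
        targets.append(pc.i50(pcurve) if kind == "i50" else bspec.nominal_energy)
    return fit_exponential(slopes, targets, kind=kind)
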