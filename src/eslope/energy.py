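"""Classical electron energy-range relationships.

Four widely used empirical formulas relate an electron beam's surface energy
to its range metrics in water:

* Markus:            ``E0 = (Rp + 0.376) / 0.521``
* NACP (1980):       ``Ep0 = 0.22 + 1.98*Rp + 0.0025*Rp**2``  (most probable
  energy at the surface)
* TG-21/25/51:       ``E0 = 2.33 * R50``  (mean incident energy)
* TG-70:             ``E0 = 0.656 + 2.059*R50 + 0.022*R50**2``

Energies in MeV, ranges in cm of water.  Inversions are provided so a
simulator can lay out a curve family from nominal energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "FORMULAS",
    "EnergyEstimate",
    "markus_e0",
    "nacp_ep0",
    "tg25_e0",
    "tg70_e0",
    "energy_from_range",
    "r50_from_e0",
    "rp_from_e0",
]


@dataclass(frozen=True)
class EnergyEstimate:
    """An energy computed from a range metric by one named formula."""

    value: float  # MeV
    formula_id: str  # markus | nacp | tg25 | tg70
    input_range: float  # cm

    def __post_init__(self):
        if self.input_range > 0 and self.value <= 0:
            raise InvalidInputError("energy must be positive for a positive range")


def _check_range(r: float, name: str) -> None:
    if r < 0:
        raise InvalidInputError(f"{name} must be >= 0, got {r}")


def markus_e0(rp: float) -> float:
    """Surface energy (MeV) from the practical range via the Markus equation."""
    _check_range(rp, "Rp")
    return (rp + 0.376) / 0.521


def nacp_ep0(rp: float) -> float:
    """Most probable surface energy (MeV) from Rp via the NACP quadratic."""
    _check_range(rp, "Rp")
    return 0.22 + 1.98 * rp + 0.0025 * rp**2


def tg25_e0(r50: float) -> float:
    """Mean incident energy (MeV) from R50, E0 = 2.33 * R50."""
    _check_range(r50, "R50")
    return 2.33 * r50


def tg70_e0(r50: float) -> float:
    """Mean incident energy (MeV) from R50 via the TG-70 quadratic."""
    _check_range(r50, "R50")
    return 0.656 + 2.059 * r50 + 0.022 * r50**2


FORMULAS = {
    "markus": markus_e0,
    "nacp": nacp_ep0,
    "tg25": tg25_e0,
    "tg70": tg70_e0,
}

#: which range metric each formula consumes
_RANGE_KIND = {"markus": "rp", "nacp": "rp", "tg25": "r50", "tg70": "r50"}


def energy_from_range(range_cm: float, formula_id: str) -> EnergyEstimate:
    """Evaluate one of the named formulas, tagging the result."""
    try:
        fn = FORMULAS[formula_id]
    except KeyError:
        raise InvalidInputError(
            f"unknown formula {formula_id!r}; choose from {sorted(FORMULAS)}"
        ) from None
    return EnergyEstimate(value=fn(range_cm), formula_id=formula_id, input_range=range_cm)


def _invert_quadratic(e0: float, c: float, b: float, a: float) -> float:
    """Positive root of a*r^2 + b*r + c = e0 (a, b > 0, monotone for r >= 0)."""
    if e0 < c:
        raise InvalidInputError(
            f"energy {e0} MeV is below the formula's zero-range value {c} MeV"
        )
    if a == 0:
        return (e0 - c) / b
    disc = b * b + 4.0 * a * (e0 - c)
    return (-b + math.sqrt(disc)) / (2.0 * a)


def r50_from_e0(e0: float, formula_id: str = "tg25") -> float:
    """Invert an R50-based formula: the R50 (cm) whose energy is ``e0``."""
    if e0 < 0:
        raise InvalidInputError("energy must be >= 0")
    if formula_id == "tg25":
        return e0 / 2.33
    if formula_id == "tg70":
        return _invert_quadratic(e0, 0.656, 2.059, 0.022)
    raise InvalidInputError(f"{formula_id!r} is not an R50-based formula")


def rp_from_e0(e0: float, formula_id: str = "markus") -> float:
    """Invert an Rp-based formula: the Rp (cm) whose energy is ``e0``."""
    if e0 < 0:
        raise InvalidInputError("energy must be >= 0")
    if formula_id == "markus":
        if e0 < 0.376 / 0.521:
            raise InvalidInputError(
                "energy below the Markus zero-range value 0.376/0.521 MeV"
            )
        return 0.521 * e0 - 0.376
    if formula_id == "nacp":
        return _invert_quadratic(e0, 0.22, 1.98, 0.0025)
    raise InvalidInputError(f"{formula_id!r} is not an Rp-based formula")
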