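"""Predictor unit handling.

Equation tables quote predictors in different conventions (kg/kg DM, g/kg DM,
% DM, MJ/MJ); conversions between members of the same unit family are exact
linear rescalings.
"""

from __future__ import annotations

from .core import DomainError

__all__ = ["UnitError", "convert_predictor", "canonical_unit"]


class UnitError(DomainError):
    """No registered conversion between the requested units."""


# scale = how many of this unit equal one canonical unit of the family
_FAMILIES = {
    "mass_fraction": {
        "kg/kg": 1.0, "kg/kg DM": 1.0,
        "g/kg": 1000.0, "g/kg DM": 1000.0,
        "%": 100.0, "% DM": 100.0,
        "g/100g": 100.0, "g/100 g DM": 100.0,
    },
    "energy_density": {"MJ/kg": 1.0, "MJ/kg DM": 1.0},
    "energy_ratio": {"MJ/MJ": 1.0},
}

_UNIT_FAMILY = {u: fam for fam, units in _FAMILIES.items() for u in units}


def canonical_unit(unit: str) -> str:
    """The 1.0-scale member of the unit's family."""
    fam = _UNIT_FAMILY.get(unit)
    if fam is None:
        raise UnitError(f"unknown unit {unit!r}")
    for u, s in _FAMILIES[fam].items():
        if s == 1.0:
            return u
    raise AssertionError  # every family has a canonical member


def convert_predictor(value: float, from_unit: str, to_unit: str) -> float:
    """Exact linear rescaling between registered units of one family."""
    fam_from = _UNIT_FAMILY.get(from_unit)
    fam_to = _UNIT_FAMILY.get(to_unit)
    if fam_from is None or fam_to is None or fam_from != fam_to:
        raise UnitError(f"no registered conversion {from_unit!r} -> {to_unit!r}")
    scale = _FAMILIES[fam_from]
    return value * (scale[to_unit] / scale[from_unit])
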