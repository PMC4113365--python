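"""Mass units and unit-safety errors.

The numerical value of an allometric scaling coefficient depends on the mass
unit (``c' = c * r**(-k)`` when masses are multiplied by ``r``), so units are
carried on every model object and validated at module boundaries rather than
assumed.
"""
from __future__ import annotations

from enum import Enum


class MassUnit(str, Enum):
    """Supported body-mass units."""

    G = "g"
    KG = "kg"

    @classmethod
    def parse(cls, value: "MassUnit | str") -> "MassUnit":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise UnitError(
                f"unknown mass unit {value!r}; expected one of "
                f"{[u.value for u in cls]}"
            ) from None


_GRAMS_PER_UNIT = {MassUnit.G: 1.0, MassUnit.KG: 1000.0}


def grams_per(unit: MassUnit | str) -> float:
    """Grams contained in one unit of ``unit``."""
    return _GRAMS_PER_UNIT[MassUnit.parse(unit)]


def mass_ratio(old: MassUnit | str, new: MassUnit | str) -> float:
    """Multiplier converting a mass value expressed in ``old`` to ``new`` units."""
    return grams_per(old) / grams_per(new)


class UnitError(ValueError):
    """Unknown unit or an operation mixing incompatible units."""


DEFAULT_EE_UNIT = "kcal/d"
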