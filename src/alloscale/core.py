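"""Allometric energy-expenditure models and their tangent-line linearizations.

Over broad ranges of body mass, energy expenditure (EE) scales as a
zero-intercept power law ``EE = c * M**k``.  Over the restricted mass ranges
typical of phenotyping studies, the same curve is locally linear, and a linear
regression ``EE = a + b*M`` fitted to such data estimates the first-order
Taylor expansion of the power law about the sample mean mass ``M0``:

    a = c * M0**k * (1 - k)
    b = c * k * M0**(k - 1)

Inverting this tangent-line relationship gives closed forms for the latent
allometric parameters in terms of the published linear ones:

    k = b*M0 / (a + b*M0)
    c = b / (k * M0**(k - 1))

This module houses the two model types (:class:`PowerLaw`,
:class:`LinearEEModel`) and the exact two-way conversion between them.  The
conversions are evaluated in closed form only; no iterative solving is
involved.  Note the sign law implied by the intercept formula: a positive
intercept corresponds to ``k < 1``, a zero intercept to ``k = 1`` and a
negative intercept to ``k > 1``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .units import DEFAULT_EE_UNIT, MassUnit, UnitError, mass_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLaw",
    "LinearEEModel",
    "NotTangentRepresentableError",
    "evaluate_power_law",
    "taylor_linearize",
    "linear_to_allometric",
    "convert_mass_units",
    "linearization_error",
]


class NotTangentRepresentableError(ValueError):
    """Linear parameters incompatible with a positive power-law tangent."""


@dataclass(frozen=True)
class PowerLaw:
    """Two-parameter allometric EE model ``EE(M) = c * M**k``.

    Parameters
    ----------
    c : float
        Scaling coefficient, in EE units per mass-unit**k (e.g.
        kcal·d⁻¹·kg⁻ᵏ).  Must be positive; its numerical value depends on
        the mass unit.
    k : float
        Dimensionless scaling exponent, positive and finite.  Metabolic-rate
        exponents are typically below one within species.
    mass_unit : MassUnit or str
        Unit of the mass argument (``"g"`` or ``"kg"``).
    ee_unit : str
        Label for the EE unit (default ``"kcal/d"``).
    """

    c: float
    k: float
    mass_unit: MassUnit
    ee_unit: str = DEFAULT_EE_UNIT

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_unit", MassUnit.parse(self.mass_unit))
        if not (math.isfinite(self.c) and self.c > 0):
            raise ValueError(f"scaling coefficient c must be positive and finite, got {self.c}")
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"scaling exponent k must be positive and finite, got {self.k}")

    def predict(self, M):
        """Evaluate ``c * M**k`` for scalar or array mass ``M`` (> 0)."""
        return evaluate_power_law(self, M)

    __call__ = predict

    def to_unit(self, unit: MassUnit | str) -> "PowerLaw":
        """Re-express the model in a different mass unit (see :func:`convert_mass_units`)."""
        return convert_mass_units(self, unit)

    @property
    def coefficient_unit(self) -> str:
        return f"{self.ee_unit}·{self.mass_unit.value}^(-{self.k:g})"


@dataclass(frozen=True)
class LinearEEModel:
    """Linear EE model ``EE(M) = a + b*M`` interpreted as a tangent at ``M0``.

    ``M0`` is the reference (centering) mass about which the line is — or is
    interpreted as — the first-order Taylor expansion of a latent power law.
    For a fitted regression this is the sample mean of the mass covariate.

    ``mass_kind`` records whether the mass covariate is total body mass or
    fat-free mass; the algebra is identical for both.
    """

    a: float
    b: float
    M0: float
    mass_unit: MassUnit
    ee_unit: str = DEFAULT_EE_UNIT
    mass_kind: str = "total"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_unit", MassUnit.parse(self.mass_unit))
        if not (math.isfinite(self.M0) and self.M0 > 0):
            raise ValueError(f"reference mass M0 must be positive and finite, got {self.M0}")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("intercept and slope must be finite")
        if self.mass_kind not in ("total", "ffm"):
            raise ValueError(f"mass_kind must be 'total' or 'ffm', got {self.mass_kind!r}")

    def predict(self, M):
        """Evaluate ``a + b*M``."""
        return self.a + self.b * np.asarray(M, dtype=float)

    __call__ = predict

    @property
    def ee_at_reference(self) -> float:
        """Predicted EE at the reference mass, ``a + b*M0``."""
        return self.a + self.b * self.M0

    def to_unit(self, unit: MassUnit | str) -> "LinearEEModel":
        """Re-express in a different mass unit (slope and M0 rescale, a is unchanged)."""
        unit = MassUnit.parse(unit)
        r = mass_ratio(self.mass_unit, unit)
        return replace(self, b=self.b / r, M0=self.M0 * r, mass_unit=unit)


def _check_mass(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.all(M > 0):
        raise ValueError("mass must be strictly positive")
    return M


def evaluate_power_law(p: PowerLaw, M, mass_unit: MassUnit | str | None = None):
    """Evaluate a power law at mass ``M`` (scalar or array, > 0).

    If ``mass_unit`` is given it must match the model's unit; this guards
    against silently mixing grams and kilograms, which changes ``c``.
    """
    if mass_unit is not None and MassUnit.parse(mass_unit) != p.mass_unit:
        raise UnitError(
            f"mass given in {MassUnit.parse(mass_unit).value!r} but model is in "
            f"{p.mass_unit.value!r}; convert with to_unit() first"
        )
    M = _check_mass(M)
    out = p.c * M**p.k
    return float(out) if out.ndim == 0 else out


def taylor_linearize(p: PowerLaw, M0: float) -> LinearEEModel:
    """First-order Taylor expansion of a power law about the reference mass ``M0``.

    Returns the tangent line ``EE = a + b*M`` with

        a = c * M0**k * (1 - k),    b = c * k * M0**(k - 1),

    which matches the curve's value and first derivative at ``M0``.
    """
    if not (math.isfinite(M0) and M0 > 0):
        raise ValueError(f"M0 must be positive and finite, got {M0}")
    a = p.c * M0**p.k * (1.0 - p.k)
    b = p.c * p.k * M0 ** (p.k - 1.0)
    return LinearEEModel(a=a, b=b, M0=M0, mass_unit=p.mass_unit, ee_unit=p.ee_unit)


def linear_to_allometric(m: LinearEEModel) -> PowerLaw:
    """Recover the latent power law whose tangent at ``M0`` is the given line.

    Closed forms: ``k = b*M0 / (a + b*M0)`` and ``c = b / (k * M0**(k-1))``.
    Requires ``b > 0`` and ``a + b*M0 > 0`` (i.e. positive slope and positive
    predicted EE at the reference mass); otherwise the line is not the tangent
    of any positive power law and :class:`NotTangentRepresentableError` is
    raised.  ``k > 1`` (negative intercept) is legal but flagged with a
    warning, since metabolic exponents below one are the typical case.
    """
    if m.b <= 0:
        raise NotTangentRepresentableError(
            f"slope b must be positive to represent an increasing power law (b={m.b})"
        )
    ee0 = m.a + m.b * m.M0
    if ee0 <= 0:
        raise NotTangentRepresentableError(
            f"predicted EE at the reference mass must be positive (a + b*M0 = {ee0})"
        )
    k = m.b * m.M0 / ee0
    c = m.b / (k * m.M0 ** (k - 1.0))
    if k > 1:
        logger.warning(
            "recovered exponent k=%.4g exceeds 1 (negative intercept); "
            "metabolic scaling exponents are typically below 1",
            k,
        )
    return PowerLaw(c=c, k=k, mass_unit=m.mass_unit, ee_unit=m.ee_unit)


def convert_mass_units(p: PowerLaw, to_unit: MassUnit | str) -> PowerLaw:
    """Re-express a power law in a different mass unit.

    If masses in the new unit are ``r`` times the old numerical values
    (kg→g: r=1000), predictions are preserved by ``c' = c * r**(-k)``; the
    exponent is dimensionless and unchanged.
    """
    to_unit = MassUnit.parse(to_unit)
    r = mass_ratio(p.mass_unit, to_unit)
    return replace(p, c=p.c * r ** (-p.k), mass_unit=to_unit)


def linearization_error(
    p: PowerLaw,
    m: LinearEEModel,
    M_lo: float,
    M_hi: float,
    n_grid: int = 201,
) -> float:
    """Maximum relative error of the tangent line against the curve on a mass grid.

    Evaluates ``|linear - curve| / curve`` on ``n_grid`` equally spaced masses
    in ``[M_lo, M_hi]`` and returns the maximum.  Zero at ``M0`` by tangency;
    identically zero when ``k = 1``.
    """
    if not (0 < M_lo < M_hi):
        raise ValueError(f"need 0 < M_lo < M_hi, got ({M_lo}, {M_hi})")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    if m.mass_unit != p.mass_unit:
        raise UnitError("power law and linear model use different mass units")
    grid = np.linspace(M_lo, M_hi, n_grid)
    curve = p.predict(grid)
    line = m.predict(grid)
    return float(np.max(np.abs(line - curve) / curve))
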