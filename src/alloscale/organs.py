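"""Organ-tissue compartment model of whole-body resting energy expenditure.

Whole-body REE is modelled as the sum of per-organ power laws of *total*
body mass M,

    REE(M) = sum_i c_i * M**k_i,

where each lumped exponent ``k_i = p_i + q_i`` combines the scaling of the
organ's mass-specific REE (p_i) and of the organ's mass (q_i) with M.
Linearizing every term at a common reference mass M0 and summing shows that
the aggregate regression intercept is

    a = sum_i c_i * M0**k_i * (1 - k_i),

so the aggregate intercept of a linear REE regression is positive whenever
every organ exponent is below one — organ-level modelling does not remove
the intercept, it decomposes it.  Each organ's intercept contribution is its
coefficient times the *intercept multiplier* ``g(k) = (1 - k) * M0**k``,
which for fixed M0 is maximized at ``k* = 1 - 1/ln(M0)``.  The multiplier
(and hence k*) depends on the numerical mass unit because M0**k is not
unit-invariant; the sensitivity analyses here follow the convention of
working in grams.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import LinearEEModel, PowerLaw, linear_to_allometric, taylor_linearize
from .units import DEFAULT_EE_UNIT, MassUnit

__all__ = [
    "OrganCompartment",
    "OrganModel",
    "OrganLinearization",
    "OrganShares",
    "SensitivityReport",
    "ReductionResult",
    "NoInteriorMaximumError",
    "whole_body_ree",
    "linearize_model",
    "organ_shares",
    "organ_mass_parameterization",
    "intercept_multiplier",
    "maximizing_exponent",
    "doubling_range",
    "exponent_sensitivity",
    "reduce_to_single_power",
]

KNOWN_ORGANS = ("liver", "brain", "heart", "kidneys", "remainder")


class NoInteriorMaximumError(ValueError):
    """Reference mass too small for the intercept multiplier to peak inside (0, 1)."""


@dataclass(frozen=True)
class OrganCompartment:
    """One organ-tissue term ``c * M**k`` of the whole-body REE sum.

    ``p`` and ``q`` are the optional components of the lumped exponent
    (mass-specific-REE exponent and organ-mass exponent); when both are given
    they must sum to ``k``.  ``f`` is the organ's optional mass fraction of
    total body mass at the reference mass.
    """

    name: str
    c: float
    k: float
    p: float | None = None
    q: float | None = None
    f: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c) and self.c > 0):
            raise ValueError(f"{self.name}: coefficient c must be positive, got {self.c}")
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"{self.name}: exponent k must be positive, got {self.k}")
        if self.p is not None and self.q is not None:
            if not math.isclose(self.p + self.q, self.k, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"{self.name}: lumped exponent k={self.k} != p + q = {self.p + self.q}"
                )
        if self.f is not None and not (0 < self.f <= 1):
            raise ValueError(f"{self.name}: mass fraction f must lie in (0, 1], got {self.f}")

    def ree(self, M) -> np.ndarray | float:
        out = self.c * np.asarray(M, dtype=float) ** self.k
        return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class OrganModel:
    """Ordered collection of organ compartments sharing one unit system."""

    compartments: tuple[OrganCompartment, ...]
    mass_unit: MassUnit
    ee_unit: str = DEFAULT_EE_UNIT

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "mass_unit", MassUnit.parse(self.mass_unit))
        if len(self.compartments) == 0:
            raise ValueError("an organ model needs at least one compartment")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError(f"compartment names must be unique, got {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    def __getitem__(self, name: str) -> OrganCompartment:
        for comp in self.compartments:
            if comp.name == name:
                return comp
        raise KeyError(f"no compartment named {name!r}; have {self.names}")

    def ree(self, M):
        return whole_body_ree(self, M)

    def to_unit(self, unit: MassUnit | str) -> "OrganModel":
        """Convert every compartment coefficient to a new mass unit."""
        unit = MassUnit.parse(unit)
        converted = tuple(
            replace(
                comp,
                c=PowerLaw(comp.c, comp.k, self.mass_unit, self.ee_unit).to_unit(unit).c,
            )
            for comp in self.compartments
        )
        return replace(self, compartments=converted, mass_unit=unit)


@dataclass(frozen=True)
class OrganLinearization:
    """Per-organ tangent lines at a common M0 and their aggregate.

    The aggregate intercept/slope are exact sums of the per-organ values
    (linearization is additive).  Shares are evaluated at M0; intercept
    shares are ``None`` when the aggregate intercept is zero.
    """

    per_organ: dict[str, tuple[float, float]]
    aggregate: LinearEEModel
    ree_shares: dict[str, float]
    intercept_shares: dict[str, float] | None
    slope_shares: dict[str, float]


@dataclass(frozen=True)
class OrganShares:
    ree: dict[str, float]
    intercept: dict[str, float] | None
    slope: dict[str, float]
    M0: float
    mass_unit: MassUnit


@dataclass(frozen=True)
class SensitivityReport:
    """Effect of replacing one organ's exponent, holding its coefficient fixed."""

    organ: str
    k_old: float
    k_new: float
    M0: float
    organ_ree_pct_change: float
    whole_body_ree_pct_change: float
    a_new: float
    b_new: float


@dataclass(frozen=True)
class ReductionResult:
    """Single power law approximating an organ-model sum, with its grid RSS."""

    power_law: PowerLaw
    rss: float
    method: str
    M0: float | None = None
    diagnostics: dict = field(default_factory=dict)


def whole_body_ree(model: OrganModel, M):
    """Sum of the per-organ power laws at total body mass ``M`` (> 0)."""
    M = np.asarray(M, dtype=float)
    if not np.all(M > 0):
        raise ValueError("mass must be strictly positive")
    out = sum(comp.ree(M) for comp in model.compartments)
    return float(out) if np.ndim(out) == 0 else out


def linearize_model(model: OrganModel, M0: float) -> OrganLinearization:
    """Tangent-line expansion of every compartment at ``M0``, plus the aggregate.

    The aggregate line has intercept Σ a_i and slope Σ b_i; linearizing the
    sum and summing the linearizations are the same operation.
    """
    per_organ: dict[str, tuple[float, float]] = {}
    for comp in model.compartments:
        lin = taylor_linearize(
            PowerLaw(comp.c, comp.k, model.mass_unit, model.ee_unit), M0
        )
        per_organ[comp.name] = (lin.a, lin.b)
    a = sum(ab[0] for ab in per_organ.values())
    b = sum(ab[1] for ab in per_organ.values())
    aggregate = LinearEEModel(a=a, b=b, M0=M0, mass_unit=model.mass_unit, ee_unit=model.ee_unit)
    shares = organ_shares(model, M0)
    return OrganLinearization(
        per_organ=per_organ,
        aggregate=aggregate,
        ree_shares=shares.ree,
        intercept_shares=shares.intercept,
        slope_shares=shares.slope,
    )


def organ_shares(model: OrganModel, M0: float) -> OrganShares:
    """Each organ's share of whole-body REE, of the aggregate intercept and slope at M0.

    Every share set sums to one.  If the aggregate intercept is (numerically)
    zero — every exponent equal to one — intercept shares are undefined and
    returned as ``None`` rather than NaN.
    """
    if not M0 > 0:
        raise ValueError("M0 must be positive")
    ree = {c.name: c.ree(M0) for c in model.compartments}
    a_i = {c.name: c.ree(M0) * (1.0 - c.k) for c in model.compartments}
    b_i = {c.name: c.c * c.k * M0 ** (c.k - 1.0) for c in model.compartments}
    total_ree = sum(ree.values())
    total_a = sum(a_i.values())
    total_b = sum(b_i.values())
    intercept = None
    if abs(total_a) > 1e-12 * total_ree:
        intercept = {n: v / total_a for n, v in a_i.items()}
    return OrganShares(
        ree={n: v / total_ree for n, v in ree.items()},
        intercept=intercept,
        slope={n: v / total_b for n, v in b_i.items()},
        M0=M0,
        mass_unit=model.mass_unit,
    )


def organ_mass_parameterization(
    model: OrganModel,
    fractions: dict[str, float] | None,
    M0: float,
) -> tuple[dict[str, float], float]:
    """Slopes per unit *organ* mass and the common intercept of a multi-organ regression.

    With organ mass ``T_i = f_i * M``, the regression of REE on the individual
    organ masses has per-organ slope ``beta_i = c_i * k_i * M0**(k_i-1) / f_i``
    and a shared intercept equal to the aggregate tangent intercept
    ``sum_i c_i * M0**k_i * (1 - k_i)``, which does not depend on the mass
    fractions — accounting for organ masses rescales slopes but cannot
    remove the intercept.

    ``fractions`` maps organ name to f_i in (0, 1]; omit (None) to use the
    f values stored on the compartments.
    """
    if not M0 > 0:
        raise ValueError("M0 must be positive")
    f: dict[str, float] = {}
    for comp in model.compartments:
        fi = fractions.get(comp.name) if fractions is not None else comp.f
        if fi is None:
            raise ValueError(f"no mass fraction available for organ {comp.name!r}")
        if not 0 < fi <= 1:
            raise ValueError(f"mass fraction for {comp.name!r} must lie in (0, 1], got {fi}")
        f[comp.name] = fi
    if sum(f.values()) > 1 + 1e-9:
        raise ValueError(f"mass fractions sum to {sum(f.values()):.6f} > 1")
    betas = {
        comp.name: comp.c * comp.k * M0 ** (comp.k - 1.0) / f[comp.name]
        for comp in model.compartments
    }
    intercept = sum(comp.ree(M0) * (1.0 - comp.k) for comp in model.compartments)
    return betas, intercept


def intercept_multiplier(k: float, M0: float) -> float:
    """Intercept multiplier ``g(k) = (1 - k) * M0**k``.

    An organ contributes ``c_i * g(k_i)`` to the aggregate intercept.
    ``g(0) = 1`` and ``g(1) = 0``; the value depends on the mass unit through
    M0.
    """
    if not M0 > 0:
        raise ValueError("M0 must be positive")
    return (1.0 - k) * M0**k


def maximizing_exponent(M0: float) -> float:
    """Exponent maximizing the intercept multiplier: ``k* = 1 - 1/ln(M0)``.

    Valid stationarity requires ``M0 > 1`` (so ln M0 > 0); the result lies in
    (0, 1) only when ``M0 > e``.  For ``M0`` in (1, e] the returned value is
    <= 0, meaning g is decreasing on (0, 1) and has no interior maximum (at
    ``M0 = e`` exactly the boundary value 0 is returned).  ``M0 <= 1`` raises
    :class:`NoInteriorMaximumError`.
    """
    if not M0 > 1:
        raise NoInteriorMaximumError(
            f"intercept multiplier has no stationary point for M0 <= 1 (got {M0})"
        )
    return 1.0 - 1.0 / math.log(M0)


def doubling_range(M0: float, threshold: float = 2.0, tol: float = 1e-6) -> tuple[float, float]:
    """Contiguous interval of exponents where the multiplier is at least ``threshold``.

    Solves ``g(k) = threshold`` on each side of the maximizer by bisection to
    ``tol``.  Returns an empty interval ``(nan, nan)`` when the maximum of g
    on (0, 1) does not reach the threshold.
    """
    from scipy.optimize import brentq

    try:
        k_star = maximizing_exponent(M0)
    except NoInteriorMaximumError:
        k_star = 0.0
    k_star = max(k_star, 0.0)
    g_max = intercept_multiplier(k_star, M0) if k_star > 0 else 1.0
    if g_max <= threshold:
        return (math.nan, math.nan)

    def h(k: float) -> float:
        return intercept_multiplier(k, M0) - threshold

    # g(0)=1 < threshold <= g(k*) and g(1)=0, so one root on each side.
    k_lo = brentq(h, 1e-12, k_star, xtol=tol)
    k_hi = brentq(h, k_star, 1.0 - 1e-12, xtol=tol)
    return (float(k_lo), float(k_hi))


def exponent_sensitivity(
    model: OrganModel,
    organ: str,
    k_new: float,
    M0: float,
) -> SensitivityReport:
    """Effect of changing one organ's exponent with its coefficient held fixed.

    The organ's REE changes by ``100 * (M0**(k_new - k) - 1)`` percent; the
    whole-body change expresses the same absolute REE difference relative to
    the whole-body REE at M0.  Both are mass-unit dependent (the coefficient's
    numerical value is pinned in the model's unit).
    """
    comp = model[organ]
    if not (math.isfinite(k_new) and k_new > 0):
        raise ValueError(f"k_new must be positive, got {k_new}")
    organ_pct = 100.0 * (M0 ** (k_new - comp.k) - 1.0)
    delta_ree = comp.ree(M0) * (M0 ** (k_new - comp.k) - 1.0)
    whole_pct = 100.0 * delta_ree / whole_body_ree(model, M0)
    new_lin = taylor_linearize(PowerLaw(comp.c, k_new, model.mass_unit, model.ee_unit), M0)
    return SensitivityReport(
        organ=organ,
        k_old=comp.k,
        k_new=k_new,
        M0=M0,
        organ_ree_pct_change=organ_pct,
        whole_body_ree_pct_change=whole_pct,
        a_new=new_lin.a,
        b_new=new_lin.b,
    )


def reduce_to_single_power(
    model: OrganModel,
    M_lo: float,
    M_hi: float,
    method: str = "taylor_sum",
    n_grid: int = 201,
    M0: float | None = None,
) -> ReductionResult:
    """Approximate a sum of organ power laws by a single two-parameter power law.

    A sum of power functions is not exactly a power function, so three
    practical identification routes are offered, all scored by residual sum
    of squares on the same equally spaced mass grid in original (not log)
    units:

    ``taylor_sum``
        Linearize every organ at ``M0`` (default: the grid midpoint), sum the
        intercepts and slopes, and convert the aggregate line back to a power
        law in closed form.
    ``loglog``
        Ordinary least squares of ln(REE sum) on ln(M) over the grid,
        back-transformed.
    ``nls``
        Nonlinear least squares of ``c * M**k`` to the grid sum, initialized
        from the ``taylor_sum`` result; by construction its RSS is no larger.
    """
    if not (0 < M_lo < M_hi):
        raise ValueError(f"need 0 < M_lo < M_hi, got ({M_lo}, {M_hi})")
    grid = np.linspace(M_lo, M_hi, n_grid)
    y = whole_body_ree(model, grid)

    if method == "taylor_sum":
        ref = M0 if M0 is not None else 0.5 * (M_lo + M_hi)
        lin = linearize_model(model, ref)
        p = linear_to_allometric(lin.aggregate)
        rss = float(np.sum((y - p.predict(grid)) ** 2))
        return ReductionResult(power_law=p, rss=rss, method=method, M0=ref)

    if method == "loglog":
        from .fitting import EEDataset, fit_loglog

        data = EEDataset(mass=grid, ee=y, mass_unit=model.mass_unit, ee_unit=model.ee_unit)
        res = fit_loglog(data)
        return ReductionResult(power_law=res.model, rss=res.rss, method=method)

    if method == "nls":
        from .fitting import EEDataset, fit_power_nls

        init = reduce_to_single_power(model, M_lo, M_hi, "taylor_sum", n_grid, M0).power_law
        data = EEDataset(mass=grid, ee=y, mass_unit=model.mass_unit, ee_unit=model.ee_unit)
        res = fit_power_nls(data, init)
        return ReductionResult(
            power_law=res.model, rss=res.rss, method=method, diagnostics=res.diagnostics
        )

    raise ValueError(f"unknown method {method!r}; expected taylor_sum, loglog or nls")
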