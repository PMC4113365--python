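"""EE normalization to metabolic body size, and the ratio-normalization confound.

Dividing EE by body mass ("per-gram" normalization) is only valid when EE is
proportional to mass.  Under the linear model EE = a + b*M with a > 0 the
expected ratio is a/M + b, a decreasing function of M: heavier animals look
hypometabolic purely as an artifact (the classic ratio confound).  The
principled alternative divides EE by M**k — 'metabolic body size' — using
the allometric exponent, which may be supplied, estimated from a linear fit
via the tangent inversion, or estimated by log-log regression.  On data that
are truly allometric with exponent k, EE / M**k is a constant (the scaling
coefficient) and uncorrelated with mass.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LinearEEModel, linear_to_allometric
from .fitting import EEDataset, fit_linear_ols, fit_loglog

__all__ = [
    "NormalizedEE",
    "naive_ratio_expectation",
    "normalize_ee",
    "residual_mass_correlation",
]

_K_METHODS = ("user", "eq_tangent", "loglog")


@dataclass(frozen=True)
class NormalizedEE:
    """Per-record EE / mass**k values plus the k used and where it came from."""

    values: np.ndarray
    k: float
    provenance: str          # "user" | "eq_tangent" | "loglog"
    unit: str                # e.g. "kcal/d·g^-0.69"
    masses: np.ndarray

    def __len__(self) -> int:
        return int(self.values.size)


def naive_ratio_expectation(m: LinearEEModel, M):
    """Expected EE/M under a linear model: ``a/M + b``.

    Strictly decreasing in M when the intercept is positive, approaching the
    slope b as M grows — the reason simple ratio normalization penalizes
    heavier individuals.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(M > 0):
        raise ValueError("mass must be strictly positive")
    out = m.a / M + m.b
    return float(out) if out.ndim == 0 else out


def normalize_ee(
    data: EEDataset,
    k: float | None = None,
    method: str = "user",
) -> NormalizedEE:
    """Normalize each record's EE by mass**k.

    ``method`` selects where the exponent comes from:

    * ``"user"`` — k is supplied by the caller;
    * ``"eq_tangent"`` — k estimated by fitting EE = a + b*M and applying the
      closed-form tangent inversion at the sample mean mass;
    * ``"loglog"`` — k from the classical log-log regression.

    Output units are EE-unit·mass-unit⁻ᵏ, reported explicitly on the result.
    """
    if method not in _K_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_K_METHODS}")
    data.require_positive("EE normalization")
    if method == "user":
        if k is None:
            raise ValueError("method='user' requires an explicit k")
    elif method == "eq_tangent":
        k = linear_to_allometric(fit_linear_ols(data).model).k
    else:
        k = fit_loglog(data).model.k
    if not np.isfinite(k):
        raise ValueError(f"exponent k must be finite, got {k}")
    values = data.ee / data.mass ** k
    unit = f"{data.ee_unit}·{data.mass_unit.value}^({-k:g})"
    return NormalizedEE(values=values, k=float(k), provenance=method, unit=unit,
                        masses=data.mass)


def residual_mass_correlation(
    normalized: NormalizedEE | np.ndarray,
    masses: np.ndarray | None = None,
    method: str = "pearson",
) -> float:
    """Correlation between normalized EE and body mass.

    Near zero when the normalizing exponent matches the data's true scaling;
    systematically negative when the exponent is too large (including the
    naive k=1 ratio applied to positive-intercept data).  Raises on
    zero-variance input, where the correlation is undefined.
    """
    if isinstance(normalized, NormalizedEE):
        values = normalized.values
        masses = normalized.masses if masses is None else np.asarray(masses, float)
    else:
        values = np.asarray(normalized, dtype=float)
        if masses is None:
            raise ValueError("masses are required when passing a bare array")
        masses = np.asarray(masses, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 records for a correlation")
    if np.std(values) == 0 or np.std(masses) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    if method == "pearson":
        return float(stats.pearsonr(values, masses).statistic)
    if method == "spearman":
        return float(stats.spearmanr(values, masses).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
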