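"""Least-squares estimation of linear and allometric EE models.

Three estimators, mirroring standard practice in metabolic phenotyping:

* :class:`LinearEERegression` — ordinary least squares of EE on mass; the
  fitted line is interpreted as the tangent of a latent power law at the
  sample mean mass.
* :class:`LogLogRegression` — the classical allometric method, OLS of
  ln(EE) on ln(M), back-transformed.
* :class:`PowerLawRegression` — direct nonlinear least squares of
  ``c * M**k``, via a Levenberg-damped Gauss–Newton iteration (relative
  parameter step below 1e-10 or 200 iterations; deterministic given the
  data and initializer).

All three report the residual sum of squares and r² on a common footing:
in the fitted (original) scale for OLS and in the original EE scale for the
power-law fits, so that methods can be compared on one objective.  Fits are
unweighted throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import LinearEEModel, PowerLaw
from .units import DEFAULT_EE_UNIT, MassUnit

__all__ = [
    "EEDataset",
    "EEFitResults",
    "FitConvergenceError",
    "LinearEERegression",
    "LogLogRegression",
    "PowerLawRegression",
    "fit_linear_ols",
    "fit_loglog",
    "fit_power_nls",
]


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(f"{message}; diagnostics: {diagnostics}")
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class EEDataset:
    """Paired (mass, EE) records with declared mass kind and units.

    ``mass_kind`` distinguishes total body mass from fat-free mass; the
    estimators treat both identically but the distinction travels with the
    data so reports stay unambiguous.
    """

    mass: np.ndarray
    ee: np.ndarray
    mass_unit: MassUnit
    ee_unit: str = DEFAULT_EE_UNIT
    mass_kind: str = "total"
    ids: tuple | None = None

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        ee = np.asarray(self.ee, dtype=float)
        object.__setattr__(self, "mass", mass)
        object.__setattr__(self, "ee", ee)
        object.__setattr__(self, "mass_unit", MassUnit.parse(self.mass_unit))
        if mass.ndim != 1 or ee.ndim != 1 or mass.size != ee.size:
            raise ValueError("mass and ee must be 1-d arrays of equal length")
        if mass.size < 2:
            raise ValueError("at least two records are required")
        if self.mass_kind not in ("total", "ffm"):
            raise ValueError(f"mass_kind must be 'total' or 'ffm', got {self.mass_kind!r}")
        if self.ids is not None:
            object.__setattr__(self, "ids", tuple(self.ids))
            if len(self.ids) != mass.size:
                raise ValueError("ids length must match the number of records")

    def __len__(self) -> int:
        return int(self.mass.size)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        mass_unit: MassUnit | str,
        ee_unit: str = DEFAULT_EE_UNIT,
        mass_kind: str = "total",
        mass_col: str = "mass",
        ee_col: str = "ee",
        id_col: str = "id",
    ) -> "EEDataset":
        missing = [c for c in (mass_col, ee_col) if c not in df.columns]
        if missing:
            raise ValueError(f"dataframe is missing required columns {missing}")
        ids = tuple(df[id_col]) if id_col in df.columns else None
        return cls(
            mass=df[mass_col].to_numpy(dtype=float),
            ee=df[ee_col].to_numpy(dtype=float),
            mass_unit=mass_unit,
            ee_unit=ee_unit,
            mass_kind=mass_kind,
            ids=ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.ids if self.ids is not None else tuple(range(len(self)))
        return pd.DataFrame({"id": ids, "mass": self.mass, "ee": self.ee})

    def require_positive(self, context: str) -> None:
        bad = np.nonzero(~((self.mass > 0) & (self.ee > 0)))[0]
        if bad.size:
            raise ValueError(
                f"{context} requires strictly positive mass and EE; "
                f"offending record indices: {bad.tolist()}"
            )


@dataclass(frozen=True)
class EEFitResults:
    """Fit results: the estimated model plus goodness-of-fit summaries."""

    model: LinearEEModel | PowerLaw
    rss: float
    r2: float
    n: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.method} fit (n={self.n})"]
        m = self.model
        if isinstance(m, LinearEEModel):
            lines.append(
                f"  EE = {m.a:.6g} + {m.b:.6g} * mass   "
                f"[{m.ee_unit}; mass in {m.mass_unit.value}, kind={m.mass_kind}]"
            )
            lines.append(f"  reference mass M0 = {m.M0:.6g} {m.mass_unit.value} (sample mean)")
        else:
            lines.append(
                f"  EE = {m.c:.6g} * mass^{m.k:.6g}   "
                f"[{m.ee_unit}; mass in {m.mass_unit.value}]"
            )
        lines.append(f"  rss = {self.rss:.6g} ({self.model.ee_unit})^2;  r2 = {self.r2:.6g}")
        for key, val in self.diagnostics.items():
            lines.append(f"  {key} = {val}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        m = self.model
        if isinstance(m, LinearEEModel):
            params = {"a": m.a, "b": m.b, "M0": m.M0, "mass_kind": m.mass_kind}
        else:
            params = {"c": m.c, "k": m.k}
        return {
            "method": self.method,
            "params": params,
            "mass_unit": m.mass_unit.value,
            "ee_unit": m.ee_unit,
            "rss": self.rss,
            "r2": self.r2,
            "n": self.n,
            **({"diagnostics": self.diagnostics} if self.diagnostics else {}),
        }


def _gof(ee: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum((ee - pred) ** 2))
    tss = float(np.sum((ee - ee.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)
    return rss, r2


class LinearEERegression:
    """OLS of EE on mass; M0 of the returned line is the sample mean mass."""

    def __init__(self, data: EEDataset):
        if np.ptp(data.mass) == 0:
            raise ValueError("mass is constant: the linear design is singular")
        self.data = data

    def fit(self) -> EEFitResults:
        data = self.data
        X = sm.add_constant(data.mass)
        res = sm.OLS(data.ee, X).fit()
        a, b = float(res.params[0]), float(res.params[1])
        model = LinearEEModel(
            a=a,
            b=b,
            M0=float(data.mass.mean()),
            mass_unit=data.mass_unit,
            ee_unit=data.ee_unit,
            mass_kind=data.mass_kind,
        )
        rss, r2 = _gof(data.ee, model.predict(data.mass))
        return EEFitResults(model=model, rss=rss, r2=r2, n=len(data), method="linear_ols")


class LogLogRegression:
    """OLS of ln(EE) on ln(mass), back-transformed to ``c * M**k``.

    RSS and r² are reported in the original EE scale so the result is
    directly comparable with the nonlinear fit.
    """

    def __init__(self, data: EEDataset):
        data.require_positive("log-log regression")
        self.data = data

    def fit(self) -> EEFitResults:
        data = self.data
        X = sm.add_constant(np.log(data.mass))
        res = sm.OLS(np.log(data.ee), X).fit()
        c = float(np.exp(res.params[0]))
        k = float(res.params[1])
        model = PowerLaw(c=c, k=k, mass_unit=data.mass_unit, ee_unit=data.ee_unit)
        rss, r2 = _gof(data.ee, model.predict(data.mass))
        return EEFitResults(model=model, rss=rss, r2=r2, n=len(data), method="loglog")


class PowerLawRegression:
    """Direct nonlinear least squares of ``c * M**k`` to (mass, EE) data.

    Levenberg-damped Gauss–Newton on (c, k) from an explicit initializer
    (typically the tangent-sum reduction).  Deterministic; converges when the
    largest relative parameter step falls below ``xtol`` or raises
    :class:`FitConvergenceError` with diagnostics after ``max_iter``
    iterations.
    """

    def __init__(
        self,
        data: EEDataset,
        init: PowerLaw,
        xtol: float = 1e-10,
        max_iter: int = 200,
    ):
        data.require_positive("power-law regression")
        if init.mass_unit != data.mass_unit:
            init = init.to_unit(data.mass_unit)
        self.data = data
        self.init = init
        self.xtol = xtol
        self.max_iter = max_iter

    def fit(self) -> EEFitResults:
        m, y = self.data.mass, self.data.ee
        logm = np.log(m)
        x = np.array([self.init.c, self.init.k], dtype=float)

        def rss_at(params: np.ndarray) -> float:
            return float(np.sum((y - params[0] * m ** params[1]) ** 2))

        lam = 1e-3
        rss = rss_at(x)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            mk = m ** x[1]
            r = y - x[0] * mk
            J = np.column_stack([mk, x[0] * mk * logm])
            A = J.T @ J
            g = J.T @ r
            # Inner damping loop: inflate lam until the step reduces the RSS.
            step = None
            for _ in range(60):
                damped = A + lam * np.diag(np.maximum(np.diag(A), 1e-300))
                try:
                    cand = np.linalg.solve(damped, g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                x_new = x + cand
                if x_new[0] > 0 and np.isfinite(rss_new := rss_at(x_new)) and rss_new <= rss:
                    step, x, rss = cand, x_new, rss_new
                    lam = max(lam / 3.0, 1e-12)
                    break
                lam *= 3.0
            if step is None:
                break  # no acceptable step: treat as stalled
            rel_step = np.max(np.abs(step) / np.maximum(np.abs(x), 1e-300))
            if rel_step < self.xtol:
                converged = True
                break

        diagnostics = {
            "converged": converged,
            "n_iter": n_iter,
            "lambda": lam,
            "init": {"c": self.init.c, "k": self.init.k},
        }
        if not converged:
            raise FitConvergenceError(
                f"power-law fit did not converge in {self.max_iter} iterations", diagnostics
            )
        model = PowerLaw(
            c=float(x[0]), k=float(x[1]),
            mass_unit=self.data.mass_unit, ee_unit=self.data.ee_unit,
        )
        rss, r2 = _gof(y, model.predict(m))
        return EEFitResults(
            model=model, rss=rss, r2=r2, n=len(self.data),
            method="power_nls", diagnostics=diagnostics,
        )


def fit_linear_ols(data: EEDataset) -> EEFitResults:
    """OLS of EE on mass (see :class:`LinearEERegression`)."""
    return LinearEERegression(data).fit()


def fit_loglog(data: EEDataset) -> EEFitResults:
    """Classical log-log allometric regression (see :class:`LogLogRegression`)."""
    return LogLogRegression(data).fit()


def fit_power_nls(data: EEDataset, init: PowerLaw) -> EEFitResults:
    """Direct nonlinear power-law fit (see :class:`PowerLawRegression`)."""
    return PowerLawRegression(data, init).fit()
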