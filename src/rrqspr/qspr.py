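"""Curvilinear QSPR: polynomial regression of physico-chemical properties on
topological indices, with the diagnostics used in descriptor screening.

The model is ordinary least squares on a degree-1 or degree-2 polynomial of a
single descriptor TI:

    P = α₁·TI + γ                      (linear)
    P = α₁·TI² + α₂·TI + γ             (quadratic)

Fitted models carry R², a residual-based χ² statistic Σ(obs−pred)²/obs
(compared against the 5%-level critical value 37.652 at 25 degrees of
freedom for a 26-molecule study), RMSE under both the /n and /(n−p)
conventions, and the average absolute residual percentage.  Descriptor
screening follows the IAMC recommendation of admitting only descriptors with
R² ≥ 0.8 for a property.

Usage mirrors statsmodels: build a :class:`PolynomialQSPR` model, call
``fit()``, inspect the returned :class:`QSPRResults` (``summary()``,
``predict()``, diagnostics).  :class:`RegressionModel` is the lightweight
coefficient container shared by fitted results and models reconstructed from
published (rounded) coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionModel",
    "PolynomialQSPR",
    "QSPRResults",
    "fit_polynomial",
    "predict",
    "chi_square_gof",
    "avg_residual_percent",
    "rmse",
    "select_best_models",
    "comparison_report",
    "CHI2_CRITICAL_25DF_5PCT",
    "IAMC_R2_THRESHOLD",
]

#: 5%-level chi-square critical value at 25 degrees of freedom, as used for
#: goodness-of-fit screening of the 26-molecule benzenoid study.
CHI2_CRITICAL_25DF_5PCT = 37.652

#: IAMC screening threshold: descriptors with R^2 below this are discarded.
IAMC_R2_THRESHOLD = 0.8


@dataclass
class RegressionModel:
    """Polynomial model P = α₁·TI + γ (degree 1) or α₁·TI² + α₂·TI + γ.

    ``alpha1`` is always the leading coefficient.  Diagnostics are optional:
    a model reconstructed from published coefficients has none until it is
    evaluated against data.
    """

    degree: int
    alpha1: float
    gamma: float
    alpha2: Optional[float] = None
    property_name: str = ""
    index_name: str = ""
    r_squared: Optional[float] = None
    chi_square: Optional[float] = None
    rmse_n: Optional[float] = None
    rmse_n_minus_p: Optional[float] = None
    avg_residual_pct: Optional[float] = None

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.degree == 2 and self.alpha2 is None:
            raise ValueError("degree-2 model needs alpha2")

    @property
    def coefficients(self) -> tuple:
        """(alpha1, gamma) or (alpha1, alpha2, gamma), leading first."""
        if self.degree == 1:
            return (self.alpha1, self.gamma)
        return (self.alpha1, self.alpha2, self.gamma)

    def predict(self, ti) -> np.ndarray | float:
        ti = np.asarray(ti, dtype=float)
        if self.degree == 1:
            out = self.alpha1 * ti + self.gamma
        else:
            out = self.alpha1 * ti**2 + self.alpha2 * ti + self.gamma
        return out if out.ndim else float(out)

    def evaluate(self, x: Sequence[float], y: Sequence[float]) -> "RegressionModel":
        """Populate diagnostics against observed data (in place; returns self)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        yhat = self.predict(x)
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
        # chi-square and residual-% are defined only for positive observations
        self.chi_square = chi_square_gof(y, yhat) if np.all(y > 0) else None
        self.avg_residual_pct = avg_residual_percent(y, yhat) if np.all(y != 0) else None
        p = self.degree + 1
        self.rmse_n = rmse(y, yhat, denominator="n")
        self.rmse_n_minus_p = rmse(y, yhat, denominator="n-p", p=p)
        return self


def predict(model: RegressionModel, ti) -> float | np.ndarray:
    """Evaluate a polynomial model at descriptor value(s) ``ti``."""
    return model.predict(ti)


class PolynomialQSPR:
    """Polynomial QSPR model of one property on one descriptor.

    Parameters
    ----------
    endog : observed property values P (length >= degree + 2)
    exog : descriptor values TI, same length
    degree : 1 (linear) or 2 (quadratic)
    """

    def __init__(self, endog, exog, degree: int = 1,
                 property_name: str = "", index_name: str = ""):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("endog and exog must be equal-length 1-d sequences")
        if len(y) < degree + 2:
            raise ValueError(f"need at least {degree + 2} observations for degree {degree}")
        if np.ptp(x) == 0:
            raise ValueError("descriptor values are all identical (rank-deficient design)")
        self.endog = y
        self.exog = x
        self.degree = degree
        self.property_name = property_name
        self.index_name = index_name

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, property_column: str,
                       index_column: str, degree: int = 1) -> "PolynomialQSPR":
        return cls(
            data[property_column], data[index_column], degree=degree,
            property_name=property_column, index_name=index_column,
        )

    def _design(self, x: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(x), x]
        if self.degree == 2:
            cols.append(x**2)
        return np.column_stack(cols)

    def fit(self) -> "QSPRResults":
        ols = sm.OLS(self.endog, self._design(self.exog)).fit()
        params = ols.params  # [gamma, a1] or [gamma, a1, a2] in design order
        if self.degree == 1:
            rm = RegressionModel(1, alpha1=float(params[1]), gamma=float(params[0]),
                                 property_name=self.property_name, index_name=self.index_name)
        else:
            rm = RegressionModel(2, alpha1=float(params[2]), alpha2=float(params[1]),
                                 gamma=float(params[0]),
                                 property_name=self.property_name, index_name=self.index_name)
        rm.evaluate(self.exog, self.endog)
        return QSPRResults(self, rm, ols)


class QSPRResults:
    """Fitted polynomial QSPR model: coefficients, diagnostics, summary."""

    def __init__(self, model: PolynomialQSPR, regression_model: RegressionModel, ols_results):
        self.model = model
        self.regression_model = regression_model
        self._ols = ols_results

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> tuple:
        return self.regression_model.coefficients

    @property
    def bse(self) -> np.ndarray:
        """Standard errors (constant first, then ascending powers)."""
        return np.asarray(self._ols.bse)

    @property
    def rsquared(self) -> float:
        return self.regression_model.r_squared

    @property
    def chi_square(self) -> float:
        return self.regression_model.chi_square

    @property
    def avg_residual_pct(self) -> float:
        return self.regression_model.avg_residual_pct

    def rmse(self, denominator: str = "n") -> float:
        if denominator == "n":
            return self.regression_model.rmse_n
        if denominator == "n-p":
            return self.regression_model.rmse_n_minus_p
        raise ValueError("denominator must be 'n' or 'n-p'")

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.regression_model.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def predict(self, ti) -> float | np.ndarray:
        return self.regression_model.predict(ti)

    def chi_square_acceptable(self, critical: float = CHI2_CRITICAL_25DF_5PCT) -> bool:
        """Goodness-of-fit screen: χ² below the critical value."""
        return self.chi_square < critical

    def summary(self) -> str:
        rm = self.regression_model
        deg = "linear" if rm.degree == 1 else "quadratic"
        lines = [
            f"Curvilinear QSPR ({deg}) — {rm.property_name or 'P'} ~ {rm.index_name or 'TI'}",
            "-" * 64,
            f"n observations      {len(self.model.endog):>12d}",
        ]
        # self.bse is in design order: const, TI, (TI^2)
        if rm.degree == 1:
            rows = [("alpha1 (TI)", rm.alpha1, self.bse[1])]
        else:
            rows = [("alpha1 (TI^2)", rm.alpha1, self.bse[2]),
                    ("alpha2 (TI)", rm.alpha2, self.bse[1])]
        rows.append(("gamma (const)", rm.gamma, self.bse[0]))
        for name, c, se in rows:
            lines.append(f"{name:<20}{c:>12.6g}   (se {se:.3g})")
        def fmt(v):
            return f"{v:>12.4f}" if v is not None else f"{'n/a':>12}"

        lines += [
            f"{'R^2':<20}{fmt(rm.r_squared)}",
            f"{'chi-square':<20}{fmt(rm.chi_square)}   (critical {CHI2_CRITICAL_25DF_5PCT})",
            f"{'RMSE (/n)':<20}{fmt(rm.rmse_n)}",
            f"{'RMSE (/(n-p))':<20}{fmt(rm.rmse_n_minus_p)}",
            f"{'avg residual %':<20}{fmt(rm.avg_residual_pct)}",
        ]
        return "\n".join(lines)


def fit_polynomial(x: Sequence[float], y: Sequence[float], degree: int,
                   property_name: str = "", index_name: str = "") -> QSPRResults:
    """OLS polynomial fit of property ``y`` on descriptor ``x``."""
    return PolynomialQSPR(y, x, degree=degree, property_name=property_name,
                          index_name=index_name).fit()


# ---------------------------------------------------------------------------
# Diagnostics


def chi_square_gof(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Residual-based goodness-of-fit statistic Σ (obs − pred)² / obs.

    All observed values must be strictly positive.  Compare against a
    chi-square critical value (37.652 at 25 d.o.f., 5% level, for n=26).
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(obs <= 0):
        raise ValueError("chi-square statistic requires strictly positive observed values")
    return float(np.sum((obs - pred) ** 2 / obs))


def avg_residual_percent(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean of 100·|obs − pred| / obs over records."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(obs == 0):
        raise ValueError("average residual percent undefined for zero observed values")
    return float(np.mean(100.0 * np.abs(obs - pred) / obs))


def rmse(observed: Sequence[float], predicted: Sequence[float],
         denominator: str = "n", p: int = 2) -> float:
    """Root-mean-square error with a configurable denominator.

    ``denominator='n'`` divides the residual sum of squares by the number of
    records; ``'n-p'`` by n minus the number of fitted coefficients ``p``
    (default 2, a linear fit).
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(obs)
    if denominator == "n":
        denom = n
    elif denominator == "n-p":
        denom = n - p
    else:
        raise ValueError("denominator must be 'n' or 'n-p'")
    if denom <= 0:
        raise ValueError(f"non-positive denominator {denom}")
    return float(math.sqrt(np.sum((obs - pred) ** 2) / denom))


# ---------------------------------------------------------------------------
# Model selection and comparison


@dataclass
class BestModel:
    """Selection outcome for one property: a winning fit or a flag."""

    property_name: str
    results: Optional[QSPRResults]
    reason: str = ""

    @property
    def selected(self) -> bool:
        return self.results is not None


def select_best_models(properties: pd.DataFrame,
                       index_values: Mapping[str, Sequence[float]],
                       degree: int = 1,
                       threshold: float = IAMC_R2_THRESHOLD) -> dict[str, BestModel]:
    """Per property: fit every descriptor, apply the R² ≥ threshold screen,
    and keep the maximum-R² survivor.

    Ties are broken by fewer coefficients (lower degree never arises here as
    degree is fixed per call) and then lexicographic descriptor name.  A
    property with no survivor is flagged, not raised.
    """
    out: dict[str, BestModel] = {}
    n = len(properties)
    for prop in properties.columns:
        y = properties[prop].to_numpy(dtype=float)
        best: Optional[QSPRResults] = None
        for name in sorted(index_values):
            x = np.asarray(index_values[name], float)
            if len(x) != n:
                raise ValueError(f"descriptor {name!r} has {len(x)} values, expected {n}")
            if np.ptp(y) == 0:
                best = None
                break
            res = fit_polynomial(x, y, degree, property_name=prop, index_name=name)
            if res.rsquared is None or res.rsquared < threshold:
                continue
            if best is None or res.rsquared > best.rsquared:
                best = res
        if np.ptp(y) == 0:
            out[prop] = BestModel(prop, None, "degenerate property (constant values)")
        elif best is None:
            out[prop] = BestModel(prop, None, f"no descriptor reached R^2 >= {threshold}")
        else:
            out[prop] = BestModel(prop, best)
    return out


def comparison_report(properties: pd.DataFrame,
                      rr_values: Mapping[str, Sequence[float]],
                      classical_values: Mapping[str, Sequence[float]],
                      threshold: float = IAMC_R2_THRESHOLD) -> pd.DataFrame:
    """Head-to-head table: per property, the best classical descriptor
    (linear) versus the best reduced-reverse descriptor (linear and
    quadratic), with R² values.  One row per property.
    """
    best_classical = select_best_models(properties, classical_values, 1, threshold)
    best_rr_lin = select_best_models(properties, rr_values, 1, threshold)
    best_rr_quad = select_best_models(properties, rr_values, 2, threshold)
    rows = []
    for prop in properties.columns:
        row: dict = {"property": prop}
        for label, sel in (("classical", best_classical[prop]),
                           ("rr_linear", best_rr_lin[prop]),
                           ("rr_quadratic", best_rr_quad[prop])):
            if sel.selected:
                row[f"{label}_index"] = sel.results.regression_model.index_name
                row[f"{label}_r2"] = sel.results.rsquared
            else:
                row[f"{label}_index"] = sel.reason
                row[f"{label}_r2"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
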