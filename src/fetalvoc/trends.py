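"""Polynomial trend fitting with AIC degree selection and pregnancy-controlled OLS.

Developmental trajectories are summarized by ordinary least-squares polynomial
fits whose degree is chosen by Akaike's information criterion,
``AIC(d) = n ln(RSS_d / n) + 2 (d + 2)`` (Gaussian likelihood; d + 2 parameters
= d + 1 coefficients plus the noise variance). Significance of a gestational-day
effect is assessed by multiple linear regression of the session-level quantity
on gestational day with pregnancy identity as fixed-effect indicator covariates,
followed by the single-term ANOVA nullity test of the day effect (for which
F = t^2 exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class PolyFit:
    """Least-squares polynomial fit.

    Coefficients are highest-degree-first in the standardized variable
    ``(x - x_mean) / x_scale`` (fitting in the raw domain is numerically
    rank-deficient at higher degrees); ``predict`` handles the mapping.
    """

    degree: int
    coefficients: np.ndarray
    aic: float
    x_domain: tuple[float, float]
    rss: float
    x_mean: float = 0.0
    x_scale: float = 1.0

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coefficients, (x - self.x_mean) / self.x_scale)

    @property
    def raw_coefficients(self) -> np.ndarray:
        """Coefficients in the raw x domain (highest-degree-first)."""
        from numpy.polynomial import polynomial as P

        z = np.array([-self.x_mean / self.x_scale, 1.0 / self.x_scale])
        out = np.zeros(1)
        for k, ck in enumerate(self.coefficients[::-1]):
            term = np.array([ck]) if k == 0 else ck * P.polypow(z, k)
            out = P.polyadd(out, term)
        return out[::-1]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    se: float
    t: float
    f: float
    p: float
    df_num: int
    df_den: int
    covariate_set: tuple[str, ...]


def _poly_rss(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    design = np.vander(x, degree + 1)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise ValueError(
            f"rank-deficient design for degree {degree} (rank {rank}): "
            "x values do not support this polynomial"
        )
    resid = y - design @ coef
    return coef, float(resid @ resid)


def poly_aic(n: int, rss: float, degree: int) -> float:
    """AIC(d) = n ln(RSS/n) + 2 (d + 2), with RSS floored to avoid log(0)."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * (degree + 2)


def select_poly_degree_aic(
    x: Sequence[float],
    y: Sequence[float],
    max_degree: int = 10,
    patience: int | None = 2,
    min_improvement: float = 2.0,
) -> int:
    """AIC-guided polynomial degree over 0..max_degree.

    The search walks degrees upward, accepting a higher degree only when it
    lowers AIC by more than ``min_improvement`` (the conventional "delta-AIC
    less than 2 is no substantial support" parsimony rule; a plain argmin
    overfits nested models with probability ~0.25 regardless of sample size),
    and stops once ``patience`` consecutive degrees fail to be accepted
    (two, so that even/odd shapes such as a symmetric inverse-U are still
    reached). ``patience=None`` with ``min_improvement=0`` is the plain
    global argmin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < max_degree + 2:
        raise ValueError(
            f"need at least max_degree + 2 = {max_degree + 2} points, got {x.size}"
        )
    # center/scale x for conditioning; AIC ranking is unaffected
    xs = (x - x.mean()) / (x.std() or 1.0)
    best_degree, best_aic = 0, np.inf
    for d in range(max_degree + 1):
        _, rss = _poly_rss(xs, y, d)
        aic = poly_aic(x.size, rss, d)
        if aic < best_aic - (min_improvement if d > 0 else 0.0):
            best_degree, best_aic = d, aic
        elif patience is not None and d - best_degree >= patience:
            break
    return best_degree


def fit_polynomial(x: Sequence[float], y: Sequence[float], degree: int) -> PolyFit:
    """Ordinary least-squares polynomial of the given degree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= degree:
        raise ValueError(f"need more than {degree} points for degree {degree}")
    x_mean = float(x.mean())
    x_scale = float(x.std()) or 1.0
    coef, rss = _poly_rss((x - x_mean) / x_scale, y, degree)
    return PolyFit(
        degree=degree,
        coefficients=coef,
        aic=poly_aic(x.size, rss, degree),
        x_domain=(float(x.min()), float(x.max())),
        rss=rss,
        x_mean=x_mean,
        x_scale=x_scale,
    )


def fit_polynomial_auto(
    x: Sequence[float],
    y: Sequence[float],
    max_degree: int = 10,
    patience: int | None = 2,
) -> PolyFit:
    """Select the degree by AIC, then fit."""
    degree = select_poly_degree_aic(x, y, max_degree=max_degree, patience=patience)
    return fit_polynomial(x, y, degree)


def regress_with_pregnancy(
    y: Sequence[float],
    gestational_day: Sequence[float],
    pregnancy_id: Sequence,
) -> RegressionResult:
    """OLS of y on gestational day controlling for pregnancy identity.

    Pregnancy enters as reference-coded indicator covariates; the reported
    F and p are the single-term ANOVA nullity test of the gestational-day
    effect (one numerator df, so F = t^2).
    """
    y = np.asarray(y, dtype=float)
    day = np.asarray(gestational_day, dtype=float)
    preg = pd.Series(list(pregnancy_id), dtype="category")
    if not (y.size == day.size == preg.size):
        raise ValueError("y, gestational_day, pregnancy_id must have equal length")
    mask = np.isfinite(y) & np.isfinite(day)
    y, day, preg = y[mask], day[mask], preg[mask.nonzero()[0]]
    covariates = ["gestational_day"]
    X = pd.DataFrame({"gestational_day": day})
    if preg.nunique() >= 2:
        dummies = pd.get_dummies(preg, drop_first=True, dtype=float)
        dummies.columns = [f"pregnancy[{c}]" for c in dummies.columns]
        dummies.index = X.index
        X = pd.concat([X, dummies], axis=1)
        covariates += list(dummies.columns)
    else:
        warnings.warn(
            "fewer than 2 pregnancies; dropping the pregnancy covariate",
            stacklevel=2,
        )
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix in regress_with_pregnancy")
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params["gestational_day"])
    se = float(fit.bse["gestational_day"])
    t = float(fit.tvalues["gestational_day"])
    f = t * t
    df_den = int(fit.df_resid)
    p = float(stats.f.sf(f, 1, df_den))
    return RegressionResult(
        slope=slope,
        se=se,
        t=t,
        f=f,
        p=p,
        df_num=1,
        df_den=df_den,
        covariate_set=tuple(covariates),
    )
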