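"""Questionnaire preprocessing: dichotomization, reliability, EM imputation.

Scale and dimension mean-scores are dichotomized with the uniform-width
method: the variable's range (observed min/max by default, or the
instrument's theoretical range) is split into two equal-width bins and
values at or above the midpoint are labelled "high".  Missing continuous
scores are imputed by multivariate-normal expectation-maximization before
discretization, mirroring common statistics-package practice.
Questionnaire reliability is summarized by Cronbach's alpha and by
intraclass correlation coefficients from a two-way mixed ANOVA
(consistency form, i.e. ICC(3,1) and ICC(3,k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationRule",
    "DegenerateRangeError",
    "fit_discretizer",
    "apply_discretizer",
    "fit_rules",
    "discretize",
    "add_composites",
    "cronbach_alpha",
    "icc_two_way_mixed",
    "em_impute",
    "EMImputeInfo",
    "read_cohort",
    "write_cohort",
]

LOW, HIGH = "low", "high"
MISSING_VALUES = ("", "NA")


class DegenerateRangeError(ValueError):
    """A constant variable leaves the uniform-width boundary undefined."""


@dataclass(frozen=True)
class DiscretizationRule:
    """Two equal-width bins on [lower, upper]; boundary at the midpoint."""

    variable: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DegenerateRangeError(
                f"variable {self.variable!r}: lower bound {self.lower} is not "
                f"below upper bound {self.upper}"
            )

    @property
    def boundary(self) -> float:
        return (self.lower + self.upper) / 2.0


def fit_discretizer(
    values: Sequence[float],
    variable: str = "x",
    range_mode: str = "observed",
    theoretical_range: tuple[float, float] | None = None,
) -> DiscretizationRule:
    """Fit a uniform-width dichotomization rule for one variable.

    ``range_mode`` "observed" uses the non-missing min/max (requires at
    least two distinct values); "theoretical" uses the instrument range.
    """
    if range_mode == "theoretical":
        if theoretical_range is None:
            raise ValueError("theoretical range_mode requires theoretical_range")
        lo, hi = theoretical_range
    elif range_mode == "observed":
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2 or arr.min() == arr.max():
            raise DegenerateRangeError(
                f"variable {variable!r}: observed range is degenerate"
            )
        lo, hi = float(arr.min()), float(arr.max())
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    return DiscretizationRule(variable, lo, hi)


def apply_discretizer(rule: DiscretizationRule, value: float):
    """low / high by the midpoint; ties go to "high"; missing stays missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    return HIGH if value >= rule.boundary else LOW


def fit_rules(
    df: pd.DataFrame,
    columns: Sequence[str] | None = None,
    range_mode: str = "observed",
    theoretical_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, DiscretizationRule]:
    columns = list(columns) if columns is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
    ]
    rules = {}
    for c in columns:
        tr = None if theoretical_ranges is None else theoretical_ranges.get(c)
        mode = range_mode if tr is None or range_mode == "theoretical" else range_mode
        rules[c] = fit_discretizer(df[c].to_numpy(dtype=float), c, mode, tr)
    return rules


def discretize(df: pd.DataFrame, rules: Mapping[str, DiscretizationRule]) -> pd.DataFrame:
    """Vectorized application of per-column rules; other columns pass through."""
    out = df.copy()
    for c, rule in rules.items():
        vals = df[c].to_numpy(dtype=float)
        states = np.where(vals >= rule.boundary, HIGH, LOW).astype(object)
        states[np.isnan(vals)] = np.nan
        out[c] = states
    return out


def add_composites(
    df: pd.DataFrame,
    stress_columns: Sequence[str],
    climate_columns: Sequence[str],
    stress_name: str = "job_stress",
    climate_name: str = "safety_climate",
) -> pd.DataFrame:
    """Append composite mean-score columns (overall stress / climate).

    The study's two composite nodes are the instrument total scores, i.e.
    the mean of the scale (dimension) mean-scores; row means skip missing
    cells, matching how total scores are formed before imputation.
    """
    out = df.copy()
    out[stress_name] = df[list(stress_columns)].mean(axis=1, skipna=True)
    out[climate_name] = df[list(climate_columns)].mean(axis=1, skipna=True)
    return out


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of an (n subjects x k items) score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with unbiased (n-1) sample variances.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing values; impute first")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def icc_two_way_mixed(ratings_matrix) -> tuple[float, float]:
    """ICC(3,1) and ICC(3,k): two-way mixed, consistency form.

    From the two-way ANOVA decomposition of an (n subjects x k measures)
    matrix:  ICC_single = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err),
    ICC_average = (MS_rows - MS_err) / MS_rows.
    """
    x = np.asarray(ratings_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 measures")
    if np.isnan(x).any():
        raise ValueError("ratings matrix contains missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        return 0.0, 0.0
    icc_single = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    icc_average = (ms_rows - ms_err) / ms_rows
    return float(icc_single), float(icc_average)


# ---------------------------------------------------------------------------
# Multivariate-normal EM imputation
# ---------------------------------------------------------------------------


@dataclass
class EMImputeInfo:
    iterations: int
    converged: bool
    loglik_trace: list


def em_impute(
    df: pd.DataFrame,
    columns: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_missing_frac: float = 0.30,
    ridge_scale: float = 1e-8,
) -> tuple[pd.DataFrame, EMImputeInfo]:
    """Impute missing continuous cells by multivariate-normal EM.

    The E-step replaces missing cells with their conditional expectations
    given the observed cells under the current mean/covariance (plus the
    conditional-covariance correction for second moments); the M-step
    updates the moments.  Iterates until the observed-data log-likelihood
    improves by less than ``tol``.  Observed cells are never touched.
    A singular covariance is ridge-regularized by
    ``ridge_scale * trace(S)/p`` on the diagonal.
    """
    columns = list(columns) if columns is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
    ]
    x = df[columns].to_numpy(dtype=float).copy()
    n, p = x.shape
    miss = np.isnan(x)
    frac = miss.mean(axis=0)
    over = [c for c, f in zip(columns, frac) if f > max_missing_frac]
    if over:
        raise ValueError(
            f"missingness exceeds the {max_missing_frac:.0%} ceiling for {over}"
        )
    info = EMImputeInfo(iterations=0, converged=True, loglik_trace=[])
    if not miss.any():
        info.iterations = 1
        return df.copy(), info

    # init: column means; covariance from mean-imputed data
    mu = np.nanmean(x, axis=0)
    filled = np.where(miss, mu, x)
    sigma = np.cov(filled, rowvar=False, ddof=0)
    sigma = np.atleast_2d(sigma)

    def regularize(s: np.ndarray) -> np.ndarray:
        ridge = ridge_scale * np.trace(s) / p
        try:
            np.linalg.cholesky(s + 0.0)
            return s
        except np.linalg.LinAlgError:
            return s + ridge * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.where((miss == key).all(axis=1))[0]
        patterns[key.tobytes()] = rows
    pattern_masks = {k: np.frombuffer(k, dtype=bool) for k in patterns}

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        sigma = regularize(sigma)
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for key, rows in patterns.items():
            m = pattern_masks[key]
            o = ~m
            xo = x[np.ix_(rows, np.where(o)[0])]
            mu_o = mu[o]
            s_oo = sigma[np.ix_(o, o)]
            if o.any():
                # observed-data log-likelihood for this pattern
                s_oo_reg = regularize_sub(s_oo)
                sign, logdet = np.linalg.slogdet(s_oo_reg)
                inv = np.linalg.inv(s_oo_reg)
                diff = xo - mu_o
                quad = np.einsum("ij,jk,ik->i", diff, inv, diff)
                ll += float(
                    -0.5 * (quad.sum() + rows.size * (logdet + o.sum() * np.log(2 * np.pi)))
                )
            comp = x[rows].copy()
            if m.any():
                if o.any():
                    s_mo = sigma[np.ix_(m, o)]
                    beta = s_mo @ inv
                    cond_mean = mu[m] + (diff @ beta.T)
                    cond_cov = sigma[np.ix_(m, m)] - beta @ s_mo.T
                else:
                    cond_mean = np.broadcast_to(mu[m], (rows.size, int(m.sum()))).copy()
                    cond_cov = sigma[np.ix_(m, m)]
                comp[:, m] = cond_mean
                sum_xx[np.ix_(m, m)] += rows.size * cond_cov
            sum_x += comp.sum(axis=0)
            sum_xx += comp.T @ comp
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        info.loglik_trace.append(ll)
        if ll + 1e-8 * (1 + abs(ll)) < prev_ll:
            raise RuntimeError("EM observed-data log-likelihood decreased")
        if abs(ll - prev_ll) < tol:
            info.iterations = it
            info.converged = True
            break
        prev_ll = ll
    else:
        info.iterations = max_iter
        info.converged = False
        warnings.warn(
            f"EM imputation did not converge in {max_iter} iterations; "
            f"log-likelihood trace tail: {info.loglik_trace[-3:]}"
        )

    # final fill with converged parameters
    sigma = regularize(sigma)
    out = x.copy()
    for key, rows in patterns.items():
        m = pattern_masks[key]
        if not m.any():
            continue
        o = ~m
        if o.any():
            s_oo = regularize_sub(sigma[np.ix_(o, o)])
            inv = np.linalg.inv(s_oo)
            beta = sigma[np.ix_(m, o)] @ inv
            diff = x[np.ix_(rows, np.where(o)[0])] - mu[o]
            out[np.ix_(rows, np.where(m)[0])] = mu[m] + diff @ beta.T
        else:
            out[np.ix_(rows, np.where(m)[0])] = mu[m]
    result = df.copy()
    result[columns] = out
    return result, info


def regularize_sub(s: np.ndarray, ridge_scale: float = 1e-8) -> np.ndarray:
    """Ridge-regularize a covariance block if it is numerically singular."""
    s = np.atleast_2d(s)
    try:
        np.linalg.cholesky(s)
        return s
    except np.linalg.LinAlgError:
        k = s.shape[0]
        return s + (ridge_scale * np.trace(s) / max(k, 1) + 1e-12) * np.eye(k)


# ---------------------------------------------------------------------------
# Cohort file IO
# ---------------------------------------------------------------------------


def read_cohort(path) -> pd.DataFrame:
    """Read the delimited cohort table (empty cell or "NA" = missing)."""
    df = pd.read_csv(path, na_values=list(MISSING_VALUES), keep_default_na=False)
    if "accident" in df.columns and df["accident"].isna().any():
        raise ValueError("accident outcome must always be observed")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="NA")
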