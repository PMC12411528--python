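"""Spearman rank-correlation analysis for small cohorts.

Every EIT-derived variable is correlated against every CT/PFT variable with
Spearman's rho (Pearson correlation of mid-ranks), a two-sided P value, and
a 95% confidence interval.  For the tiny cohorts this analysis targets
(n <= 8) the P value is computed by exact enumeration of all n! rank
permutations; larger samples fall back to the t-distributed approximation
t = rho * sqrt((n-2) / (1 - rho^2)).  Confidence intervals use the Fisher
z-transform with variance 1.06/(n-3) by default, or a seeded pairwise
bootstrap.  Significance is gated at P < 0.01 with no multiplicity
correction; Benjamini-Hochberg adjusted P values are emitted as an extra,
clearly labeled column for readers who want them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "spearman_rho",
    "spearman_p",
    "exact_permutation_p",
    "spearman_ci",
    "correlation_matrix",
]

EXACT_MAX_N = 10


@dataclass
class AssociationResult:
    """One cell of the EIT-by-CT correlation matrix."""

    var_x: str
    var_y: str
    n: int
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool
    p_method: str = ""
    ci_method: str = ""


def _validate_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length one-dimensional arrays")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values must be removed upstream")
    return x, y


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks (average ranks on ties).

    Returns NaN when either vector is constant (correlation undefined).
    """
    x, y = _validate_pair(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! permutations (untied ranks)."""
    ident = np.arange(n)
    perms = np.array(list(itertools.permutations(range(n))))
    d2 = ((perms - ident) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return np.sort(np.abs(rho))


def spearman_p(rho: float, n: int, method: str = "auto") -> float:
    """Two-sided P value for an observed Spearman rho.

    ``exact_permutation`` enumerates all n! rank permutations (untied data;
    refused above n = 10 because of factorial blow-up); ``t_approx`` uses the
    t statistic with n - 2 degrees of freedom; ``auto`` picks exact for
    n <= 8.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if math.isnan(rho):
        return float("nan")
    if method == "auto":
        method = "exact_permutation" if n <= 8 else "t_approx"
    if method == "exact_permutation":
        if n > EXACT_MAX_N:
            raise ValueError(
                f"exact permutation enumeration refused for n={n} > {EXACT_MAX_N} "
                f"({math.factorial(n)} permutations)"
            )
        null = _exact_null_abs_rho(n)
        k = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return float(k / null.size)
    if method == "t_approx":
        if abs(rho) >= 1.0:
            return 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    raise ValueError(f"unknown method {method!r}")


def exact_permutation_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided permutation P value computed from the data.

    Handles ties by enumerating permutations of the mid-ranks of y; for
    untied data this reduces to the cached rank-difference enumeration.
    """
    x, y = _validate_pair(x, y)
    n = x.size
    if n > EXACT_MAX_N:
        raise ValueError(f"exact permutation enumeration refused for n={n} > {EXACT_MAX_N}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    untied = (np.unique(rx).size == n) and (np.unique(ry).size == n)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    if untied:
        return spearman_p(rho_obs, n, method="exact_permutation")
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    rho_all = (ryc @ rxc) / np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def spearman_ci(x: Sequence[float], y: Sequence[float], level: float = 0.95,
                method: str = "fisher_z", n_boot: int = 10_000,
                seed: Optional[int] = None) -> Tuple[float, float]:
    """Confidence interval for Spearman's rho.

    ``fisher_z`` transforms rho with atanh and uses variance 1.06/(n-3);
    ``bootstrap`` resamples subject pairs with replacement (percentile
    interval, seeded).  Requires n >= 4.
    """
    x, y = _validate_pair(x, y, min_n=4)
    n = x.size
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return float("nan"), float("nan")
    if method == "fisher_z":
        z = math.atanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        se = math.sqrt(1.06 / (n - 3))
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rhos = np.empty(n_boot)
        for b in range(n_boot):
            rb = spearman_rho(x[idx[b]], y[idx[b]])
            rhos[b] = rho if math.isnan(rb) else rb
        lo = float(np.quantile(rhos, (1 - level) / 2.0))
        hi = float(np.quantile(rhos, 0.5 + level / 2.0))
        return lo, hi
    raise ValueError(f"unknown method {method!r}")


def correlation_matrix(cohort: pd.DataFrame,
                       x_vars: Sequence[str],
                       y_vars: Sequence[str],
                       alpha: float = 0.01,
                       p_method: str = "auto",
                       ci_method: str = "fisher_z",
                       ci_level: float = 0.95,
                       n_boot: int = 10_000,
                       seed: Optional[int] = None) -> pd.DataFrame:
    """All-pairs Spearman associations between two variable panels.

    One row per (x, y) pair with pairwise-complete observations.  The
    ``significant`` flag applies the uncorrected P < alpha gate; the ``p_bh``
    column adds Benjamini-Hochberg adjusted P values as a labeled extension.
    """
    if not len(x_vars) or not len(y_vars):
        raise ValueError("x_vars and y_vars must be non-empty")
    missing = (set(x_vars) | set(y_vars)) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns {sorted(missing)}")
    rows: List[AssociationResult] = []
    for vx in x_vars:
        for vy in y_vars:
            pair = cohort[[vx, vy]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"pair ({vx}, {vy}) has only {len(pair)} complete observations"
                )
            x = pair[vx].to_numpy(dtype=float)
            y = pair[vy].to_numpy(dtype=float)
            n = x.size
            rho = spearman_rho(x, y)
            method = p_method
            if method == "auto":
                method = "exact_permutation" if n <= 8 else "t_approx"
            if math.isnan(rho):
                p = float("nan")
            elif method == "exact_permutation":
                p = exact_permutation_p(x, y)
            else:
                p = spearman_p(rho, n, method=method)
            if math.isnan(rho) or n < 4:
                ci_lo, ci_hi = float("nan"), float("nan")
            else:
                ci_lo, ci_hi = spearman_ci(x, y, level=ci_level, method=ci_method,
                                           n_boot=n_boot, seed=seed)
                ci_lo = min(ci_lo, rho)
                ci_hi = max(ci_hi, rho)
            rows.append(AssociationResult(
                var_x=vx, var_y=vy, n=n, rho=rho, p_value=p,
                ci_low=ci_lo, ci_high=ci_hi,
                significant=bool(p < alpha) if not math.isnan(p) else False,
                p_method=method, ci_method=ci_method,
            ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    valid = df["p_value"].notna()
    df["p_bh"] = np.nan
    if valid.any():
        df.loc[valid, "p_bh"] = multipletests(df.loc[valid, "p_value"], method="fdr_bh")[1]
    return df
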