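"""Exploitation-trait association statistics.

Distribution comparisons between exploited and non-exploited species
(one- or two-sided Kolmogorov-Smirnov), exact binomial confidence intervals
for per-functional-category exploitation proportions, Wilcoxon rank-sum
comparisons (e.g. regional body sizes), and the deterministic hierarchical
logistic model of exploitation on standardized traits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import fit_logistic_mixed
from .types import ModelFit, SpeciesRecord

__all__ = [
    "ks_two_sample",
    "binomial_ci",
    "rank_sum",
    "build_design",
    "fit_exploitation_model",
    "CONTINUOUS_PREDICTORS",
    "CATEGORICAL_PREDICTORS",
]

#: continuous predictors -> (record attribute, log10-transform before z-scoring)
CONTINUOUS_PREDICTORS = {
    "size": ("shell_size", True),
    "min_bathymetry": ("min_bathymetry", True),
    "geographic_range": ("geographic_range_area", True),
    "thermal_range": ("thermal_range", False),
}

#: categorical predictors -> (record attribute, reference level)
CATEGORICAL_PREDICTORS = {
    "feeding": ("feeding", "suspension"),
    "attachment": ("attachment", "unattached"),
    "mobility": ("mobility", "mobile"),
    "position": ("position", "infaunal"),
}


def ks_two_sample(
    a, b, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``alternative='less'`` tests whether the ECDF of ``a`` lies below that of
    ``b`` (i.e. ``a`` stochastically larger); ``'greater'`` the reverse. The
    p-value uses the asymptotic KS distribution at the effective sample size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    res = sps.ks_2samp(a, b, alternative=alt, method="asymp")
    return float(res.statistic), float(res.pvalue)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k successes of n.

    Uses the beta-quantile identity; the lower bound is 0 when k = 0 and the
    upper bound 1 when k = n."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("require 0 <= k <= n with n > 0")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def rank_sum(a, b, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank sum of sample a, p-value).

    Small tie-free samples (min n <= 20) are evaluated by exact enumeration;
    otherwise the normal approximation with continuity and tie correction is
    used. Ties take midranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = min(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alt, method=method, use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def build_design(
    records: list[SpeciesRecord],
    predictors: list[str],
    transform: str = "log10",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix for the exploitation model.

    Continuous traits spanning orders of magnitude (size, range area,
    bathymetry + 1) are log10-transformed when ``transform='log10'``; all
    continuous predictors are then z-standardized so coefficients are
    log-odds per standard deviation. Categorical predictors are dummy-coded
    against a fixed reference level. Records missing any requested predictor
    are dropped. Returns ``(X, y, family_index, column_names)`` with X
    including a leading intercept column.
    """
    if transform not in {"log10", "none"}:
        raise ValueError("transform must be 'log10' or 'none'")
    unknown = [p for p in predictors if p not in CONTINUOUS_PREDICTORS
               and p not in CATEGORICAL_PREDICTORS]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")

    usable = []
    for r in records:
        ok = True
        for p in predictors:
            attr = (CONTINUOUS_PREDICTORS.get(p) or CATEGORICAL_PREDICTORS[p])[0]
            if getattr(r, attr) is None:
                ok = False
                break
        if ok:
            usable.append(r)
    if len(usable) < 10:
        raise ValueError("too few complete records for the model")

    cols: list[np.ndarray] = [np.ones(len(usable))]
    names = ["intercept"]
    for p in predictors:
        if p in CONTINUOUS_PREDICTORS:
            attr, do_log = CONTINUOUS_PREDICTORS[p]
            v = np.array([float(getattr(r, attr)) for r in usable])
            if transform == "log10" and do_log:
                v = np.log10(v + 1.0) if attr == "min_bathymetry" else np.log10(v)
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValueError(f"predictor {p} is constant")
            cols.append((v - v.mean()) / sd)
            names.append(p)
        else:
            attr, ref = CATEGORICAL_PREDICTORS[p]
            levels = sorted({getattr(r, attr) for r in usable} - {ref})
            for lev in levels:
                cols.append(
                    np.array([1.0 if getattr(r, attr) == lev else 0.0 for r in usable])
                )
                names.append(f"{p}[{lev}]")
    X = np.column_stack(cols)
    y = np.array([1.0 if r.exploited else 0.0 for r in usable])
    fams = sorted({r.family for r in usable})
    fmap = {f: i for i, f in enumerate(fams)}
    fidx = np.array([fmap[r.family] for r in usable], dtype=int)
    return X, y, fidx, names


def fit_exploitation_model(
    records: list[SpeciesRecord],
    predictors: list[str] | None = None,
    transform: str = "log10",
    n_quad: int = 9,
) -> ModelFit:
    """ML fit of exploitation ~ standardized traits + (1 | family).

    Coefficients are log-odds per standard deviation of the (optionally
    log10-transformed) trait; the family effect is a Gaussian random
    intercept integrated out by adaptive Gauss-Hermite quadrature.
    """
    if predictors is None:
        predictors = ["size", "min_bathymetry", "geographic_range", "thermal_range"]
    X, y, fidx, names = build_design(records, predictors, transform=transform)
    fit = fit_logistic_mixed(X, y, fidx, n_quad=n_quad)
    coef = dict(zip(names[1:], [float(b) for b in fit["beta"][1:]]))
    return ModelFit(
        coefficients=coef,
        intercept=float(fit["beta"][0]),
        sigma_family=fit["sigma"],
        loglik=fit["loglik"],
        converged=fit["converged"],
        n_obs=fit["n_obs"],
        n_families=fit["n_families"],
        separation_flag=fit["separation_flag"],
    )
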