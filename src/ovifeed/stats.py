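"""Descriptive trait statistics: correlations, period comparisons, repeatability.

Correlations are Pearson with two-sided t-based p-values on pairwise-complete
observations; significance is flagged at p < 0.05.  Period comparisons use
Welch's unequal-variance two-tailed t-test (the trait SDs differ up to
four-fold between growth and maintenance, so a pooled test would be wrong).

Repeatability is the intraclass correlation from a one-way random-intercept
model, y_ij = mu + a_i + e_ij with animal as the grouping factor, fitted by
restricted maximum likelihood:

    R = sigma2_animal / (sigma2_animal + sigma2_residual).

Uncertainty comes from a parametric bootstrap: resimulate responses from the
fitted variances on the same design, refit, and take the standard deviation
and percentile interval of the refitted R.  Negative variance estimates are
truncated at zero, so R = 0 is returned (not an error) when all variance is
within animals.  An option to standardise values within period exists because
pooling raw periods with very unequal variances shrinks R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import InsufficientDataError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# correlations and period comparison
# ---------------------------------------------------------------------------

def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    r, p = sps.pearsonr(x[ok], y[ok])
    return float(r), float(p), n


def correlation_matrix(
    pheno: pd.DataFrame, traits: list[str], alpha: float = ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix over trait columns.

    Returns (r, p, significant) DataFrames indexed by trait; pairwise-complete
    observations, unit diagonal, two-sided p from the exact t reference.
    """
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij, _ = _pairwise_pearson(
                pheno[traits[i]].to_numpy(dtype=float),
                pheno[traits[j]].to_numpy(dtype=float),
            )
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    return rdf, pdf, pdf < alpha


def between_period_correlations(
    pheno1: pd.DataFrame, pheno2: pd.DataFrame, traits: list[str], alpha: float = ALPHA
) -> pd.DataFrame:
    """Per-trait correlation of the same trait measured in two periods.

    Animals are matched on animal_id; an animal missing a trait in either
    period is excluded for that trait only.
    """
    merged = pheno1.merge(pheno2, on="animal_id", suffixes=("_p1", "_p2"))
    rows = []
    for t in traits:
        r, p, n = _pairwise_pearson(
            merged[f"{t}_p1"].to_numpy(dtype=float), merged[f"{t}_p2"].to_numpy(dtype=float)
        )
        rows.append({"trait": t, "r": r, "p": p, "n": n, "significant": bool(p < alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows)


def compare_periods(values1, values2) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test between period trait values."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("need >= 2 values per period")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# repeatability (intraclass correlation) by REML
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityEstimate:
    """Intraclass correlation with parametric-bootstrap uncertainty."""

    r: float
    se: float | None
    ci: tuple[float, float] | None
    sigma2_animal: float
    sigma2_residual: float
    n_animals: int
    n_obs: int
    n_bootstrap: int


def _reml_oneway(values: np.ndarray, group_sizes: np.ndarray, group_sums: np.ndarray):
    """REML fit of the one-way random-intercept model.

    Profiles the residual variance out of the REML criterion and optimises the
    variance ratio lam = sigma2_animal / sigma2_residual by bounded Brent
    search on log(lam).  Returns (sigma2_animal, sigma2_residual).
    """
    n_total = values.size
    sum_sq = float(np.sum(values**2))

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        shrink = lam / (1.0 + lam * group_sizes)
        xtvx = float(np.sum(group_sizes / (1.0 + lam * group_sizes)))
        beta = float(np.sum(group_sums / (1.0 + lam * group_sizes))) / xtvx
        # (y-Xb)' V^-1 (y-Xb) with V_i = I + lam J, via Woodbury
        centered_sums = group_sums - group_sizes * beta
        rss = sum_sq - 2 * beta * float(group_sums.sum()) + beta**2 * n_total
        rss -= float(np.sum(shrink * centered_sums**2))
        rss = max(rss, 1e-300)
        return (
            (n_total - 1) * np.log(rss / (n_total - 1))
            + float(np.sum(np.log1p(lam * group_sizes)))
            + np.log(xtvx)
        )

    lo, hi = -14.0, 14.0
    res = optimize.minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    best = res.x
    # the boundary lam -> 0 (R = 0) may beat the interior optimum
    if neg2_reml(lo) <= res.fun + 1e-12 or best <= lo + 1e-6:
        lam = 0.0
    else:
        lam = float(np.exp(best))
    shrink = lam / (1.0 + lam * group_sizes) if lam > 0 else np.zeros_like(group_sizes, dtype=float)
    xtvx = float(np.sum(group_sizes / (1.0 + lam * group_sizes)))
    beta = float(np.sum(group_sums / (1.0 + lam * group_sizes))) / xtvx
    centered_sums = group_sums - group_sizes * beta
    rss = sum_sq - 2 * beta * float(group_sums.sum()) + beta**2 * n_total
    rss -= float(np.sum(shrink * centered_sums**2))
    sigma2_e = max(rss, 0.0) / (n_total - 1)
    return lam * sigma2_e, sigma2_e


def repeatability(
    data: pd.DataFrame,
    *,
    value_col: str = "value",
    group_col: str = "animal_id",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
    standardize_within: str | None = None,
) -> RepeatabilityEstimate:
    """Repeatability of a trait measured repeatedly on the same animals.

    `data` is long-format with one row per (animal, measurement); with
    ``standardize_within`` naming a period column, values are z-scored within
    each period before fitting (default off: raw values, matching common
    practice even when period variances differ).
    """
    df = data[[group_col, value_col] + ([standardize_within] if standardize_within else [])].dropna()
    if standardize_within:
        df = df.copy()
        df[value_col] = df.groupby(standardize_within)[value_col].transform(
            lambda v: (v - v.mean()) / v.std(ddof=1)
        )
    counts = df.groupby(group_col)[value_col].count()
    keep = counts[counts >= 2].index
    if len(keep) < 3:
        raise InsufficientDataError("need >= 3 animals with >= 2 measurements each")
    df = df[df[group_col].isin(keep)]
    values = df[value_col].to_numpy(dtype=float)
    groups, codes = np.unique(df[group_col].to_numpy(), return_inverse=True)
    group_sizes = np.bincount(codes).astype(float)
    group_sums = np.bincount(codes, weights=values)
    # degenerate case: animals perfectly consistent across measurements
    within_ss = float(np.sum((values - group_sums[codes] / group_sizes[codes]) ** 2))
    if within_ss == 0.0 and np.std(group_sums / group_sizes) > 0:
        s2a = float(np.var(group_sums / group_sizes, ddof=1))
        est = RepeatabilityEstimate(1.0, None, None, s2a, 0.0, len(groups), values.size, 0)
        s2_pair = (s2a, 0.0)
    else:
        values_c = values - values.mean()
        s2a, s2e = _reml_oneway(values_c, group_sizes, np.bincount(codes, weights=values_c))
        r = s2a / (s2a + s2e) if (s2a + s2e) > 0 else 0.0
        est = RepeatabilityEstimate(float(np.clip(r, 0.0, 1.0)), None, None, s2a, s2e,
                                    len(groups), values.size, 0)
        s2_pair = (s2a, s2e)

    if n_boot > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        s2a, s2e = s2_pair
        boots = np.empty(n_boot)
        for b in range(n_boot):
            a = rng.normal(0.0, np.sqrt(s2a), size=len(groups))
            y = a[codes] + rng.normal(0.0, np.sqrt(s2e), size=values.size)
            ba, be = _reml_oneway(y - y.mean(), group_sizes, np.bincount(codes, weights=y - y.mean()))
            boots[b] = ba / (ba + be) if (ba + be) > 0 else 0.0
        boots = np.clip(boots, 0.0, 1.0)
        tail = (1.0 - ci_level) / 2.0
        est.se = float(np.std(boots, ddof=1))
        est.ci = (float(np.quantile(boots, tail)), float(np.quantile(boots, 1.0 - tail)))
        est.n_bootstrap = n_boot
    return est


def anova_icc(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation for balanced designs.

    Mean-squares estimator ICC = (MSB − MSW) / (MSB + (k−1)·MSW), truncated at
    zero; for balanced data with the REML optimum interior this equals the
    REML repeatability.  Used as an independent cross-check.
    """
    values = np.asarray(values, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    sizes = np.bincount(codes)
    if len(set(sizes)) != 1:
        raise InsufficientDataError("anova_icc requires a balanced design")
    k = int(sizes[0])
    n_groups = len(labels)
    means = np.bincount(codes, weights=values) / k
    grand = values.mean()
    msb = k * np.sum((means - grand) ** 2) / (n_groups - 1)
    msw = np.sum((values - means[codes]) ** 2) / (n_groups * (k - 1))
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return float(max(icc, 0.0))
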