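"""Genotype quality control, genomic relationships, and mixed-model association.

The association model is the standard single-marker linear mixed model

    y = X b + g a_j + u + e,   u ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I),

with K the genomic relationship matrix (VanRaden method 1: dosage columns
centred by twice the observed allele frequency, cross-product scaled by
2 * sum_j p_j (1 - p_j)).  Variance components are estimated once under the
null model (no SNP) by restricted maximum likelihood using the spectral
decomposition of K, after which every SNP is tested by generalised least
squares with the covariance held fixed — the EMMAX approximation.  The Wald
statistic uses the exact t reference with n − rank([X | g]) degrees of
freedom rather than a normal approximation, which matters at cohort sizes of
a few dozen animals.  Family-wise error is controlled by Bonferroni.

Quality control applies, in order: multi-allelic removal, SNP call rate,
individual call rate, then minor allele frequency recomputed on the retained
individuals.  Removals are strict inequalities — a SNP at exactly the call
rate or MAF threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import EmptyPanelError, InsufficientDataError, SingularFitError
from .io import MISSING, GenotypeMatrix

_TINY_P = 5e-324  # smallest subnormal double; keeps p in (0, 1]


# ---------------------------------------------------------------------------
# quality control and dosage coding
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Bookkeeping for one QC pass; removal reasons are disjoint, applied in
    the order multi-allelic -> SNP call rate -> individual call rate -> MAF."""

    n_snps_in: int
    n_removed_multi_allelic: int
    n_removed_snp_call_rate: int
    n_removed_maf: int
    n_snps_kept: int
    n_individuals_in: int
    n_individuals_removed: int
    n_individuals_kept: int
    snp_call_rate_min: float
    ind_call_rate_min: float
    maf_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def qc_filter(
    G: GenotypeMatrix,
    snp_call_rate_min: float = 0.90,
    ind_call_rate_min: float = 0.90,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove multi-allelic / low-call-rate / rare SNPs and low-call-rate animals."""
    n, m = G.n_animals, G.n_snps
    observed = G.calls != MISSING

    snp_keep = ~G.multi_allelic
    n_multi = int(G.multi_allelic.sum())

    call_rate_snp = observed.mean(axis=0)
    fail_cr = snp_keep & (call_rate_snp < snp_call_rate_min)
    n_cr = int(fail_cr.sum())
    snp_keep &= ~fail_cr

    ind_call_rate = observed[:, snp_keep].mean(axis=1) if snp_keep.any() else np.zeros(n)
    ind_keep = ind_call_rate >= ind_call_rate_min
    n_ind_removed = int((~ind_keep).sum())

    # MAF recomputed on retained individuals only
    sub_calls = G.calls[np.ix_(ind_keep, snp_keep)].astype(float)
    sub_calls[sub_calls == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(sub_calls, axis=0) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep_idx = np.flatnonzero(snp_keep)
    fail_maf = keep_idx[maf < maf_min]
    n_maf = len(fail_maf)
    snp_keep[fail_maf] = False

    if not snp_keep.any():
        raise EmptyPanelError("quality control removed every SNP")

    out = G.subset(np.flatnonzero(ind_keep), np.flatnonzero(snp_keep))
    report = QcReport(
        n_snps_in=m,
        n_removed_multi_allelic=n_multi,
        n_removed_snp_call_rate=n_cr,
        n_removed_maf=n_maf,
        n_snps_kept=int(snp_keep.sum()),
        n_individuals_in=n,
        n_individuals_removed=n_ind_removed,
        n_individuals_kept=int(ind_keep.sum()),
        snp_call_rate_min=snp_call_rate_min,
        ind_call_rate_min=ind_call_rate_min,
        maf_min=maf_min,
    )
    return out, report


def allele_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Additive coding: count of the A1 allele per animal/SNP, in [0, 2].

    Missing calls are imputed with the SNP's mean observed dosage, which
    preserves the SNP's observed allele frequency exactly and keeps one
    spectral transform shared across all SNPs in the scan.
    """
    dose = G.calls.astype(float)
    dose[dose == MISSING] = np.nan
    col_mean = np.nanmean(dose, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    nan_mask = np.isnan(dose)
    dose[nan_mask] = np.broadcast_to(col_mean, dose.shape)[nan_mask]
    return dose


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GRM:
    """Symmetric animal × animal genomic relationship matrix (VanRaden 1)."""

    animal_ids: list[str]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.animal_ids, columns=self.animal_ids)


def compute_grm(dosage: np.ndarray, animal_ids: list[str] | None = None) -> GRM:
    """VanRaden method 1: K = Z Z' / (2 Σ p_j (1−p_j)), Z centred by 2 p_j.

    Allele frequencies are observed frequencies; monomorphic SNPs carry no
    information and are skipped.
    """
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if n < 2:
        raise InsufficientDataError("GRM needs >= 2 animals")
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise InsufficientDataError("GRM needs >= 1 polymorphic SNP")
    Z = dosage[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = Z @ Z.T / denom
    K = (K + K.T) / 2.0
    ids = animal_ids if animal_ids is not None else [str(i) for i in range(n)]
    return GRM(list(ids), K)


# ---------------------------------------------------------------------------
# null-model REML via spectral decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance components of the null mixed model."""

    sigma2_g: float
    sigma2_e: float
    delta: float          # sigma2_e / sigma2_g; inf at the sigma2_g = 0 boundary
    loglik: float         # REML log-likelihood at the optimum


def _restricted_eigen(K: np.ndarray, X: np.ndarray):
    """Eigenpairs of S K S restricted to the complement of the column space of X."""
    n, q = X.shape
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    vals, vecs = np.linalg.eigh(S @ K @ S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = np.clip(vals[: n - q], 0.0, None)
    return lam, vecs[:, : n - q]


def reml_loglik(delta: float, lam: np.ndarray, eta: np.ndarray) -> float:
    """Profiled REML log-likelihood at variance ratio delta = sigma2_e/sigma2_g."""
    nq = lam.size
    denom = lam + delta
    quad = float(np.sum(eta**2 / denom))
    return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(quad)) - float(np.sum(np.log(denom))))


def fit_null(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> VarianceComponents:
    """REML estimate of (sigma2_g, sigma2_e) for y = X b + u + e, u ~ N(0, sigma2_g K).

    One spectral decomposition reduces the problem to a one-dimensional
    optimisation of the profiled REML log-likelihood in log(delta) over a
    bounded grid refined by Brent's method.  A boundary optimum (delta -> inf)
    is returned as sigma2_g = 0 with the residual variance from ordinary
    least squares, never raised as an error.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q = X.shape
    if not np.all(np.isfinite(y)):
        raise InsufficientDataError("phenotype contains non-finite values")
    if np.linalg.matrix_rank(X) < q:
        raise SingularFitError("covariate design is rank deficient")
    lam, U = _restricted_eigen(np.asarray(K, dtype=float), X)
    eta = U.T @ y

    lo, hi = -10.0, 10.0
    grid = np.linspace(lo, hi, 100)
    vals = np.array([reml_loglik(np.exp(g), lam, eta) for g in grid])
    k = int(np.argmax(vals))
    if k == len(grid) - 1:
        # delta -> inf: no genetic variance; the model collapses to OLS
        beta, rss0, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        return VarianceComponents(0.0, rss / (n - q), np.inf, reml_loglik(np.exp(hi), lam, eta))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -reml_loglik(np.exp(g), lam, eta),
        bounds=(a, b), method="bounded", options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    sigma2_g = float(np.sum(eta**2 / (lam + delta))) / (n - q)
    return VarianceComponents(sigma2_g, delta * sigma2_g, delta, float(-res.fun))


# ---------------------------------------------------------------------------
# EMMAX scan
# ---------------------------------------------------------------------------

def snp_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    dosage: np.ndarray,
    vc: VarianceComponents,
    *,
    snp_ids: list[str] | None = None,
    chromosome: np.ndarray | None = None,
    position_bp: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every SNP by GLS under V = sigma2_g K + sigma2_e I (EMMAX).

    Variance components stay fixed at the null fit.  Each SNP's effect is the
    generalised-least-squares coefficient of its dosage added to the covariate
    design; the Wald test uses the t reference with n − rank([X | g]) degrees
    of freedom.  A SNP collinear with the covariates is flagged degenerate
    with effect 0 and p = 1.  The significance flag applies the Bonferroni
    threshold alpha / (number of SNPs tested).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dosage = np.asarray(dosage, dtype=float)
    n, q = X.shape
    m = dosage.shape[1]

    if vc.sigma2_g > 0:
        s, U = np.linalg.eigh(np.asarray(K, dtype=float))
        d = vc.sigma2_g * np.clip(s, 0.0, None) + vc.sigma2_e
        w = 1.0 / np.sqrt(d)
        yt = w * (U.T @ y)
        Xt = w[:, None] * (U.T @ X)
        Gt = w[:, None] * (U.T @ dosage)
    else:  # no genetic variance: plain OLS geometry
        yt, Xt, Gt = y / np.sqrt(vc.sigma2_e), X / np.sqrt(vc.sigma2_e), dosage / np.sqrt(vc.sigma2_e)

    Q, _ = np.linalg.qr(Xt)
    resid_y = yt - Q @ (Q.T @ yt)
    resid_G = Gt - Q @ (Q.T @ Gt)

    gtg = np.einsum("ij,ij->j", resid_G, resid_G)
    scale = np.einsum("ij,ij->j", Gt, Gt)
    degenerate = gtg <= 1e-12 * np.maximum(scale, 1.0)
    gtg_safe = np.where(degenerate, 1.0, gtg)

    beta = (resid_G.T @ resid_y) / gtg_safe
    rss = float(resid_y @ resid_y) - beta**2 * gtg_safe
    df = n - q - 1
    if df <= 0:
        raise InsufficientDataError("no residual degrees of freedom for the SNP test")
    se = np.sqrt(np.maximum(rss, 0.0) / df / gtg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * sps.t.sf(np.abs(tstat), df)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    pval = np.where(degenerate, 1.0, np.clip(pval, _TINY_P, 1.0))

    threshold = bonferroni_threshold(m, alpha)
    out = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)],
            "chromosome": chromosome if chromosome is not None else np.repeat("1", m),
            "position_bp": position_bp if position_bp is not None else np.arange(1, m + 1),
            "beta": beta,
            "se": se,
            "p": pval,
            "neg_log10_p": -np.log10(pval),
            "degenerate": degenerate,
        }
    )
    out["significant"] = out["p"] < threshold
    return out


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling family-wise error: alpha / m."""
    if m < 1:
        raise InsufficientDataError("need at least one test")
    return alpha / m


# ---------------------------------------------------------------------------
# Manhattan table
# ---------------------------------------------------------------------------

def _chrom_sort_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, str(label))


def manhattan_table(
    results: pd.DataFrame, threshold: float, window_bp: int = 1_000_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay chromosomes end to end for plotting and list significant hits.

    Returns ``(table, hits)``: `table` adds a strictly increasing cumulative
    genome coordinate and the −log10 threshold line; `hits` lists SNPs with
    p < threshold together with the ±`window_bp` candidate-gene window around
    each (the interval screened for nearby genes).
    """
    df = results.copy()
    df["chromosome"] = df["chromosome"].astype(str)
    chroms = sorted(df["chromosome"].unique(), key=_chrom_sort_key)
    offset = 0
    offsets = {}
    for c in chroms:
        offsets[c] = offset
        offset += int(df.loc[df["chromosome"] == c, "position_bp"].max()) + 1
    df["cum_pos"] = df["position_bp"] + df["chromosome"].map(offsets)
    df["threshold_neg_log10"] = -np.log10(threshold)
    df = df.sort_values(["cum_pos"]).reset_index(drop=True)

    hits = df[df["p"] < threshold].copy()
    hits["window_start_bp"] = hits["position_bp"] - window_bp
    hits["window_end_bp"] = hits["position_bp"] + window_bp
    return df, hits.reset_index(drop=True)
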