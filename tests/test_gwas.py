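import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ovifeed import (
    EmptyPanelError,
    GenotypeMatrix,
    allele_dosage,
    bonferroni_threshold,
    compute_grm,
    fit_null,
    manhattan_table,
    qc_filter,
    simulate_genotypes,
    snp_scan,
)
from ovifeed.gwas import reml_loglik, _restricted_eigen
from ovifeed.io import MISSING


def _matrix(calls, multi=None, chrom=None, pos=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"a{i}" for i in range(n)],
        [f"s{j}" for j in range(m)],
        chrom if chrom is not None else ["1"] * m,
        pos if pos is not None else np.arange(1, m + 1) * 1000,
        ["A"] * m,
        ["G"] * m,
        calls,
        multi_allelic=multi,
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _brute_force_qc(calls, multi, snp_cr, ind_cr, maf_min):
    """Independent enumeration of the QC rules, small-n loops only."""
    n, m = calls.shape
    snps = [j for j in range(m) if not multi[j]]
    snps = [
        j
        for j in snps
        if sum(calls[i, j] != MISSING for i in range(n)) / n >= snp_cr
    ]
    animals = [
        i
        for i in range(n)
        if sum(calls[i, j] != MISSING for j in snps) / len(snps) >= ind_cr
    ]
    kept = []
    for j in snps:
        obs = [calls[i, j] for i in animals if calls[i, j] != MISSING]
        if not obs:
            continue
        f = sum(obs) / (2 * len(obs))
        if min(f, 1 - f) >= maf_min:
            kept.append(j)
    return animals, kept


def toy_qc_panel():
    """10 SNPs × 10 animals exercising every QC rule exactly once.

    s0/s1 are multi-allelic; s2 is missing in two animals (call rate 0.8);
    animal a9 misses s3–s5, i.e. 3 of the 7 SNPs that survive the SNP filters
    (call rate 4/7); s3 is monomorphic once a9 is gone (MAF 0); s4–s9 stay.
    """
    X = MISSING
    calls = np.array(
        [
            # s0 s1 s2 s3 s4 s5 s6 s7 s8 s9
            [X, X, X, 0, 1, 1, 1, 1, 1, 1],
            [X, X, X, 0, 1, 1, 1, 1, 1, 1],
            [X, X, 1, 0, 1, 1, 1, 0, 2, 0],
            [X, X, 0, 0, 1, 0, 1, 0, 1, 0],
            [X, X, 1, 0, 0, 0, 1, 2, 0, 1],
            [X, X, 0, 0, 0, 0, 0, 1, 0, 1],
            [X, X, 1, 0, 0, 0, 0, 1, 0, 0],
            [X, X, 0, 0, 0, 0, 0, 0, 0, 0],
            [X, X, 1, 0, 0, 0, 0, 0, 0, 0],
            [X, X, 0, X, X, X, 2, 1, 1, 1],  # a9: poorly genotyped
        ],
        dtype=np.int8,
    )
    multi = np.zeros(10, dtype=bool)
    multi[[0, 1]] = True
    return calls, multi


def test_qc_matches_exhaustive_enumeration_on_toy_panel():
    calls, multi = toy_qc_panel()
    G = _matrix(calls, multi=multi)
    out, report = qc_filter(G, 0.90, 0.90, 0.05)
    animals, kept = _brute_force_qc(calls, multi, 0.90, 0.90, 0.05)
    assert [G.animal_ids[i] for i in animals] == out.animal_ids
    assert [G.snp_ids[j] for j in kept] == out.snp_ids
    assert report.n_removed_multi_allelic == 2
    assert report.n_removed_snp_call_rate == 1  # s2 at call rate 8/10
    assert report.n_individuals_removed == 1    # a9 at call rate 4/7
    assert report.n_removed_maf == 1            # s3 monomorphic once a9 is gone
    assert report.n_snps_kept == 6
    assert report.n_snps_in == report.n_snps_kept + 2 + 1 + 1
    assert report.n_individuals_in == report.n_individuals_kept + report.n_individuals_removed


def test_qc_boundaries_are_kept_not_removed():
    # SNP 0 and animal 0 sit at call rate exactly 0.9; SNP 1 at MAF exactly
    # 0.05; all are strict "less than" removals, so everything is kept
    calls = np.zeros((10, 10), dtype=np.int8)
    calls[1:5, 2:] = 1            # SNPs 2..9 at MAF 4/20 = 0.2
    calls[0, 0] = MISSING         # SNP 0 and animal 0 both at call rate 9/10
    calls[1:3, 0] = 1             # SNP 0 at MAF 2/18 ~ 0.11
    calls[1, 1] = 1               # SNP 1 at MAF 1/20 = 0.05 exactly
    G = _matrix(calls)
    out, report = qc_filter(G)
    assert out.n_snps == 10 and report.n_individuals_removed == 0


def test_qc_clean_panel_removes_nothing():
    G = simulate_genotypes(40, 100, 5, maf_range=(0.2, 0.5), seed=21)
    out, report = qc_filter(G)
    assert out.n_snps == 100 and report.n_individuals_removed == 0
    assert report.n_removed_maf == report.n_removed_snp_call_rate == 0


def test_qc_empty_panel_raises():
    calls = np.full((4, 3), MISSING, dtype=np.int8)
    with pytest.raises(EmptyPanelError):
        qc_filter(_matrix(calls))


# ---------------------------------------------------------------------------
# dosage and GRM
# ---------------------------------------------------------------------------

def test_dosage_coding_and_mean_imputation():
    calls = np.array([[0], [1], [2]], dtype=np.int8)
    np.testing.assert_array_equal(allele_dosage(_matrix(calls)).ravel(), [0.0, 1.0, 2.0])
    calls = np.array([[0], [2], [MISSING]], dtype=np.int8)
    dose = allele_dosage(_matrix(calls))
    assert dose[2, 0] == pytest.approx(1.0)
    # imputation preserves the observed allele frequency
    assert dose[:, 0].mean() / 2.0 == pytest.approx(0.5)


def test_grm_duplicate_animals_share_relationship():
    calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=np.int8)
    K = compute_grm(allele_dosage(_matrix(calls))).matrix
    assert K[0, 1] == pytest.approx(K[0, 0])
    assert K[0, 1] == pytest.approx(K[1, 1])


def test_grm_mean_diagonal_near_one_on_unstructured_panel():
    G = simulate_genotypes(200, 5000, 26, fst=0.0, seed=22)
    K = compute_grm(allele_dosage(G)).matrix
    assert abs(np.diag(K).mean() - 1.0) < 0.05
    # Gram-matrix property: positive semi-definite up to round-off
    w = np.linalg.eigvalsh(K)
    assert w.min() > -1e-8 * w.max()
    assert np.allclose(K, K.T)


# ---------------------------------------------------------------------------
# null model REML
# ---------------------------------------------------------------------------

def _structured_K(n, seed):
    G = simulate_genotypes(n, 800, 10, fst=0.15, seed=seed)
    return compute_grm(allele_dosage(G)).matrix


def test_identity_kinship_scan_reduces_to_ols(rng):
    n, m = 50, 30
    dose = rng.integers(0, 3, size=(n, m)).astype(float)
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    vc = fit_null(y, X, np.eye(n))
    # total variance matches the OLS residual variance
    assert vc.sigma2_g + vc.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=1e-6)
    res = snp_scan(y, X, np.eye(n), dose, vc)
    for j in range(m):
        W = np.column_stack([np.ones(n), dose[:, j]])
        ols = np.linalg.lstsq(W, y, rcond=None)[0]
        r = y - W @ ols
        s2 = (r @ r) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(W.T @ W)[1, 1])
        p = 2 * sps.t.sf(abs(ols[1] / se), n - 2)
        assert res.p[j] == pytest.approx(p, abs=1e-10)


def test_spectral_reml_equals_dense_restricted_likelihood(rng):
    """The eigen-shortcut REML log-likelihood agrees with a direct dense-matrix
    evaluation of the restricted likelihood at arbitrary variance ratios."""
    n = 40
    K = _structured_K(n, seed=23)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    lam, U = _restricted_eigen(K, X)
    eta = U.T @ y
    q = X.shape[1]
    for delta in np.exp(rng.uniform(-4, 4, size=10)):
        H = K + delta * np.eye(n)
        Hi = np.linalg.inv(H)
        XHX = X.T @ Hi @ X
        P = Hi - Hi @ X @ np.linalg.inv(XHX) @ X.T @ Hi
        quad = float(y @ P @ y)
        nq = n - q
        dense = 0.5 * (
            nq * (np.log(nq / (2 * np.pi)) - 1 - np.log(quad))
            - (np.linalg.slogdet(H)[1] + np.linalg.slogdet(XHX)[1] - np.linalg.slogdet(X.T @ X)[1])
        )
        assert reml_loglik(delta, lam, eta) == pytest.approx(dense, abs=1e-8)


def test_reml_variance_component_recovery():
    n = 300
    K = _structured_K(n, seed=24)
    vals, vecs = np.linalg.eigh(K)
    Ks = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    X = np.ones((n, 1))
    rng = np.random.default_rng(25)
    est = []
    for _ in range(100):
        y = Ks @ rng.standard_normal(n) + rng.standard_normal(n)
        vc = fit_null(y, X, K)
        est.append((vc.sigma2_g, vc.sigma2_e))
    est = np.asarray(est)
    for k, truth in enumerate((1.0, 1.0)):
        mc_se = est[:, k].std(ddof=1) / 10
        assert abs(est[:, k].mean() - truth) < 3 * mc_se


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def test_scan_matches_dense_gls_oracle():
    n, m = 60, 100
    G = simulate_genotypes(n, m, 5, seed=26)
    dose = allele_dosage(G)
    K = compute_grm(dose).matrix
    rng = np.random.default_rng(27)
    vals, vecs = np.linalg.eigh(K)
    y = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T @ rng.standard_normal(n)
    y += rng.standard_normal(n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    vc = fit_null(y, X, K)
    res = snp_scan(y, X, K, dose, vc)
    V = vc.sigma2_g * K + vc.sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    for j in range(m):
        if dose[:, j].var() < 1e-12:  # monomorphic: no GLS fit exists
            assert res.degenerate[j] and res.p[j] == 1.0
            continue
        W = np.column_stack([X, dose[:, j]])
        A = np.linalg.inv(W.T @ Vi @ W)
        b = A @ W.T @ Vi @ y
        r = y - W @ b
        s2 = (r @ Vi @ r) / (n - W.shape[1])
        t = b[-1] / np.sqrt(s2 * A[-1, -1])
        p = 2 * sps.t.sf(abs(t), n - W.shape[1])
        assert -np.log10(res.p[j]) == pytest.approx(-np.log10(p), abs=1e-6)


def test_scan_type_one_error_is_calibrated():
    """Under a purely polygenic phenotype the EMMAX scan's empirical type-I
    error at alpha = 0.01 over 2,500 null SNPs lies within 3 binomial SE."""
    G = simulate_genotypes(120, 2500, 26, seed=5)
    dose = allele_dosage(G)
    K = compute_grm(dose).matrix
    vals, vecs = np.linalg.eigh(K)
    Ks = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    rng = np.random.default_rng(6)
    y = Ks @ rng.standard_normal(120) + rng.standard_normal(120)
    X = np.ones((120, 1))
    vc = fit_null(y, X, K)
    res = snp_scan(y, X, K, dose, vc)
    rate = float((res.p < 0.01).mean())
    assert abs(rate - 0.01) < 3 * np.sqrt(0.01 * 0.99 / 2500)


def test_causal_snp_ranks_high_in_power_simulation():
    n, m = 67, 5000
    G = simulate_genotypes(n, m, 26, seed=28)
    dose = allele_dosage(G)
    K = compute_grm(dose).matrix
    vals, vecs = np.linalg.eigh(K)
    Ks = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    X = np.ones((n, 1))
    rng = np.random.default_rng(29)
    hits = 0
    reps = 100
    for _ in range(reps):
        j = int(rng.integers(m))
        g = dose[:, j] - dose[:, j].mean()
        var_g = g.var()
        if var_g < 1e-3:
            continue
        beta = np.sqrt(0.25 / var_g)  # causal SNP explains ~25% of variance
        y = beta * g + np.sqrt(0.375) * (Ks @ rng.standard_normal(n)) + np.sqrt(0.375) * rng.standard_normal(n)
        vc = fit_null(y, X, K)
        res = snp_scan(y, X, K, dose, vc)
        rank = int((res.p < res.p[j]).sum())
        hits += rank < 10
    # at exactly 25% explained variance and n = 67 the top-10 detection
    # probability sits in the mid/high 80s; 75% is three binomial SE below
    assert hits >= 0.75 * reps


def test_scan_invariant_to_snp_and_animal_permutations(rng):
    n, m = 40, 50
    G = simulate_genotypes(n, m, 5, seed=30)
    dose = allele_dosage(G)
    K = compute_grm(dose).matrix
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    vc = fit_null(y, X, K)
    base = snp_scan(y, X, K, dose, vc)
    perm = rng.permutation(m)
    shuffled = snp_scan(y, X, K, dose[:, perm], vc)
    np.testing.assert_allclose(base.p.to_numpy()[perm], shuffled.p.to_numpy(), atol=1e-10)
    rowp = rng.permutation(n)
    vc2 = fit_null(y[rowp], X[rowp], K[np.ix_(rowp, rowp)])
    permuted = snp_scan(y[rowp], X[rowp], K[np.ix_(rowp, rowp)], dose[rowp], vc2)
    np.testing.assert_allclose(base.p.to_numpy(), permuted.p.to_numpy(), rtol=1e-6)


def test_degenerate_snp_flagged(rng):
    n = 30
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    dose = np.column_stack([np.full(n, 2.0), rng.integers(0, 3, n).astype(float)])
    vc = fit_null(y, X, np.eye(n))
    res = snp_scan(y, X, np.eye(n), dose, vc)
    assert bool(res.degenerate[0]) and res.p[0] == 1.0 and res.beta[0] == 0.0
    assert not res.degenerate[1]


# ---------------------------------------------------------------------------
# thresholds and Manhattan layout
# ---------------------------------------------------------------------------

def test_bonferroni_threshold_values():
    assert bonferroni_threshold(44855, 0.05) == pytest.approx(0.05 / 44855)
    assert bonferroni_threshold(1, 0.05) == 0.05
    assert bonferroni_threshold(20, 0.05) == pytest.approx(2.5e-3)


def test_manhattan_windows_and_ordering():
    res = pd.DataFrame(
        {
            "snp_id": ["a", "b", "c"],
            "chromosome": ["1", "2", "10"],
            "position_bp": [5_000_000, 68_812_505, 1_000],
            "p": [0.5, 1e-8, 0.2],
            "neg_log10_p": [0.3, 8.0, 0.7],
        }
    )
    table, hits = manhattan_table(res, threshold=1e-6)
    assert list(table["snp_id"]) == ["a", "b", "c"]  # numeric chromosome order 1, 2, 10
    assert np.all(np.diff(table["cum_pos"]) > 0)
    assert len(hits) == 1
    assert hits.loc[0, "window_start_bp"] == 67_812_505
    assert hits.loc[0, "window_end_bp"] == 69_812_505


def test_manhattan_empty_hit_list_keeps_full_table():
    res = pd.DataFrame(
        {
            "snp_id": ["a", "b"],
            "chromosome": ["1", "X"],
            "position_bp": [10, 20],
            "p": [0.5, 0.6],
            "neg_log10_p": [0.3, 0.2],
        }
    )
    table, hits = manhattan_table(res, threshold=1e-6)
    assert len(table) == 2 and hits.empty
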