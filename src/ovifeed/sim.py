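"""Synthetic flock generator: the ground truth behind every pipeline stage.

The generator emulates a two-period sheep feeding trial: a growth period
(lambs ~121 d old, gaining ~0.26 kg/d on a pelleted diet) and a maintenance
period (~355 d old, ~−0.02 kg/d on hay), with two moderately diverged breeds,
weekly weighing over a 42-day collection window, daily feed-disappearance
records, and SNP-chip genotypes on 26 autosomes.

Genotypes follow a Balding–Nichols model: each SNP has an ancestral frequency
drawn in ``maf_range`` and breed-specific frequencies drawn from a beta
distribution around it with divergence ``fst``; genotypes are two independent
allele draws.  The residual-feed-intake ground truth has a component shared
across periods — a polygenic part with covariance proportional to the GRM of
the simulated genotypes (exactly the structure the mixed-model scan assumes),
one causal SNP with an additive effect, and a permanent-environment part —
plus an independent period-specific deviation.  The shared variance is set
from the target repeatability: sigma2_shared = R · sd_RFI,1 · sd_RFI,2, so the
true between-period RFI correlation converges to R across replicate flocks.

Daily dry-matter intake is b0 + B1·MBW_true + B2·ADG_true + RFI_true + noise,
converted to as-fed by the diet dry-matter fraction.  The coefficients b0 and
B1 are solved at configuration time so that each period's expected DMI mean
and SD, and its intake-model residual SD, match the configured trial moments;
B2 is fixed.  Weighing noise (0.5 kg) and daily intake noise (0.15 kg DM) are
measurement-scale choices exposed in the config.

With the seed fixed the whole simulation is bit-reproducible, and attrition
(enrolled → period-1 → period-2 cohorts) is uniform at random, never
preferential with respect to genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gwas import allele_dosage, compute_grm
from .io import GenotypeMatrix, IntakeSeries, WeightSeries

_BASES = np.array(list("ACGT"))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def breed_assignment(n_animals: int, n_breeds: int) -> np.ndarray:
    """Deterministic contiguous-block breed labels for n animals."""
    idx = (np.arange(n_animals) * n_breeds) // n_animals
    if n_breeds == 2:
        names = np.array(["Targhee", "Rambouillet"], dtype=object)
    else:
        names = np.array([f"breed{k + 1}" for k in range(n_breeds)], dtype=object)
    return names[idx]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_animals: int,
    n_snps: int,
    n_chromosomes: int = 26,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_breeds: int = 2,
    fst: float = 0.1,
    seed=0,
) -> GenotypeMatrix:
    """Simulate a biallelic SNP panel with Balding–Nichols breed divergence.

    SNPs are assigned to chromosomes in (near-)equal blocks with sorted 1-based
    positions.  After generation, A1 is re-oriented to the minor allele by
    observed frequency (alphabetical tie-break), matching what loaders do.
    """
    if n_snps < n_chromosomes:
        raise ConfigurationError("need at least one SNP per chromosome")
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ConfigurationError("maf_range must lie within (0, 0.5]")
    if not 0 <= fst < 1:
        raise ConfigurationError("fst must lie in [0, 1)")
    rng = _as_rng(seed)

    ancestral = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    breeds = breed_assignment(n_animals, n_breeds)
    _, breed_codes = np.unique(breeds, return_inverse=True)
    if fst > 0:
        c = (1.0 - fst) / fst
        breed_freq = rng.beta(
            ancestral[None, :] * c, (1.0 - ancestral[None, :]) * c, size=(n_breeds, n_snps)
        )
    else:
        breed_freq = np.broadcast_to(ancestral, (n_breeds, n_snps)).copy()
    p = breed_freq[breed_codes]  # animals × SNPs
    calls = (rng.random((n_animals, n_snps)) < p).astype(np.int8)
    calls += (rng.random((n_animals, n_snps)) < p).astype(np.int8)

    # allele labels: two distinct bases per SNP
    first = rng.integers(0, 4, size=n_snps)
    second = (first + rng.integers(1, 4, size=n_snps)) % 4
    a1 = _BASES[first].astype(object)
    a2 = _BASES[second].astype(object)

    # orient A1 to the observed minor allele; alphabetical tie-break at 0.5
    freq = calls.mean(axis=0) / 2.0
    flip = (freq > 0.5) | ((freq == 0.5) & (a2 < a1))
    calls[:, flip] = 2 - calls[:, flip]
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()

    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    chrom = np.concatenate(
        [np.repeat(str(c + 1), k) for c, k in enumerate(per_chrom)]
    ).astype(object)
    position = np.concatenate(
        [np.sort(rng.choice(100_000_000, size=k, replace=False)) + 1 for k in per_chrom]
    )
    snp_ids = [f"snp_{c}_{p_}" for c, p_ in zip(chrom, position)]
    animal_ids = [f"ewe{i:03d}" for i in range(n_animals)]
    return GenotypeMatrix(animal_ids, snp_ids, chrom, position, a1, a2, calls)


# ---------------------------------------------------------------------------
# trial configuration
# ---------------------------------------------------------------------------

@dataclass
class PeriodSim:
    """Study conditions for one experimental period.

    Weight is parametrised by the initial (day-0) weight so that the implied
    mid-test body weight has the configured trial moments:
    MTBW mean = init + ADG·midpoint, MTBW var = init_sd² + midpoint²·ADG_sd².
    """

    name: str
    dm_fraction: float
    init_weight_mean: float      # kg at day 0
    init_weight_sd: float
    adg_mean: float              # kg/day
    adg_sd: float
    dmi_mean: float              # kg DM/day, cohort mean
    dmi_sd: float                # kg DM/day, cohort SD (total)
    rfi_sd: float                # kg DM/day, intake-model residual SD
    n_days: int = 42
    weigh_interval: int = 7
    b2: float = 0.8              # kg DM/day per kg/day of gain

    @property
    def midpoint(self) -> float:
        return self.n_days / 2.0

    @property
    def mtbw_mean(self) -> float:
        return self.init_weight_mean + self.adg_mean * self.midpoint

    @property
    def mtbw_sd(self) -> float:
        return math.sqrt(self.init_weight_sd**2 + (self.midpoint * self.adg_sd) ** 2)

    @property
    def mbw_mean(self) -> float:
        return self.mtbw_mean**0.75

    @property
    def mbw_sd(self) -> float:
        return 0.75 * self.mtbw_mean ** (-0.25) * self.mtbw_sd

    def intake_coefficients(self) -> tuple[float, float, float]:
        """Solve (b0, b1, b2) so expected DMI mean/SD and residual SD hit the
        configured moments (delta-method variance for the MBW term)."""
        explained = self.dmi_sd**2 - self.rfi_sd**2
        if explained < 0:
            raise ConfigurationError(
                f"period {self.name}: rfi_sd exceeds total dmi_sd (negative explained variance)"
            )
        cov_mbw_adg = 0.75 * self.mtbw_mean ** (-0.25) * self.midpoint * self.adg_sd**2
        aa = self.mbw_sd**2
        bb = 2.0 * self.b2 * cov_mbw_adg
        cc = self.b2**2 * self.adg_sd**2 - explained
        if aa <= 0:
            raise ConfigurationError(f"period {self.name}: zero weight variance")
        disc = bb**2 - 4 * aa * cc
        if disc < 0:
            raise ConfigurationError(f"period {self.name}: infeasible intake variance split")
        b1 = (-bb + math.sqrt(disc)) / (2 * aa)
        b0 = self.dmi_mean - b1 * self.mbw_mean - self.b2 * self.adg_mean
        return b0, b1, self.b2


def default_periods() -> tuple[PeriodSim, PeriodSim]:
    """Growth (pellet) and maintenance (hay) periods at the trial's moments."""
    growth = PeriodSim(
        name="period1", dm_fraction=0.906,
        init_weight_mean=22.34, init_weight_sd=3.594,
        adg_mean=0.26, adg_sd=0.12,
        dmi_mean=2.01, dmi_sd=0.38, rfi_sd=0.24,
    )
    maintenance = PeriodSim(
        name="period2", dm_fraction=0.897,
        init_weight_mean=43.32, init_weight_sd=6.254,
        adg_mean=-0.02, adg_sd=0.16,
        dmi_mean=2.02, dmi_sd=1.19, rfi_sd=0.97,
    )
    return growth, maintenance


@dataclass
class SimConfig:
    """Full flock-simulation configuration (defaults are the study conditions)."""

    n_enrolled: int = 81
    n_period1: int = 74
    n_period2: int = 70
    n_genotyped: int = 67
    n_snps: int = 5000
    n_chromosomes: int = 26
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_breeds: int = 2
    fst: float = 0.1
    periods: tuple[PeriodSim, PeriodSim] = field(default_factory=default_periods)
    target_repeatability: float = 0.157
    weight_corr_between_periods: float = 0.7
    weigh_noise_sd: float = 0.5        # kg
    intake_noise_sd: float = 0.15      # kg DM per day
    causal_effect: float = 0.1         # kg DM/day per A1 allele on shared RFI
    causal_maf_target: float = 0.3
    polygenic_fraction: float = 0.5    # of the shared variance left after the causal SNP
    ebv_weight_loading: float = 0.5    # corr driver between PWWT EBV and initial weight
    ebv_mean: float = 2.0              # kg
    ebv_sd: float = 1.5

    def variance_split(self, causal_var: float) -> tuple[float, float, float, tuple[float, float]]:
        """(sigma2_polygenic, sigma2_perm_env, sigma2_shared, per-period deviation vars)."""
        sd1, sd2 = (p.rfi_sd for p in self.periods)
        sigma2_shared = self.target_repeatability * sd1 * sd2
        dev = (sd1**2 - sigma2_shared, sd2**2 - sigma2_shared)
        if min(dev) < 0:
            raise ConfigurationError("target repeatability implies negative period-specific variance")
        remaining = sigma2_shared - causal_var
        if remaining < 0:
            raise ConfigurationError("causal-SNP variance exceeds the shared RFI variance")
        s2_poly = self.polygenic_fraction * remaining
        return s2_poly, remaining - s2_poly, sigma2_shared, dev


# ---------------------------------------------------------------------------
# flock simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth of one simulated flock."""

    per_animal: pd.DataFrame
    causal_snp_id: str
    causal_index: int
    causal_effect: float
    sigma2_shared: float
    sigma2_polygenic: float
    sigma2_perm_env: float
    sigma2_causal: float
    rfi_sd_by_period: dict[str, float]
    target_repeatability: float


@dataclass
class FlockData:
    """Everything one simulated trial produces."""

    genotypes: GenotypeMatrix
    weights: dict[str, dict[str, WeightSeries]]   # period -> animal -> series
    intakes: dict[str, dict[str, IntakeSeries]]
    covariates: pd.DataFrame
    truth: SimTruth


def _matrix_sqrt_psd(K: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(K)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def simulate_flock(G: GenotypeMatrix, config: SimConfig | None = None, seed=0) -> FlockData:
    """Simulate two-period weight/intake records and covariates on genotypes G."""
    config = config or SimConfig()
    rng = _as_rng(seed)
    n = G.n_animals
    ids = np.array(G.animal_ids, dtype=object)

    dosage = allele_dosage(G)
    freq = dosage.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    causal_index = int(np.argmin(np.abs(maf - config.causal_maf_target)))
    p_c = freq[causal_index]
    causal_var = 2.0 * p_c * (1 - p_c) * config.causal_effect**2
    s2_poly, s2_pe, s2_shared, dev_vars = config.variance_split(causal_var)

    grm = compute_grm(dosage, G.animal_ids)
    Ksqrt = _matrix_sqrt_psd(grm.matrix)
    polygenic = math.sqrt(s2_poly) * (Ksqrt @ rng.standard_normal(n))
    perm_env = rng.normal(0.0, math.sqrt(s2_pe), size=n)
    causal_component = config.causal_effect * (dosage[:, causal_index] - 2.0 * p_c)
    shared = polygenic + causal_component + perm_env

    # cohort attrition, uniformly at random
    in_p1 = np.zeros(n, dtype=bool)
    in_p1[rng.choice(n, size=min(config.n_period1, n), replace=False)] = True
    p1_idx = np.flatnonzero(in_p1)
    in_p2 = np.zeros(n, dtype=bool)
    in_p2[rng.choice(p1_idx, size=min(config.n_period2, len(p1_idx)), replace=False)] = True
    genotyped = np.zeros(n, dtype=bool)
    genotyped[rng.choice(p1_idx, size=min(config.n_genotyped, len(p1_idx)), replace=False)] = True

    # correlated initial weights across periods; independent ADG draws
    z1 = rng.standard_normal(n)
    rho = config.weight_corr_between_periods
    z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    zw = {config.periods[0].name: z1, config.periods[1].name: z2}
    membership = {config.periods[0].name: in_p1, config.periods[1].name: in_p2}

    truth_cols: dict[str, np.ndarray] = {
        "animal_id": ids,
        "breed": breed_assignment(n, config.n_breeds),
        "in_period1": in_p1,
        "in_period2": in_p2,
        "genotyped": genotyped,
        "rfi_shared": shared,
        "causal_dosage": dosage[:, causal_index],
    }

    weights: dict[str, dict[str, WeightSeries]] = {}
    intakes: dict[str, dict[str, IntakeSeries]] = {}
    for k, period in enumerate(config.periods):
        member = membership[period.name]
        init_w = period.init_weight_mean + period.init_weight_sd * zw[period.name]
        adg = rng.normal(period.adg_mean, period.adg_sd, size=n)
        rfi = shared + rng.normal(0.0, math.sqrt(dev_vars[k]), size=n)
        rfi = rfi - rfi[member].mean()  # centred over the period cohort

        b0, b1, b2 = period.intake_coefficients()
        mbw_true = np.clip(init_w + adg * period.midpoint, 1e-6, None) ** 0.75
        expected = b0 + b1 * mbw_true + b2 * adg

        weigh_days = np.arange(0, period.n_days + 1, period.weigh_interval)
        intake_days = np.arange(0, period.n_days)
        wmap: dict[str, WeightSeries] = {}
        imap: dict[str, IntakeSeries] = {}
        for i in np.flatnonzero(member):
            w_obs = init_w[i] + adg[i] * weigh_days + rng.normal(
                0.0, config.weigh_noise_sd, size=len(weigh_days)
            )
            wmap[ids[i]] = WeightSeries(ids[i], weigh_days, np.clip(w_obs, 0.1, None))
            dmi_daily = expected[i] + rfi[i] + rng.normal(
                0.0, config.intake_noise_sd, size=len(intake_days)
            )
            as_fed = np.clip(dmi_daily / period.dm_fraction, 0.0, None)
            imap[ids[i]] = IntakeSeries(ids[i], intake_days, as_fed)
        weights[period.name] = wmap
        intakes[period.name] = imap

        suffix = str(k + 1)
        truth_cols[f"init_weight_period{suffix}"] = init_w
        truth_cols[f"adg_period{suffix}"] = adg
        truth_cols[f"rfi_period{suffix}"] = np.where(member, rfi, np.nan)

    ebv_c = config.ebv_weight_loading
    ebv = config.ebv_mean + config.ebv_sd * (
        ebv_c * z1 + math.sqrt(1 - ebv_c**2) * rng.standard_normal(n)
    )
    covariates = pd.DataFrame(
        {
            "animal_id": ids,
            "breed": truth_cols["breed"],
            "pwwt_ebv": ebv,
            "genotyped": genotyped,
        }
    )

    truth = SimTruth(
        per_animal=pd.DataFrame(truth_cols),
        causal_snp_id=G.snp_ids[causal_index],
        causal_index=causal_index,
        causal_effect=config.causal_effect,
        sigma2_shared=s2_shared,
        sigma2_polygenic=s2_poly,
        sigma2_perm_env=s2_pe,
        sigma2_causal=causal_var,
        rfi_sd_by_period={p.name: p.rfi_sd for p in config.periods},
        target_repeatability=config.target_repeatability,
    )
    return FlockData(G, weights, intakes, covariates, truth)


# ---------------------------------------------------------------------------
# direct intake cohorts (trait-level simulation)
# ---------------------------------------------------------------------------

def simulate_intake_cohort(
    period: PeriodSim, n: int, seed=0, sample_calibrated: bool = True
) -> pd.DataFrame:
    """Simulate one cohort of (mbw, adg, dmi) directly at the trait level.

    MBW and ADG are independent normals at the period's moments and DMI is
    generated from the expected-intake regression plus a normal residual.
    With ``sample_calibrated`` (default) the population residual SD is
    inflated by sqrt((n−1)/(n−3)) so the *expected sample* residual SD of the
    fitted intake model equals the period's configured residual SD, and the
    explained variance is set so the expected sample DMI SD equals the
    configured total — i.e. the simulated cohorts look like the trial cohort
    as measured, not like its hypothetical population.
    """
    if n < 5:
        raise ConfigurationError("cohort simulation needs n >= 5")
    rng = _as_rng(seed)
    resid_sd = period.rfi_sd * (math.sqrt((n - 1) / (n - 3)) if sample_calibrated else 1.0)
    explained = period.dmi_sd**2 - resid_sd**2
    if explained < 0:
        raise ConfigurationError("residual SD exceeds total DMI SD")
    b2 = period.b2
    b1 = math.sqrt(max(explained - b2**2 * period.adg_sd**2, 0.0)) / period.mbw_sd
    b0 = period.dmi_mean - b1 * period.mbw_mean - b2 * period.adg_mean

    mbw = rng.normal(period.mbw_mean, period.mbw_sd, size=n)
    adg = rng.normal(period.adg_mean, period.adg_sd, size=n)
    dmi = b0 + b1 * mbw + b2 * adg + rng.normal(0.0, resid_sd, size=n)
    return pd.DataFrame(
        {
            "animal_id": [f"ewe{i:03d}" for i in range(n)],
            "mbw": mbw,
            "adg": adg,
            "dmi": dmi,
        }
    )


def default_sim_config() -> SimConfig:
    return SimConfig()


__all__ = [
    "PeriodSim",
    "SimConfig",
    "SimTruth",
    "FlockData",
    "breed_assignment",
    "default_periods",
    "default_sim_config",
    "simulate_genotypes",
    "simulate_flock",
    "simulate_intake_cohort",
]
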