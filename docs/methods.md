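# Methods

## Trait derivation

Average daily gain is the slope of an ordinary least-squares regression of
body weight (kg) on day within one experimental period; mid-test body weight
(MTBW) is that regression's prediction at the window midpoint, and metabolic
body weight is MBW = MTBW^0.75.  Using the fitted midpoint rather than the
raw mid-test weighing makes MTBW robust to single-day weighing error.

Daily as-fed intake is converted to dry matter by multiplying by the diet's
dry-matter fraction (0.906 for the pelleted growth diet, 0.897 for the hay
maintenance diet).  Each animal's DMI scalar is the fitted value at the
window midpoint of an OLS regression of daily DMI on day — the natural
analogue of MTBW.  When observation days are symmetric about the midpoint
this equals the arithmetic mean exactly; a `method="mean"` switch selects
the plain mean.  Days with no recorded feeding are treated as absent
observations, not zeros: the feeding system logs disappearance only when an
animal eats, so imputing zeros would bias DMI downward.  Animals with fewer
than two weight or two intake observations in a period are excluded from
that period with a logged reason.

## Residual feed intake

Within each period separately, expected intake is one multiple OLS
regression with intercept of DMI on MBW and ADG across the cohort; RFI is
the residual.  MBW is the size regressor (a `size_regressor="mtbw"` switch
exists for sensitivity analysis), and no breed or pen terms are included by
default — the cohorts are analysed pooled.  Two OLS identities double as
run-time checks and tests: the cohort mean RFI is 0 and
corr(DMI, RFI) = SD(RFI)/SD(DMI).

## Correlations, period comparison, repeatability

Correlations are Pearson on pairwise-complete observations with two-sided
t-based p-values, flagged at p < 0.05.  Period comparisons use Welch's
unequal-variance two-tailed t-test, because trait SDs differ up to four-fold
between growth and maintenance and a pooled test would be miscalibrated.

Repeatability is the intraclass correlation of a one-way random-intercept
model (animal as grouping factor) fitted by REML.  The residual variance is
profiled out analytically and the variance ratio optimised by bounded Brent
search on its logarithm; a boundary optimum returns R = 0 rather than an
error, and perfectly consistent animals return R = 1.  For balanced designs
with an interior optimum this coincides with the one-way ANOVA ICC, which an
independent mean-squares oracle verifies in the tests to 1e-6; on unbalanced
data the fit is cross-checked against a general mixed-model fitter.
Uncertainty comes from a parametric bootstrap (default 1,000 replicates):
responses are resimulated from the fitted variances on the observed design,
refitted, and summarised by the SD and a percentile 95% interval.
Repeatability is computed on raw RFI from both periods even though the
period variances differ strongly (≈0.24 vs ≈0.97 kg DM/d); pooling unequal
variances shrinks R, so a `standardize_within` option z-scores within period
first (default off, matching common practice).

## Genotype QC, GRM, mixed-model scan

Quality control applies, in this fixed order: multi-allelic SNPs, SNP call
rate, individual call rate (computed on the SNPs surviving the first two
steps), then minor allele frequency recomputed on the retained individuals —
the order matters because individual removal changes borderline MAFs.  All
removals are strict inequalities against the thresholds (defaults 0.90 call
rates, 0.05 MAF), so a SNP exactly at a threshold is kept.

Additive dosages count the minor (A1) allele; missing calls are imputed with
the SNP's mean observed dosage, which preserves the observed allele
frequency and lets one spectral transform serve every SNP.  The genomic
relationship matrix is VanRaden method 1, K = ZZ'/(2Σp_j(1−p_j)) with Z
centred by twice the observed frequencies; the construction is isolated
behind `compute_grm` and swappable.

The null model y = Xb + u + e with u ~ N(0, σ²_g K) is fitted by REML: one
eigendecomposition of K projected off the covariate space reduces the
restricted likelihood to a one-dimensional function of δ = σ²_e/σ²_g,
maximised on a log-spaced grid refined by Brent's method (the spectral
shortcut is verified against a direct dense-matrix evaluation of the
restricted likelihood).  A boundary optimum (δ → ∞) is returned as
σ²_g = 0, collapsing the scan to OLS.  Each SNP is then tested by GLS under
the fixed covariance (EMMAX approximation) with a Wald t-statistic on
n − rank([X | g]) degrees of freedom — the exact small-sample reference, not
a normal approximation, because trial cohorts are ~60–70 animals.  SNPs
collinear with the covariates are flagged degenerate with effect 0 and
p = 1.  Genome-wide significance is Bonferroni at α/m; the Manhattan table
lays chromosomes end to end (numeric order, non-numeric labels last) and
reports a ±1 Mb candidate-gene window around every significant SNP.

Known approximation: EMMAX holds the variance components at their null-model
values for every SNP test, which is slightly conservative for large-effect
SNPs compared with per-SNP refitting (GEMMA-style exact tests are out of
scope).  No genomic-control inflation adjustment is applied.

## The flock simulator

The generator's defaults are the study conditions of a two-period,
two-breed range-ewe trial: 81 ewes enrolled, 74 completing a 42-day growth
test (weekly weighing, daily intake), 70 continuing to a 42-day maintenance
test, 67 genotyped; 5,000 SNPs on 26 autosomes as a desk-scale panel.
Attrition is uniform at random.

Genotypes follow a Balding–Nichols model (ancestral frequencies uniform in
the MAF range, breed frequencies beta-distributed around them with
divergence F_ST = 0.1, genotypes two independent allele draws); SNPs sit in
equal chromosome blocks with sorted positions.  Weight is parametrised by
the day-0 intercept: initial weights (mean 22.34/43.32 kg, SD 3.594/6.254)
and ADG (0.26 ± 0.12, −0.02 ± 0.16 kg/d) are chosen so the implied MTBW
moments are 27.8 ± 4.39 and 42.9 ± 7.10 kg; initial weights correlate 0.7
between periods, ADG draws are independent.  Observed weights add N(0, 0.5²)
kg weighing noise; daily intakes add N(0, 0.15²) kg DM — measurement-scale
choices exposed in the config.

True daily intake is b0 + B1·MBW + B2·ADG + RFI + noise, converted to as-fed
by the diet DM fraction (floored at zero — a fidelity limit of the normal
model in the high-variance maintenance period, where the printed intake SD
of 1.19 against a mean of 2.02 implies a skewed real distribution).  With B2
fixed at 0.8 kg DM per kg/d of gain, b0 and B1 are solved per period so that
the expected DMI mean and SD and the intake-model residual SD equal the
configured trial moments (2.01 ± 0.38 with residual 0.24 in growth;
2.02 ± 1.19 with residual 0.97 at maintenance), giving
(b0, B1) ≈ (−0.135, 0.16) and (−2.99, 0.30).

The RFI ground truth splits into a shared and a period-specific part.  The
shared variance is σ²_s = R·σ₁·σ₂ with R the target repeatability (0.157),
so the true between-period RFI correlation converges to R; the shared part
itself is the sum of a polygenic draw K^{1/2}z scaled to half the remaining
variance (tying the phenotype's null structure to exactly the GRM the scan
assumes; the symmetric square root clips negative eigenvalues at 0), a
causal-SNP term a·(dosage − 2p) with a = 0.1 kg DM/d per allele at the SNP
nearest MAF 0.3 (a deliberately subtle effect, ~11% of the shared variance),
and a permanent-environment residual.  Period RFIs are centred to mean zero
over each period's cohort.  The PWWT EBV covariate is a linear function of
the true initial weight plus noise (loading 0.5, giving corr(MTBW, EBV) ≈
0.4) — it mirrors the phenotypic structure of an external breeding value
without modelling a genetic evaluation.

What the simulator does not emulate: linkage disequilibrium beyond breed
structure, pen/bunk effects, behavioural adaptation failure, selection, or
non-normal intake distributions.  Passing tests therefore demonstrate the
correctness of the estimators under the assumed model, not robustness to
those features of real trial data.

A separate trait-level helper, `simulate_intake_cohort`, generates (MBW,
ADG, DMI) cohorts directly for studying the intake model in isolation.  It
calibrates to *sample* statistics: the population residual SD is inflated by
sqrt((n−1)/(n−3)) and the explained variance set so the expected sample
residual and total DMI SDs equal the configured values — simulated cohorts
resemble a real cohort as measured, and the expected corr(DMI, RFI) is the
plain ratio of the configured SDs.

## Numerical choices

- Minor-allele orientation is recomputed from observed frequencies at load
  time for PLINK text input (alphabetical tie-break at frequency 0.5);
  binary input trusts its own A1/A2 columns so round trips are lossless.
- Weight/intake CSVs are written with `%.17g` and parsed with round-trip
  float precision, making write-then-read bit exact.
- Intake-model designs with condition number above 1e10 raise a singular-fit
  error; REML optimisations use bounded Brent with tolerances of 1e-10 to
  1e-12 on the log variance ratio.
- p-values are clipped into (0, 1] at the smallest subnormal double.

## Problem sizes in tests

The test-suite simulations are sized for a desk run: flock replicates use
60-SNP panels, the calibration check 120 animals × 2,500 SNPs, the power
check 67 × 5,000, variance-component recovery 300 animals × 100 replicates,
and repeatability recovery 100 replicates of 70 × 2 — large enough that
every Monte-Carlo comparison carries its own standard-error bound, small
enough that the whole suite runs in well under a minute.
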