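# ovifeed

Feed-efficiency phenotypes, trait statistics and mixed-model GWAS for sheep
feeding trials.

Feed is the dominant cost of range-sheep production, and selection on
post-weaning weight EBVs has raised concern that producers are indirectly
selecting less feed-efficient animals.  The standard way to ask that question
is a feeding trial: record every ewe's daily feed disappearance and weekly
body weight over a test window, derive **residual feed intake (RFI)** — how
much an animal eats beyond what its size and growth predict — and relate RFI
to weights, breeding values and genotypes.  `ovifeed` implements that
analysis end to end for a two-period design (a growth phase on a pelleted
diet and a maintenance phase on hay), for geneticists and graduate students
who want a transparent, fully tested alternative to ad-hoc trial scripts.

## The model

Per animal and period, from the raw records:

- **ADG** (kg/d): slope of the OLS regression of body weight on day;
- **MTBW** (kg): the same regression evaluated at the test midpoint;
- **MBW** = MTBW^0.75 (kg^0.75): allometric scaling of maintenance demand;
- **DMI** (kg DM/d): as-fed intake × the diet's dry-matter fraction,
  summarised as the fitted value at the test midpoint of DMI-on-day.

Across the cohort of one period, expected intake is the Koch-style regression

```
DMI_i = b0 + B1·MBW_i + B2·ADG_i + e_i ,          RFI_i = e_i
```

so the cohort mean RFI is 0 and RFI is uncorrelated with size and growth by
construction.  Between-period **repeatability** is the intraclass correlation
R = σ²_animal / (σ²_animal + σ²_residual) from a one-way random-intercept
model fitted by REML, with a parametric bootstrap for its SE and CI.

The association scan is the single-marker linear mixed model

```
y = X b + g a_j + u + e ,   u ~ N(0, σ²_g K) ,   e ~ N(0, σ²_e I)
```

with K the VanRaden method-1 genomic relationship matrix.  Variance
components are estimated once under the null by spectral-decomposition REML
and every SNP is then tested by generalised least squares with the covariance
fixed (the EMMAX approximation), using exact t reference distributions —
cohorts here are a few dozen animals — and Bonferroni control.

A synthetic flock generator (`ovifeed.sim`) reproduces the statistical
structure of such a trial — two breeds with Balding–Nichols divergence, a
polygenic RFI component with covariance proportional to the GRM, one causal
SNP, permanent-environment effects, and configurable between-period
repeatability — so every stage of the pipeline can be validated against
known ground truth.

## Worked example

`examples/` contains one narrative script per capability.  Deriving
phenotypes and RFI from a simulated trial (`examples/03_residual_feed_intake.py`):

```
period1: DMI = 0.136 + 0.134·MBW + 0.947·ADG  (R² 0.63, n 74)
  RFI -0.00 ± 0.21 kg DM/d   best ewe ewe019 (-0.43), worst ewe055 (+0.50)
period2: DMI = -3.312 + 0.322·MBW + 0.901·ADG  (R² 0.40, n 70)
  RFI -0.00 ± 0.92 kg DM/d   best ewe ewe017 (-2.14), worst ewe053 (+1.97)
```

The intercept and coefficients are the fitted expected-intake model per
period; RFI means are zero by construction and the SDs (≈0.2 kg DM/d while
growing, ≈0.9 at maintenance) are the selectable variation in efficiency.
The mixed-model scan (`examples/05_gwas_scan.py`) on a flock carrying one
strong planted variant prints:

```
QC: kept 2780/3000 SNPs and 64 ewes
null model: sigma2_g = 0.028, sigma2_e = 1.080 (delta = 38.14)
Bonferroni threshold 1.80e-05; 1 SNP(s) genome-wide significant
  snp_1_92660347  chr1:92660347  beta +0.833  -log10 p 6.34 <- simulated causal SNP
```

i.e. after quality control the scan recovers exactly the simulated causal
SNP past the Bonferroni line, and reports the ±1 Mb candidate-gene window
around it.

The same stages are available as a thin command-line pipeline:

```
ovifeed simulate   --out-dir data --seed 3
ovifeed phenotypes --data-dir data --out-dir out
ovifeed rfi        --pheno-dir out --out-dir out
ovifeed stats      --rfi-dir out --out-dir out
ovifeed gwas       --data-dir data --rfi-dir out --out-dir out --trait rfi --period period2
ovifeed report     --gwas-file out/gwas_rfi_period2.tsv --out-dir out
```

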