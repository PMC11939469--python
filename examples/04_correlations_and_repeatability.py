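"""Trait correlations within and between periods, and RFI repeatability.

Repeatability is the intraclass correlation from a one-way random-intercept
model on the two RFI measurements per ewe, with a parametric bootstrap for
its uncertainty.  A low value means RFI measured during growth and RFI
measured at maintenance are largely different traits.
"""

import pandas as pd

from ovifeed import (
    between_period_correlations,
    compare_periods,
    compute_rfi,
    correlation_matrix,
    derive_phenotypes,
    fit_intake_model,
    repeatability,
    simulate_flock,
    simulate_genotypes,
)
from ovifeed.sim import SimConfig

cfg = SimConfig(n_snps=500)
G = simulate_genotypes(cfg.n_enrolled, cfg.n_snps, cfg.n_chromosomes, seed=1)
flock = simulate_flock(G, cfg, seed=2)

phenos = {}
for period in cfg.periods:
    pheno = derive_phenotypes(
        flock.weights[period.name], flock.intakes[period.name],
        start_day=0, end_day=period.n_days, dm_fraction=period.dm_fraction,
        covariates=flock.covariates,
    )
    phenos[period.name] = compute_rfi(pheno, fit_intake_model(pheno, period.name))

traits = ["mtbw", "mbw", "adg", "dmi", "rfi"]
r, p, sig = correlation_matrix(phenos["period1"], traits + ["pwwt_ebv"])
print("growth-period correlations (* = p < 0.05):")
for a in ("dmi", "rfi"):
    for b in ("mtbw", "pwwt_ebv"):
        star = "*" if sig.loc[a, b] else " "
        print(f"  corr({a.upper()}, {b.upper()}) = {r.loc[a, b]:+.3f}{star}")

t, pv = compare_periods(phenos["period1"]["mtbw"], phenos["period2"]["mtbw"])
print(f"MTBW growth vs maintenance: Welch t = {t:.1f}, p = {pv:.2g}")

between = between_period_correlations(phenos["period1"], phenos["period2"], traits)
print("between-period correlations:")
print(between[["trait", "r", "p"]].to_string(index=False, float_format=lambda x: f"{x:.3f}"))

long = pd.concat(
    [ph[["animal_id", "rfi"]].assign(period=k) for k, ph in phenos.items()]
).rename(columns={"rfi": "value"})
est = repeatability(long, n_boot=1000, seed=3)
print(f"RFI repeatability R = {est.r:.3f} ± {est.se:.3f} "
      f"(95% CI {est.ci[0]:.3f}–{est.ci[1]:.3f}, {est.n_animals} ewes)")
# Body weight carries over strongly between periods; RFI only weakly — the
# efficiency ranking of a growing lamb says little about her as a yearling.
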