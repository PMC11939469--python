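"""Fit the expected-intake model and compute residual feed intake.

Expected intake is DMI regressed on metabolic weight and gain with an
intercept; RFI is the residual.  A negative RFI ewe eats less than her size
and growth predict — she is the efficient one.
"""

from ovifeed import compute_rfi, derive_phenotypes, fit_intake_model, simulate_flock, simulate_genotypes
from ovifeed.sim import SimConfig

cfg = SimConfig(n_snps=500)
G = simulate_genotypes(cfg.n_enrolled, cfg.n_snps, cfg.n_chromosomes, seed=1)
flock = simulate_flock(G, cfg, seed=2)

for period in cfg.periods:
    pheno = derive_phenotypes(
        flock.weights[period.name], flock.intakes[period.name],
        start_day=0, end_day=period.n_days, dm_fraction=period.dm_fraction,
    )
    model = fit_intake_model(pheno, period.name)
    pheno = compute_rfi(pheno, model)
    print(f"{period.name}: DMI = {model.intercept:.3f} + {model.b1:.3f}·MBW "
          f"+ {model.b2:.3f}·ADG  (R² {model.r_squared:.2f}, n {model.n})")
    print(f"  RFI {pheno.rfi.mean():+.2f} ± {pheno.rfi.std(ddof=1):.2f} kg DM/d   "
          f"best ewe {pheno.loc[pheno.rfi.idxmin(), 'animal_id']} "
          f"({pheno.rfi.min():+.2f}), worst {pheno.loc[pheno.rfi.idxmax(), 'animal_id']} "
          f"({pheno.rfi.max():+.2f})")
# The cohort mean RFI is 0.00 by construction (it is an OLS residual); the
# spread — ~0.24 kg DM/d in growth, ~0.97 in maintenance — is what a breeder
# could select on.
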