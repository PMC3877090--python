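"""Generate a synthetic case-control cohort under the liability-threshold model.

Cases have latent liability l = w'beta + x'g + e above 0; the generator
rejection-samples until the case/control quotas are filled, so the output is a
case-control sample, not a population cohort.
"""

import numpy as np

from inflamsig import SimConfig, simulate_cohort

cfg = SimConfig(n_cases=500, n_controls=500, p_snps=200, n_causal=5,
                effect_size=0.35, ld_block_size=4, ld_rho=0.5,
                missing_rate=0.02, seed=7)
G, C, truth = simulate_cohort(cfg)

print(f"cohort: {G.n} individuals x {G.p} SNPs "
      f"({(C.labels == 1).sum()} cases / {(C.labels == 0).sum()} controls)")
print(f"missing calls: {100 * (G.codes == -1).mean():.2f}%  "
      f"(MCAR at rate {cfg.missing_rate})")
print(f"causal SNPs (liability effect +-{cfg.effect_size} per allele copy):")
for j, g in zip(truth.causal_indices, truth.g_true):
    print(f"  {G.snps.rs.iloc[j]:>10}  g = {g:+.2f}  MAF = {G.maf()[j]:.2f}")
print("smoking prevalence, cases vs controls:",
      f"{(C.data[C.data.label == 1].smoking != 'never').mean():.2f} vs",
      f"{(C.data[C.data.label == 0].smoking != 'never').mean():.2f}")
print("\nCases over-represent smokers and risk alleles because both raise the")
print("liability; every marginal genotype distribution is Hardy-Weinberg.")
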