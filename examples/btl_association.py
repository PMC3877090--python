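"""Fit the Bayesian Threshold LASSO and read off the multi-SNP signature.

The sampler augments the binary outcome with latent liabilities, applies
double-exponential shrinkage to every SNP coefficient jointly, and selects
SNPs whose posterior probability of a non-zero (one-sided) effect exceeds 0.8.
Odds ratios are mapped to the observed scale with the normal-CDF (threshold
model) transformation.
"""

from inflamsig import (BTLConfig, SimConfig, btl_snp_table, gibbs_sample,
                       select_snps, signature_or, simulate_cohort)

cfg = SimConfig(n_cases=500, n_controls=500, p_snps=150, n_causal=5,
                effect_size=0.35, ld_rho=0.0, missing_rate=0.0, seed=21)
G, C, truth = simulate_cohort(cfg)
post = gibbs_sample(G, C, BTLConfig(n_iter=10000, burn_in=2000, seed=1))

sel = select_snps(post, cutoff=0.8)
table = btl_snp_table(post, G).set_index("rs")
true_rs = {G.snps.rs.iloc[j] for j in truth.causal_indices}

print(f"{len(sel)} SNPs selected at Pr > 0.8 (true causal: {len(true_rs)})")
for _, row in sel.iterrows():
    t = table.loc[row.rs]
    tag = "causal" if row.rs in true_rs else "false positive"
    print(f"  {row.rs:>10}  Pr = {row.post_prob:.3f}  "
          f"OR_aa/AA = {t.or_mean:.2f} [{t.or_q025:.2f}, {t.or_q975:.2f}]  ({tag})")

sig = signature_or(post, sel).summary().iloc[0]
print(f"\nsignature OR (most-risky vs most-protective genotype combination):")
print(f"  median {sig['median']:.1f}, 95% interval "
      f"[{sig['q025']:.1f}, {sig['q975']:.1f}], Pr(OR > 1) = {sig['prob_gt_1']:.2f}")
print("\nPer-SNP ORs are modest; the joint signature OR is much larger because")
print("it stacks every selected effect in opposite directions.")
print("\nGeweke convergence z-scores:")
print(post.geweke().to_string(index=False))
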