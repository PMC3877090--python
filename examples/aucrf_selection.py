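"""AUC-guided random-forest backward elimination.

A full-model forest fixes the Gini-importance ranking; 20% of the worst-ranked
variables are dropped per step and each subset is scored by out-of-bag AUC.
The optimal subset maximizes OOB AUC (ties favour the smaller subset).
"""

from inflamsig import (AUCRFConfig, SimConfig, backward_eliminate, feature_table,
                       simulate_cohort)

cfg = SimConfig(n_cases=400, n_controls=400, p_snps=100, n_causal=5,
                effect_size=0.4, maf_range=(0.2, 0.4), missing_rate=0.0, seed=3)
G, C, truth = simulate_cohort(cfg)
X = feature_table(G, C)  # SNPs + gender, smoking, region, age in 3 groups

res = backward_eliminate(X, C.labels, AUCRFConfig(ntree=500, drop_fraction=0.2,
                                                  k_min=10, seed=3))
print("elimination path (size -> OOB AUC):")
for _, row in res.path.iterrows():
    marker = " <- optimal" if set(row.variables) == set(res.optimal_subset) else ""
    print(f"  {row['size']:>4}  {row.oob_auc:.3f}{marker}")

causal_rs = {G.snps.rs.iloc[j] for j in truth.causal_indices}
print(f"\noptimal subset: {len(res.optimal_subset)} variables, "
      f"{len(causal_rs & set(res.optimal_subset))}/5 causal SNPs included")
print("\ntop of the fixed initial ranking (relative importance = MDG/max MDG):")
print(res.importances.head(8).to_string(index=False))
print("\nSmoking and the causal SNPs dominate; noise SNPs drop out early.")
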