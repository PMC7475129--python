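"""Compositional analysis of a simulated caecal metagenome count table.

Simulates a two-group Dirichlet-multinomial count table with two planted
4-fold enrichments, runs the full compositional chain (filter -> CLR ->
diversity -> PCA -> PERMANOVA -> differential abundance) and aggregates a
toy KO table into a functional module.
"""

import numpy as np
import pandas as pd

import cihpheno as cp

spec = cp.CountSimSpec(
    n_taxa=80,
    n_samples_per_group=12,
    groups=("VEH", "PREB"),
    planted_effects=((5, "PREB", 2.0), (9, "PREB", 2.0)),  # 4-fold up on prebiotic
    seed=5,
)
table, truth = cp.simulate_count_table(spec)

filtered, da_mask = cp.filter_features(table)
clr = cp.clr_transform(filtered)
div = cp.alpha_diversity(table)
scores, _, evr = cp.pca_clr(clr)
perm = cp.permanova(clr, table.groups, n_perm=999, seed=1)
da = cp.differential_abundance(clr, table.groups, da_mask=da_mask, fdr=0.10)

print(f"features kept after 5% prevalence filter: {filtered.n_features}/{table.n_features}")
print(f"Shannon (mean over samples): {div['shannon'].mean():.2f} nats; "
      f"Simpson {div['simpson'].mean():.3f}; Chao1 {div['chao1'].mean():.1f}")
print(f"PCA explained variance: PC1 {100 * evr[0]:.0f}%, PC2 {100 * evr[1]:.0f}%")
row = perm.iloc[0]
print(f"PERMANOVA {row.comparison}: pseudo-F {row.pseudo_F:.2f}, p = {row.p:.3f}")
hits = da[da.reject]
print(f"differentially abundant at q<0.10: {list(hits.index)}")
print(f"planted truth: {list(truth.feature)}")

# --- KO -> module aggregation ----------------------------------------------
defs = [cp.ModuleDefinition("MGB001", "GABA synthesis demo",
                            (frozenset({"K01580"}), frozenset({"K00823", "K07250"})))]
kos = pd.DataFrame({"s1": [30, 4, 6], "s2": [0, 0, 1]},
                   index=["K01580", "K00823", "K07250"])
abund, cover = cp.aggregate_modules(kos, defs)
print(f"module abundance per sample: {abund.loc['MGB001'].tolist()}, "
      f"coverage {cover.loc['MGB001'].tolist()}")
print()
print("The differential test should recover the two planted taxa (and only")
print("those).  PERMANOVA stays non-significant here: a shift in 2 of 80 taxa")
print("barely moves whole-community Aitchison distances - feature-level and")
print("community-level tests answer different questions.")
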