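"""Gene ages, TRG flags and compartment enrichment.

Simulates a homology hit table over an 8-rank taxonomy ladder, assigns
each gene the rank of its oldest qualifying hit (e-value <= 1e-5), flags
taxonomically restricted genes, then demonstrates the compartment
statistics: SDR windows simulated with higher repeat density than
autosomes are detected by the seeded permutation test with BH correction.
"""

import numpy as np
import pandas as pd

from uvsdr import phylostrat, simulate, stats

hits, true_ages, ladder = simulate.simulate_homology_table(
    n_genes=300, n_strata=8, stratum_proportions=None, seed=41)
ages = phylostrat.assign_gene_ages(hits, ladder)
ages = phylostrat.flag_trg(ages, cutoff_rank=7, n_strata=8)
exact = all(true_ages[r.gene] == r.age_rank for r in ages.itertuples())
print(f"{len(ages)} genes aged over {ladder.n_strata} strata; "
      f"truth recovered exactly: {exact}")
print(ages["age_rank"].value_counts().sort_index().rename("n_genes")
      .to_string())
print(f"TRGs at cutoff rank 7: {int(ages['trg'].sum())}")

# compartment contrast: young (high-rank) ages enriched in the SDR
rng = np.random.default_rng(42)
comp = np.array(["SDR"] * 60 + ["PAR"] * 60 + ["autosome"] * 180)
rank = np.concatenate([
    rng.choice([6, 7, 8], size=60),            # SDR: young genes
    rng.choice(np.arange(1, 9), size=240),     # PAR + autosomes: uniform
])
out = stats.compartment_permutation_tests(
    pd.Series(rank.astype(float)), pd.Series(comp),
    stats.EnrichmentConfig(n_perm=10_000, seed=1))
print("\npairwise permutation tests on mean gene-age rank "
      "(10,000 permutations, BH-corrected):")
print(out.to_string(index=False))
print("\nThe SDR-vs-other contrasts reject: its genes are statistically "
      "younger, the taxonomically-restricted-gene enrichment signature.")
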