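"""Downstream statistics on a simulated ocular-surface microbiome.

Aggregates species to phylum level, lumps taxa below 1% mean abundance into
an "Under 1%" bin, compares Shannon diversity between groups, tests group
separation by PERMANOVA on scaled abundances, and tests the marker species'
presence/absence association by Fisher's exact test.
"""

from tearomics import (
    MicrobiomeSimConfig,
    aggregate_level,
    community_comparison,
    diversity_compare,
    lump_rare,
    presence_absence_test,
    simulate_microbiome,
)

table, ann, _ = simulate_microbiome(MicrobiomeSimConfig(seed=1))

phyla = aggregate_level(table.to_percent(), "phylum")
print("mean phylum abundances (%):")
print(phyla.abundances.mean(axis=1).round(2).sort_values(ascending=False).to_string())

lumped = lump_rare(table.to_percent(), ann)
print(f"\nafter 1% lumping: {lumped.abundances.shape[0]} taxa retained "
      f"(rare taxa pooled into 'Under 1%', mean "
      f"{lumped.abundances.loc['Under 1%'].mean():.2f}%)")

div = diversity_compare(table, ann)
print(f"\nShannon diversity: patients {div.group_summaries['patient']['mean_shannon']:.3f} "
      f"vs controls {div.group_summaries['control']['mean_shannon']:.3f}, "
      f"Welch p = {div.p_value:.3f}")

_, perma = community_comparison(table, ann, n_perm=1000, seed=1)
print(f"PERMANOVA (Euclidean on scaled abundances, 1000 permutations): "
      f"pseudo-F = {perma.pseudo_F:.3f}, p = {perma.p_value:.4f}")

assoc = presence_absence_test(table, ann, "Corynebacterium_mastitidis")
gs = assoc.group_summaries
print(f"marker species positives: patients {gs['patient']['positive']}/16, "
      f"controls {gs['control']['positive']}/16 -> Fisher p = {assoc.p_value:.4f}")
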