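"""Run the full differential-expression pipeline on a simulated cohort.

Filters the protein-group table, imputes left-censored missing values by
downshifted Gaussians over 20 cycles, applies the moderated t test with BH
adjustment and the fold-change-dependent significance curve, and flags
proteins that stay significant in every imputation cycle.
"""

from tearomics import ProteomeSimConfig, run_proteome_pipeline, simulate_proteome

table, ann, truth = simulate_proteome(ProteomeSimConfig(seed=1))
de, report = run_proteome_pipeline(table, ann)

f = report["filter"]
print(f"filtering: {f['input']} -> {f['surviving']} proteins "
      f"(-{f['removed_min_peptides']} <2 peptides, -{f['removed_contaminant']} "
      f"contaminants, -{f['removed_group_ids']} group IDs, "
      f"-{f['removed_sex_ids']} sex IDs)")
print(f"variance prior: d0 = {de.d0_hat:.2f}, s0^2 = {de.s0sq_hat:.3f} "
      "(per-protein variances shrink toward s0^2 with d0 extra df)")
print(f"significant (cycle 1): {de.n_significant}; "
      f"stable across all 20 imputation cycles: {de.n_stable}")

truth_tested = truth.is_differential.loc[de.table.index]
stable = de.table["stable"]
fp = int((stable & ~truth_tested).sum())
print(f"of the stable calls, {fp} are false positives "
      f"(empirical FDR {100 * fp / max(de.n_stable, 1):.1f}%)")

top = de.table[stable].reindex(
    de.table[stable]["p_adj"].sort_values().index).head(5)
print("\nstrongest stable proteins (log2FC = patient - control):")
print(top[["log2fc", "t_mod", "p_adj"]].round(4).to_string())
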