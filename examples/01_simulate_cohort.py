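"""Simulate a two-group multi-omics cohort with planted ground truth.

The generator emulates every input of the analysis: three expression layers
(mRNA, miRNA, lncRNA) for cases vs controls, a beta-value methylation
matrix, a paired hippocampus/cortex reference cohort, and a miRNA
target-prediction table. Planted signals (DE features, sponge triads,
hypomethylated-upregulated genes, tissue-confounded decoys) are recorded in
a GroundTruth object so downstream stages can be scored.
"""

from cernet import (
    SimulationConfig,
    simulate_cohort,
    simulate_reference_pairs,
    simulate_target_database,
)

config = SimulationConfig(seed=1)
cohort = simulate_cohort(config)
reference, ref_sheet = simulate_reference_pairs(config)
predictions = simulate_target_database(cohort.truth, config, decoy_fraction=0.3)

print(f"cohort: {config.n_case} cases vs {config.n_control} controls")
for layer in ("mRNA", "miRNA", "lncRNA", "methylation"):
    m = cohort.layer(layer)
    print(f"  {layer:12s} {m.n_features} features x {m.n_samples} samples")
truth = cohort.truth
print(f"planted: {sum(len(v) for v in truth.de_features.values())} DE features, "
      f"{len(truth.triads)} ceRNA triads, {len(truth.hypo_up_genes)} hypo-up genes, "
      f"{len(truth.all_confounded())} tissue-confounded decoys")
print(f"first planted triad (lncRNA, miRNA, mRNA): {truth.triads[0]}")
print(f"prediction table: {len(predictions)} rows "
      f"({2 * len(truth.triads)} planted sponge edges, the rest decoys)")
# The triad's latent-activity coupling means its miRNA anticorrelates with
# both its lncRNA and its mRNA across samples -- the sponge signature the
# network stage looks for.
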