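"""Nine-quadrant methylation-expression integration.

Genes are cross-classified by methylation state (hypo/none/hyper) and
expression state (down/none/up) from their significance calls. Quadrant 3
(hypomethylated + upregulated) flags candidate epigenetically activated
genes, ordered by severity of hypomethylation.
"""

from cernet import (
    SimulationConfig,
    classify_de,
    differential_methylation,
    nine_quadrant,
    select_hypomethylated_upregulated,
    simulate_cohort,
    student_t_de,
)
from cernet.methylation_integration import quadrant_counts

cohort = simulate_cohort(SimulationConfig(seed=1))
dm = differential_methylation(cohort.methylation, cohort.samples)
de = classify_de(student_t_de(cohort.mrna, cohort.samples))

assignments = nine_quadrant(dm, de)
counts = quadrant_counts(assignments)
print("quadrant counts (rows: hypo/none/hyper methylation; "
      "cols: down/none/up expression):")
for row in range(3):
    print("  " + "  ".join(f"Q{3 * row + col + 1}:{counts[3 * row + col + 1]:3d}"
                           for col in range(3)))

hypo_up = select_hypomethylated_upregulated(assignments)
print(f"hypomethylated-upregulated genes (most severe first): {hypo_up}")
print(f"planted: {cohort.truth.hypo_up_genes}")
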