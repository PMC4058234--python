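"""Sample QC: how CV filtering rescues clustering on noise-dominated data.

Builds a study in which 97% of genes carry no biology and one control
sample shares a technical signature with the disease group.  On all genes
that control clusters with the wrong group; keeping only the top-5%
coefficient-of-variation genes restores the correct grouping.
"""

from multirank import (
    noise_dominated_scenario,
    filter_top_cv,
    hierarchical_cluster,
    spearman_distance_matrix,
)

counts, groups, outlier = noise_dominated_scenario(seed=1)
print(f"{counts.n_genes} genes x {counts.n_samples} samples; "
      f"expected problem sample: {outlier}\n")

for fraction in (1.0, 0.10, 0.05):
    kept = filter_top_cv(counts, fraction)
    distances = spearman_distance_matrix(kept)
    result = hierarchical_cluster(distances, groups, counts.sample_ids, fraction)
    label = "all genes" if fraction == 1.0 else f"top {fraction:.0%} CV"
    mis = sorted(result.misclassified) or ["none"]
    print(f"{label:>12} ({kept.n_genes:4d} genes): misclassified = {', '.join(mis)}")

print("\nA sample listed as misclassified clusters against its declared "
      "phenotype; with aggressive CV filtering the informative genes "
      "dominate and the grouping becomes correct.")
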