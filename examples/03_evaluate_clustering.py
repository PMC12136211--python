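"""Run the evaluation battery: silhouettes, centroids, associations.

Clustering of the first three scaled ancestry PCs is scored at the ancestry-
group level and at the individual level (repeated samples), and each PC is
tested against the grouping with an assumption-gated ANOVA / Kruskal-Wallis.
"""

from methylancestry import (SimConfig, evaluate_methods, run_from_data,
                            simulate_cohort)

cohort = simulate_cohort(SimConfig(seed=1))
result = run_from_data(cohort.annotation, cohort.signals, cohort.sheet,
                       cohort.cell_props, cohort.control_probes)
report = evaluate_methods(result.pcs, cohort.sheet,
                          geno_pcs=cohort.truth["geno_pcs"])

print("method        silhouette  repeat-dist  mean|r| vs genotype PCs")
for tag, entry in report.per_method.items():
    print(f"{tag:<13} {entry['group']['silhouette_mean']:>9.4f}"
          f"  {entry['repeated']['mean_distance_to_centroid']:>10.4f}"
          f"  {entry['genotype_correlation']['mean_abs_r']:>10.4f}")

print("\ncombined method, PC associations with ancestry group:")
for assoc in report.per_method["combined"]["group"]["associations"]:
    print(f"  PC{assoc.pc_index}: {assoc.test_used}, p = {assoc.p_value:.2e}")
# Higher silhouettes and smaller distances of repeat samples to their
# individual's centroid indicate better ancestry clustering.
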