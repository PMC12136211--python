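"""Simulate a synthetic methylation cohort with known ancestry structure.

Builds the standard design — three ancestry groups of 50 individuals with
divergence fst = 0.1, 20% of individuals contributing a repeat sample, 500
SNP-overlapping CpG probes, 50 genotyping rs probes, batch and cell-type
effects — and prints what the cohort contains.
"""

from methylancestry import SimConfig, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=1))

print(f"samples:              {len(cohort.sheet)}")
print(f"individuals:          {cohort.sheet['individual_id'].nunique()}")
rep = cohort.sheet["individual_id"].value_counts()
print(f"with repeat samples:  {(rep > 1).sum()}")
print(f"probes in signal set: {len(cohort.signals.meth)}  "
      f"(500 SNP-overlap CpG + 50 rs + 50 other CpG)")
print(f"control probes:       {cohort.control_probes.shape[1]}")
print("samples per ancestry group:")
print(cohort.sheet["ancestry_label"].value_counts().to_string())
# Each count is slightly above 50 because some individuals were sampled twice;
# the ground truth (genotypes, group codes, batch factors) is in cohort.truth.
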