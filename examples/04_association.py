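"""Random-forest genotype-phenotype association with its control analyses.

Trains 1500-tree forests on stratified 2/3 Monte-Carlo splits (10
repetitions), reports balanced accuracy and AUC-ROC with their permuted
-training controls, aggregates out-of-bag permutation importances and
selects the final variant set "A" by computed ABC analysis.
"""

from thermopain import AssocConfig, CohortSpec, generate_cohort, run_association

spec = CohortSpec(seed=1, n_assoc_loci=8, n_null_loci=72, n_rare_loci=0,
                  n_hwe_violating_loci=0, n_control_loci=0)
table, labels, matrix = generate_cohort(spec)

report = run_association(matrix, labels, AssocConfig(seed=1))

for name, m in report.metrics.items():
    print(f"{name}: {m['mean']:.3f} (95% interval {m['ci_low']:.3f}-"
          f"{m['ci_high']:.3f})")
print(f"final set A: {len(report.final_set)} of {len(report.initial_set)} loci")
planted = set(matrix.info.index[matrix.info["kind"] == "assoc"])
print(f"planted associated loci recovered: "
      f"{len(planted & set(report.final_set))} of {len(planted)}")
print("per-gene tallies (initial vs final):")
print(report.gene_tallies.to_string())

# The intact genotype-phenotype link should clearly beat its permuted
# control on AUC, the permuted control should sit at ~50% balanced
# accuracy (guessing), and most planted loci should reach set "A".
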