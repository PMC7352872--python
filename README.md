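# thermopain

Machine-learned association of ion-channel gene variants with human thermal
pain sensitivity phenotypes.

Human sensitivity to painful heat and cold varies widely, and part of that
variability is genetic: thermosensitive ion channels (TRPV1-4, TRPM2-8,
TRPA1, TRPC1, ASIC1-4) transduce thermal stimuli and carry common variants
that may shift pain thresholds. `thermopain` implements a two-step data
science pipeline for cohorts phenotyped with quantitative sensory testing
(QST) and genotyped by targeted next-generation sequencing:

1. **Phenotype discovery (unsupervised).** From z-scored heat/cold pain
   thresholds at baseline and after UV-B hypersensitization, plus derived
   UV-B effects, strongly correlated variables (|r| > 0.8) are collapsed by
   PCA (eigenvalue > 1 retention); subjects are projected onto an emergent
   self-organizing map (a toroidal grid of 50 × 80 neurons, Gaussian
   neighborhood, 20 epochs) and clusters are read off the U-matrix — the
   landscape of inter-neuron distances — by an automated watershed.
   Clusters are validated with the silhouette index, explained with
   RIPPER-style threshold rules, and compared by repeated-measures ANOVA,
   Welch t-tests (Bonferroni-corrected α = 0.05/6) and a sex χ² test.

2. **Genotype association (supervised).** Variants coded as allele dosages
   x ∈ {0, 1, 2} pass a fixed filter funnel — exact Hardy–Weinberg test,
   Shannon information Info = −p₀·ln p₀ − p₁·ln p₁ of the carrier
   probability, and an allele-level χ² effect-size screen, the latter two
   with data-driven cutoffs from computed ABC analysis (set "A" retained).
   Random forests (1500 trees, ⌈0.2·√d⌉ features per split) are trained on
   stratified 2/3 Monte-Carlo splits, 10 repetitions, reporting balanced
   accuracy and AUC-ROC; out-of-bag permutation importance aggregated over
   repetitions feeds a final ABC analysis whose set "A" is the selected
   variant panel. Two safeguards accompany every run: training repeated on
   permuted genotypes must fall to guessing, and variants in
   negative-control genes (CYP2J2, CYP2C9, CYP2C19) must not be selected.

Because no subject-level data are deposited for this study design, the
package ships a first-class synthetic cohort generator
(`thermopain.cohort`) reproducing the statistical structure the analysis
assumes, and a packaged table of the published 38 selected variants
(`thermopain.packaged_selected_variants()`).

## Worked example

```python
from thermopain import (AssocConfig, CohortSpec, generate_cohort,
                        negative_control_audit, preprocess_genotypes,
                        run_association)

spec = CohortSpec(seed=1)                  # 67 subjects, clusters 42/25
table, labels, matrix = generate_cohort(spec)

filtered, funnel = preprocess_genotypes(matrix, labels)
print(funnel.summary())
# {'input': 92, 'post_hwe': 82, 'post_shannon': 39, 'post_chi2': 5}

report = run_association(filtered, labels, AssocConfig(seed=1))
print(round(report.metrics["auc_roc"]["mean"], 3),
      round(report.metrics["control_balanced_accuracy"]["mean"], 3))
# 0.846 0.476
print(negative_control_audit(report.final_set, matrix.info))
# {'passed': True, 'n_control_loci': 12, 'offending_loci': []}
```

The funnel numbers are loci surviving each filter stage (92 simulated loci
→ 82 after Hardy–Weinberg exclusion → 39 informative by Shannon/ABC → 5
with cluster-level effect sizes in ABC set "A"). The forests then assign
subjects to their phenotype cluster from genotypes alone with a mean
AUC-ROC of 0.85, while the permuted-training control sits at the guessing
level of ~0.5 — the signature that the learned association is real rather
than overfitting — and none of the 12 negative-control-gene loci was
selected. Narrative
walk-throughs of each capability are under `examples/`; the end-to-end run
is also available from the shell:

```sh
thermopain run --outdir runs/demo --seed 1
```

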