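# Methods

This note documents the models and procedures implemented in `thermopain`,
the parameters that matter, the design choices made where the design was
genuinely open, and the known limitations.

## Data model

The analysis operates on two tables. The *phenotype table* holds, per
subject, z-scored heat and cold pain thresholds at baseline and after UV-B
irradiation (`zHPT_baseline`, `zHPT_UVB`, `zCPT_baseline`, `zCPT_UVB`; QST
convention: z-scores are signed so that larger values mean higher pain
sensitivity, with the heat-threshold sign flip assumed already applied) and
the derived UV-B effects `UVBEff_Heat = zHPT_UVB − zHPT_baseline` and
`UVBEff_Cold = zCPT_UVB − zCPT_baseline`. Rows with missing values are not
imputed; operations that need complete data refuse incomplete rows. The
*genotype matrix* holds allele-dosage codes x ∈ {0, 1, 2} (count of
non-reference alleles) per subject and locus, with a missing mask and
per-locus metadata (gene, chromosome, position, variant class SNV/Del/Ins/
MIX inferred from REF/ALT lengths, dbSNP id, negative-control flag). VCF
input is read with cyvcf2; multi-allelic records are split per alternate
allele.

## Phenotype construction

**Correlation screen and decorrelation.** Variable groups chained by
|Pearson r| above a threshold (default 0.8) are replaced by the principal
components of their correlation matrix with eigenvalue strictly greater
than 1 (a component at exactly 1.0 is not retained). For a standardized
2-variable block the eigenvalues are 1 ± r in closed form, so the cold
pair at r = 0.812 yields 1.812 and 0.188 and collapses to one component;
the clustering input space is then five-dimensional (four originals plus
`PC1_zCPT`). The six-variable space without decorrelation remains
available (`feature_matrix(..., decorrelate=False)`).

**Self-organizing map.** The map is *emergent*: 50 × 80 = 4000 neurons —
vastly more than expected clusters — on a torus (opposite edges
connected), used as a projection surface rather than as a k-means
surrogate. Training is online competitive learning: for each sample, the
best-matching unit (BMU) is the nearest neuron in feature space, and all
neurons are pulled toward the sample with weight
α · exp(−g²/2σ²), g the toroidal grid distance to the BMU. Defaults: 20
epochs; σ anneals linearly from half the smaller grid dimension to 1 and α
from 0.5 to 0.05 over all per-sample steps; weights initialize uniformly
within each feature's data range. All of this is deterministic under the
seed. Only grid size, kernel shape and epoch count were externally fixed;
the annealing schedule and initialization are this package's choices.

**U-matrix and watershed.** Each neuron's U-height is the mean Euclidean
distance between its weight vector and its 8 toroidal grid neighbours;
high "ridges" separate valleys of similar subjects. Cluster extraction is
automated: neurons are flooded in increasing height order into basins,
basin merges are recorded with their ridge heights, and the resulting
basin dendrogram is cut at the k − 1 ridges of greatest *topographic
persistence* (ridge height minus the shallower basin's deepest point). A
flat merge-threshold cut was tried first and rejected: it is equivalent to
a single-linkage dendrogram cut and, on large sparsely-populated maps,
splits off single-outlier basins instead of the main boundary. Persistence
cutting formalizes the visual criterion that a boundary counts by how deep
the valleys on both sides are. Two robustness options, used by the
pipeline defaults: a toroidal mean filter on the heights before flooding
(window 5) and a minimum basin occupancy (10% of subjects) below which a
cut is not accepted. Both default off in the library function.

**Validation and explanation.** Cluster quality is the mean silhouette
width (Euclidean; singleton clusters and 0/0 contribute 0), computed via
scikit-learn and cross-checked in the tests against a brute-force O(n²)
implementation. Clusters are explained by a RIPPER-style
separate-and-conquer learner: conjunctive threshold rules for the minority
class grown by FOIL information gain over midpoint thresholds, pruned by
reduced-error pruning on a held-out third (metric (p − n)/(p + n)), with a
one-sided binomial test of the pruned rule against the class prior
(α = 0.05) as the stopping criterion — this keeps noise-fitted rules out
while recovering planted thresholds to ±0.1. A guardrail drops trailing
rules if training accuracy would fall below the majority-class baseline.
Cluster contrasts use a two-way mixed ANOVA (within factor "test" over the
six variables, between factor cluster, subject as repeated unit; standard
sums-of-squares decomposition, no sphericity correction, verified in tests
against both hand-computed sums of squares and pingouin), Welch t-tests
per variable at Bonferroni-corrected α = 0.05/6 ≈ 0.00833, and a 2 × 2 sex
χ² with Yates continuity correction (matching R's default, since reference
results were produced in R).

## Computed ABC analysis

ABC analysis partitions non-negative item values into a most-profitable
set "A", intermediate "B" and trivial "C" purely from the cumulative
yield-vs-effort curve of the descending-sorted values. The A/B limit is
the observed curve point closest (Euclidean) to the ideal point (0, 1);
the B/C limit sits just before the first item whose marginal yield falls
below the uniform rate 1/n. Both criteria are evaluated on the empirical
step curve without interpolation, making the partition deterministic and
checkable by exhaustive search (the tests do exactly that for n ≤ 200).
Ties in sorting break by original index; distance ties break toward the
smaller set within a 1e-9 tolerance, which also makes the partition
invariant under positive scaling. If the break-even index precedes the
Pareto index, B is empty by clamping.

## Genotype filter funnel

The order is fixed: Hardy–Weinberg → Shannon/ABC → χ²/ABC, with a report
of locus counts surviving each stage. Filters only ever remove loci.

**Hardy–Weinberg exact test.** Conditional on the subject count and
minor-allele count, all heterozygote counts of matching parity are
enumerated; P(n_het) ∝ 2^n_het · n!/(n₀!n₁!n₂!), and the p-value sums
configurations no more probable than the observed one. Monomorphic loci
return p = 1. Exclusion α defaults to 0.05 (configurable; the reference
threshold is unstated). The test is validated against a rational-arithmetic
enumeration oracle for every genotype table with n ≤ 20 and shown
sub-uniform under simulated null loci.

**Shannon information.** Info = −p₀·ln p₀ − p₁·ln p₁ (nats, 0·ln 0 = 0)
with p₁ the *carrier* fraction (n₁ + n₂)/n by default — reading the
observation event as "subject carries at least one variant allele" — and
an allele-frequency alternative exposed as `mode="allele"`. The
informativeness cutoff is not a constant: the per-locus Info values are
partitioned by ABC analysis and set "A" is retained (configurable to
"AB").

**Effect-size screen.** Per locus, a 2 × 2 Pearson χ² (no continuity
correction) of allele counts (two alleles per subject, reference vs
variant) by cluster; subjects with missing calls at a locus are dropped
for that locus. χ² values again go through ABC analysis with set "A"
retained. Allele-level tables were chosen over 2 × 3 genotype tables for
consistency with per-cluster allelic-frequency reporting.

## Association harness

The data space is d genetic features over n subjects in 2 phenotype
classes. Each of `n_repetitions = 10` Monte-Carlo repetitions draws a
stratified split with train size round(2n/3) (per-class rounding adjusted
to the exact total), fits a random forest with `n_trees = 1500` and
⌈0.2·√d⌉ candidate features per split (scikit-learn, unlimited depth, no
class weighting), and evaluates balanced accuracy (mean of per-class
recalls) and AUC-ROC from the forests' vote fractions on the held-out
third. Metric summaries report the mean and the 2.5th–97.5th percentile
interval across repetitions (the interval method is this package's
choice). With one repetition the interval degenerates to the point value.

**Importance.** Per-locus importance is out-of-bag permutation mean
decrease in accuracy: for each tree, accuracy on its out-of-bag training
samples before and after permuting one feature, averaged over trees and
`importance_repeats = 3` permutations. One global permutation per repeat
is evaluated on each tree's OOB subset (statistically equivalent to
per-tree permutation for breaking the feature–label link) and all permuted
matrices share one batched forest traversal. Exclusion-refit importance
(drop the locus, refit, measure the accuracy loss) is available as a slow
option. Importances are averaged across repetitions, clipped at zero
(irrelevant loci can drift slightly negative), and partitioned by ABC
analysis; set "A" is the final variant selection. A per-run consensus mode
is not implemented; averaging is the default reading.

**Controls.** The permutation control shuffles the rows of the training
genotype block (phenotypes fixed) before fitting and evaluates on the
untouched test fold; an identity-permutation hook reproduces the plain fit
exactly, which the tests exercise. On planted-association cohorts the
control sits at 50% balanced accuracy while the intact link exceeds its
control by ≥ 0.15 AUC. The negative-control audit passes iff no
control-flagged locus (cytochrome P450 genes, no known nociception role)
reaches the final set "A". Gene tallies count variants per gene in the
initial and final sets with a Pearson correlation between the two count
vectors (undefined and reported as such below 3 genes).

## Synthetic cohorts

The generator defines the study conditions; its defaults emulate the
genotyped cohort: 67 subjects in clusters of 42 and 25 (a phenotyping
variant with 82 subjects, 51/31, is provided), within-cluster unit-variance
Gaussian phenotypes (inputs are z-scores by construction), a cold pair
drawn bivariate-normal at r = 0.812 within cluster, a heat pair at r =
0.55 with a +0.8 z right-shift after UV-B (and +0.2 for cold) so the
derived UV-B effects are non-degenerate without modeling skin physiology.
Between-cluster mean shifts (−1.35, −1.2, −3.0, −2.2 z-units on
zHPT_baseline, zHPT_UVB, zCPT_baseline, zCPT_UVB) are sized to reproduce
the reported cluster contrasts: dominated by baseline cold, moderate heat,
small UV-B-effect differences. The resulting Mahalanobis separation in the
5-feature clustering space is ≈3.4 SD (Bayes error ≈5%), so perfect
cluster recovery is impossible by construction — passing tests demonstrate
substantial, not perfect, agreement at these conditions; the ≥0.9 adjusted
Rand property is demonstrated at 5-SD separation, where the k-means oracle
confirms separability.

The locus panel mixes: 8 associated loci with per-cluster allele
frequencies at differentials 0.25–0.35 (e.g. 0.39 vs 0.66, the range of
the published selected variants), sampled binomial(2, q_cluster); null and
negative-control loci in Hardy–Weinberg proportions with q ~ U(0.05, 0.5);
rare loci with 1–2 heterozygous carriers; HWE-violating loci sampled
homozygote-only (maximal heterozygote deficit). Variant classes are drawn
at the observed composition (78.7% SNV, 10.9% Del, 8.6% Ins, 1.8% MIX).
One master seed drives independent per-component streams (phenotypes,
genotypes, scores), so every stage is bit-reproducible on its own. The
generator does **not** model linkage disequilibrium between loci,
sequencing error, read-level data, or the joint distribution of heat and
cold beyond the stated correlations — so passing tests say nothing about
robustness to LD structure or genotyping artifacts beyond the planted
ones. Functional-score sets (e.g. Eigen scores, which this package never
computes) are emulated as normal samples at requested moments.

## Score comparisons

Wilcoxon–Mann–Whitney tests compare per-variant functional-score
distributions between sets. W follows the first-sample convention
(rank-sum of x minus n_x(n_x+1)/2, so W(x,y) + W(y,x) = n_x·n_y), with
exact enumeration for untied samples of combined size ≤ 20 and the normal
approximation with tie and continuity corrections otherwise.

## Problem sizes and runtimes

The test suite runs the full-size configuration (1500 trees, 10
repetitions) for the chance-level control and the importance-recovery
property (4 seeds), and scaled-down configurations elsewhere (500 trees /
5 repetitions for the 10-seed audit property; 20 × 30 maps for the
clustering property suite; a 12 × 18 map and 120-tree forests in the
pipeline smoke test). These sizes are the package's choices to keep the
suites exhaustive per property rather than per replicate. The acceptance
script runs the full-size association configuration once.

## Known limitations

- Watershed cluster extraction on U-matrices of moderately overlapping
  data is less accurate than centroid methods at the same separation; it
  is retained because it imposes no cluster shape.
- The rm-ANOVA applies no sphericity correction.
- The HWE test, Shannon filter and χ² screen treat loci independently; no
  multiple-testing adjustment is applied across loci in the funnel (the
  ABC cutoffs are rank-based, not error-rate-based).
- OOB bootstrap reconstruction relies on scikit-learn's internal bootstrap
  index generator; the environment pins the version.
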