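"""Machine-learned genotype-phenotype association with control analyses.

The association harness asks whether genotypes carry information about the
phenotype clusters: random forests are trained on Monte-Carlo resampled
2/3 splits of the subjects and evaluated on the held-out third (balanced
accuracy and AUC-ROC from the forests' vote fractions).  Three safeguards
accompany the headline numbers:

* a permutation control refits each run with the subject-to-genotype links
  shuffled in the training data — performance must drop to guessing;
* negative-control loci (variants in genes with no known nociception role)
  must not survive into the final variant selection;
* per-locus importances (mean decrease in accuracy under feature
  permutation) are averaged over runs and submitted to a computed ABC
  analysis, whose set "A" is the final most-informative variant set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .abc_analysis import abc_partition
from .genotypes import GenotypeMatrix

__all__ = [
    "AssocConfig",
    "RunResult",
    "AssociationReport",
    "mc_split",
    "fit_and_evaluate",
    "permutation_control",
    "run_association",
    "negative_control_audit",
    "gene_tally",
]


@dataclass(frozen=True)
class AssocConfig:
    """Hyperparameters of the association harness.

    ``n_trees`` and the per-split feature count ``ceil(mtry_factor * sqrt(d))``
    follow the tuned forest configuration; training uses a stratified
    Monte-Carlo ``train_fraction`` split repeated ``n_repetitions`` times.
    """

    n_trees: int = 1500
    mtry_factor: float = 0.2
    train_fraction: float = 2 / 3
    n_repetitions: int = 10
    seed: int = 0
    permutation_control: bool = True
    importance_method: str = "permutation"  # or "refit" (slow)
    importance_repeats: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1 or self.n_repetitions < 1:
            raise ValueError("counts must be positive")
        if self.importance_method not in ("permutation", "refit"):
            raise ValueError("importance_method must be 'permutation' or 'refit'")

    def mtry(self, d: int) -> int:
        return max(1, math.ceil(self.mtry_factor * math.sqrt(d)))


@dataclass(frozen=True)
class RunResult:
    """Metrics of one Monte-Carlo repetition (and its permuted control)."""

    repetition: int
    balanced_accuracy: float
    auc_roc: float
    importances: np.ndarray = field(repr=False)
    control_balanced_accuracy: float | None = None
    control_auc_roc: float | None = None


def mc_split(n: int, labels, fraction: float = 2 / 3, seed: int = 0):
    """Stratified Monte-Carlo train/test split of ``n`` subjects.

    Train size is ``round(fraction * n)``; per-class allocations are rounded
    and then adjusted so both classes appear in both parts and the total is
    exact.  Returns ``(train_idx, test_idx)`` as sorted index arrays.
    """
    labels = np.asarray(labels)
    if n < 6 or labels.shape[0] != n:
        raise ValueError("need n >= 6 subjects with aligned labels")
    classes = np.unique(labels)
    if any((labels == c).sum() < 2 for c in classes):
        raise ValueError("every class needs at least 2 subjects")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    target = int(round(fraction * n))
    takes = {}
    for c in classes:
        nc = int((labels == c).sum())
        takes[c] = min(max(int(round(fraction * nc)), 1), nc - 1)
    # fix rounding drift while keeping 1 <= take <= nc-1
    drift = target - sum(takes.values())
    for c in sorted(classes, key=lambda c: -(labels == c).sum()):
        nc = int((labels == c).sum())
        adj = max(1, min(nc - 1, takes[c] + drift))
        drift -= adj - takes[c]
        takes[c] = adj
        if drift == 0:
            break
    train = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        train.extend(rng.permutation(members)[: takes[c]])
    train = np.sort(np.asarray(train))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def _forest(d: int, config: AssocConfig, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.mtry(d),
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )


def _evaluate(model, X_test, y_test) -> tuple[float, float]:
    from sklearn.metrics import balanced_accuracy_score, roc_auc_score

    pred = model.predict(X_test)
    votes = model.predict_proba(X_test)[:, 1]
    bacc = balanced_accuracy_score(y_test, pred)
    auc = roc_auc_score(y_test, votes)
    return float(bacc), float(auc)


def fit_and_evaluate(X_train, y_train, X_test, y_test, config: AssocConfig,
                     seed: int = 0, compute_importance: bool = True) -> RunResult:
    """Train one forest and evaluate it on the held-out subjects.

    Per-locus importance is the mean decrease in accuracy when that locus's
    test values are permuted (``importance_method="permutation"``) or when
    the locus is excluded and the forest refit (``"refit"``, slow).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    d = X_train.shape[1]
    model = _forest(d, config, seed)
    model.fit(X_train, y_train)
    bacc, auc = _evaluate(model, X_test, y_test)

    importances = np.zeros(d)
    if compute_importance:
        if config.importance_method == "permutation":
            importances = _oob_permutation_mda(
                model, X_train, y_train, config.importance_repeats,
                seed=int(seed) % (2**32))
        else:  # exclusion-refit
            from sklearn.metrics import accuracy_score

            base = accuracy_score(y_test, model.predict(X_test))
            for j in range(d):
                keep = np.delete(np.arange(d), j)
                sub = _forest(d - 1, config, seed + j + 1)
                sub.fit(X_train[:, keep], y_train)
                importances[j] = base - accuracy_score(
                    y_test, sub.predict(X_test[:, keep]))
    return RunResult(repetition=0, balanced_accuracy=bacc, auc_roc=auc,
                     importances=importances)


def _oob_masks(model, n: int) -> np.ndarray:
    """Boolean (n_trees, n) mask of each tree's out-of-bag samples."""
    from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                          _get_n_samples_bootstrap)

    n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    masks = np.zeros((len(model.estimators_), n), dtype=bool)
    for t, est in enumerate(model.estimators_):
        idx = _generate_unsampled_indices(est.random_state, n, n_boot, None)
        masks[t, idx] = True
    return masks


def _per_tree_correct(model, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean (rows, n_trees): does each tree predict each row correctly?

    One batched ``apply`` call resolves every row to its leaf in every tree;
    leaves are then mapped to majority classes, avoiding per-tree predict
    overhead.
    """
    leaves = model.apply(X)  # (rows, n_trees)
    correct = np.empty(leaves.shape, dtype=bool)
    for t, est in enumerate(model.estimators_):
        node_class = model.classes_[
            np.argmax(est.tree_.value.squeeze(axis=1), axis=1)]
        correct[:, t] = node_class[leaves[:, t]] == y
    return correct


def _oob_permutation_mda(model, X_train, y_train, n_repeats: int,
                         seed: int) -> np.ndarray:
    """Out-of-bag mean decrease in accuracy under feature permutation.

    For each tree, accuracy is measured on its out-of-bag training samples
    before and after permuting one feature's values; the importance of the
    feature is the decrease averaged over trees (and permutation repeats).
    All permuted matrices share one batched forest traversal.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    n, d = X.shape
    oob = _oob_masks(model, n)                      # (T, n)
    oob_sizes = oob.sum(axis=1)
    live = oob_sizes > 0
    base_correct = _per_tree_correct(model, X, y)   # (n, T)
    base_acc = np.where(
        live, (base_correct.T & oob).sum(axis=1) / np.maximum(oob_sizes, 1), 0.0)

    stacked = np.empty((d * n_repeats, n, d))
    block = 0
    for j in range(d):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            stacked[block] = Xp
            block += 1
    correct = _per_tree_correct(model, stacked.reshape(-1, d),
                                np.tile(y, d * n_repeats))
    correct = correct.reshape(d * n_repeats, n, -1).astype(np.float32)
    perm_acc = np.einsum("bnt,tn->bt", correct, oob.astype(np.float32))
    perm_acc /= np.maximum(oob_sizes, 1)[None, :]
    perm_acc = perm_acc.reshape(d, n_repeats, -1).mean(axis=1)  # (d, T)
    drops = base_acc[None, :] - perm_acc
    return drops[:, live].mean(axis=1)


def permutation_control(X_train, y_train, X_test, y_test, config: AssocConfig,
                        seed: int = 0, permutation=None) -> RunResult:
    """Refit with subject-to-genotype links destroyed in the training data.

    Rows of the training genotype block are shuffled (phenotype labels stay
    fixed) before fitting; evaluation uses the untouched test data.  Passing
    an explicit ``permutation`` (e.g. the identity) overrides the shuffle —
    a test hook.
    """
    X_train = np.asarray(X_train, dtype=float)
    if permutation is None:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(seed), 0xC0])))
        permutation = rng.permutation(X_train.shape[0])
    return fit_and_evaluate(X_train[np.asarray(permutation)], y_train,
                            X_test, y_test, config, seed=seed,
                            compute_importance=False)


def _summary(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "ci_low": float(np.percentile(arr, 2.5)),
        "ci_high": float(np.percentile(arr, 97.5)),
    }


@dataclass
class AssociationReport:
    """Aggregated outcome of the Monte-Carlo association analysis."""

    runs: list[RunResult]
    metrics: dict                      # summaries for each metric
    importances: pd.Series             # mean over runs, per locus
    final_set: list[str]               # ABC set "A" of the importances
    initial_set: list[str]
    gene_tallies: pd.DataFrame | None
    gene_correlation: tuple[float, float] | None
    control_audit: dict | None
    chance_level: bool                 # accuracy CI covers 0.5
    config: AssocConfig

    def to_json(self) -> str:
        payload = {
            "metrics": self.metrics,
            "final_set": list(self.final_set),
            "n_final": len(self.final_set),
            "n_initial": len(self.initial_set),
            "chance_level": self.chance_level,
            "control_audit": self.control_audit,
            "gene_correlation": (
                None if self.gene_correlation is None
                else {"r": self.gene_correlation[0], "p": self.gene_correlation[1]}
            ),
            "runs": [
                {
                    "repetition": r.repetition,
                    "balanced_accuracy": r.balanced_accuracy,
                    "auc_roc": r.auc_roc,
                    "control_balanced_accuracy": r.control_balanced_accuracy,
                    "control_auc_roc": r.control_auc_roc,
                }
                for r in self.runs
            ],
            "seed": self.config.seed,
        }
        return json.dumps(payload, indent=2)


def run_association(matrix: GenotypeMatrix, labels,
                    config: AssocConfig | None = None) -> AssociationReport:
    """Full Monte-Carlo association analysis of a preprocessed matrix.

    Each repetition draws a stratified 2/3 split, fits and evaluates a
    forest, and (optionally) a permuted-training control.  Importances are
    averaged across repetitions and partitioned by computed ABC analysis;
    set "A" is the final variant selection.  If the balanced-accuracy
    interval covers 0.5 the report flags chance-level performance.
    """
    config = config or AssocConfig()
    labels = np.asarray(labels)
    X = matrix.codes.to_numpy(dtype=float)
    if np.isnan(X).any():
        # forests need complete data; impute is out of policy, so drop the
        # offending loci with an explicit error instead
        raise ValueError("association requires loci without missing calls")
    n, d = X.shape
    root = np.random.SeedSequence(int(config.seed))
    run_seeds = root.generate_state(config.n_repetitions * 2, dtype=np.uint32)

    runs: list[RunResult] = []
    for rep in range(config.n_repetitions):
        s_split, s_fit = (int(run_seeds[2 * rep]), int(run_seeds[2 * rep + 1]))
        train, test = mc_split(n, labels, config.train_fraction, seed=s_split)
        result = fit_and_evaluate(X[train], labels[train], X[test],
                                  labels[test], config, seed=s_fit)
        result = replace(result, repetition=rep)
        if config.permutation_control:
            ctrl = permutation_control(X[train], labels[train], X[test],
                                       labels[test], config, seed=s_fit)
            result = replace(result,
                             control_balanced_accuracy=ctrl.balanced_accuracy,
                             control_auc_roc=ctrl.auc_roc)
        runs.append(result)

    metrics = {
        "balanced_accuracy": _summary([r.balanced_accuracy for r in runs]),
        "auc_roc": _summary([r.auc_roc for r in runs]),
    }
    if config.permutation_control:
        metrics["control_balanced_accuracy"] = _summary(
            [r.control_balanced_accuracy for r in runs])
        metrics["control_auc_roc"] = _summary([r.control_auc_roc for r in runs])

    mean_imp = pd.Series(np.mean([r.importances for r in runs], axis=0),
                         index=matrix.loci, name="importance")
    # ABC analysis needs non-negative items; permutation MDA can dip just
    # below zero for irrelevant loci — clip at zero (they are trivial anyway)
    abc = abc_partition(np.clip(mean_imp.to_numpy(), 0.0, None))
    final = [matrix.loci[i] for i in abc.a]
    initial = list(matrix.loci)

    tallies = corr = None
    if "gene" in matrix.info.columns:
        tallies, corr = gene_tally(final, initial, matrix.info)
    audit = None
    if "is_control" in matrix.info.columns and matrix.info["is_control"].any():
        audit = negative_control_audit(final, matrix.info)

    ci = metrics["balanced_accuracy"]
    report = AssociationReport(
        runs=runs,
        metrics=metrics,
        importances=mean_imp,
        final_set=final,
        initial_set=initial,
        gene_tallies=tallies,
        gene_correlation=corr,
        control_audit=audit,
        chance_level=bool(ci["ci_low"] <= 0.5 <= ci["ci_high"]),
        config=config,
    )
    return report


def negative_control_audit(final_set, info: pd.DataFrame) -> dict:
    """Pass iff no negative-control locus reached the final set "A"."""
    controls = set(info.index[info["is_control"].astype(bool)])
    offenders = sorted(controls & set(final_set))
    return {
        "passed": not offenders,
        "n_control_loci": len(controls),
        "offending_loci": offenders,
    }


def gene_tally(final_set, initial_set, info: pd.DataFrame):
    """Per-gene variant counts in the initial and final sets, with Pearson r.

    The correlation asks whether the final selection merely mirrors how many
    variants each gene started with.  With fewer than 3 genes the
    correlation is undefined and reported as None.
    """
    genes = info.loc[list(initial_set), "gene"]
    initial_counts = genes.value_counts()
    final_counts = info.loc[list(final_set), "gene"].value_counts()
    tallies = pd.DataFrame({
        "initial": initial_counts,
        "final": final_counts.reindex(initial_counts.index, fill_value=0),
    }).fillna(0).astype(int)
    corr = None
    if len(tallies) >= 3 and tallies["initial"].nunique() > 1 \
            and tallies["final"].nunique() > 1:
        r, p = stats.pearsonr(tallies["initial"], tallies["final"])
        corr = (float(r), float(p))
    return tallies, corr
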