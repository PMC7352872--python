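"""Phenotype construction and cluster statistics for thermal pain data.

The phenotype space consists of z-scored heat and cold pain thresholds at
baseline and after UV-B hypersensitization, plus the two derived UV-B
effects (post-irradiation minus baseline).  Before projecting subjects with
a self-organizing map, strongly correlated variables are replaced by their
leading principal components; after clustering, the clusters are compared
with a repeated-measures ANOVA, per-variable Welch t-tests under Bonferroni
correction, and a sex contingency test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PHENOTYPE_VARS",
    "ALL_VARS",
    "derive_uvb_effects",
    "CorrelationScreen",
    "correlation_screen",
    "PcaBlock",
    "pca_decorrelate",
    "feature_matrix",
    "silhouette_index",
    "ClusterStats",
    "cluster_stats",
]

PHENOTYPE_VARS = ("zHPT_baseline", "zHPT_UVB", "zCPT_baseline", "zCPT_UVB")
UVB_EFFECT_VARS = ("UVBEff_Heat", "UVBEff_Cold")
ALL_VARS = PHENOTYPE_VARS + UVB_EFFECT_VARS


def derive_uvb_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Append the UV-B effect columns (post-UV-B minus baseline z-scores)."""
    missing = [c for c in PHENOTYPE_VARS if c not in table.columns]
    if missing:
        raise KeyError(f"phenotype table lacks columns: {missing}")
    out = table.copy()
    out["UVBEff_Heat"] = table["zHPT_UVB"] - table["zHPT_baseline"]
    out["UVBEff_Cold"] = table["zCPT_UVB"] - table["zCPT_baseline"]
    return out


@dataclass(frozen=True)
class CorrelationScreen:
    """Groups of variables pairwise linked by |r| above the threshold."""

    blocks: tuple[tuple[str, ...], ...]
    singles: tuple[str, ...]
    excluded_constant: tuple[str, ...]
    correlations: pd.DataFrame = field(repr=False)


def correlation_screen(table: pd.DataFrame, threshold: float = 0.8,
                       columns=None) -> CorrelationScreen:
    """Find maximal groups of variables chained by |Pearson r| > threshold.

    Constant columns (undefined correlation) are reported and excluded.
    Variables not in any group pass through as singles.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(cols) < 2:
        raise ValueError("need at least two numeric columns")
    data = table[cols]
    if data.isna().any().any():
        raise ValueError("correlation screen requires complete rows")
    constant = tuple(c for c in cols if data[c].nunique() <= 1)
    usable = [c for c in cols if c not in constant]
    corr = data[usable].corr()
    # union-find over the |r| > threshold graph -> connected components
    parent = {c: c for c in usable}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for c in usable:
        groups.setdefault(find(c), []).append(c)
    blocks = tuple(tuple(g) for g in groups.values() if len(g) > 1)
    singles = tuple(c for g in groups.values() if len(g) == 1 for c in g)
    return CorrelationScreen(blocks, singles, constant, corr)


@dataclass(frozen=True)
class PcaBlock:
    """PCA of a standardized variable block (correlation-matrix eigensystem)."""

    variables: tuple[str, ...]
    eigenvalues: np.ndarray          # descending; sums to block size
    loadings: np.ndarray             # columns = components
    scores: pd.DataFrame             # retained component scores
    retained: tuple[str, ...]        # names of retained components

    @property
    def explained_pct(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum() * 100.0


def pca_decorrelate(table: pd.DataFrame, block) -> PcaBlock:
    """Decorrelate a block of variables via PCA of their correlation matrix.

    Variables are standardized before the eigendecomposition; components
    with eigenvalue strictly greater than 1 are retained (components at
    exactly 1 are not).  Component names share the block's common prefix,
    e.g. the cold pair ``zCPT_baseline``/``zCPT_UVB`` yields ``PC1_zCPT``.
    """
    block = tuple(block)
    if len(block) < 2:
        raise ValueError("PCA block needs at least two variables")
    data = table[list(block)].to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError("PCA block requires complete rows")
    sd = data.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variable in PCA block")
    z = (data - data.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    # sign convention: make each component's largest loading positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0),
                           np.arange(len(block))])
    eigvecs = eigvecs * np.where(flip == 0, 1.0, flip)

    import os
    prefix = os.path.commonprefix([v for v in block]).rstrip("_") or "block"
    names = tuple(f"PC{k + 1}_{prefix}" for k in range(len(block)))
    keep = eigvals > 1.0
    scores = pd.DataFrame(
        (z @ eigvecs)[:, keep],
        columns=[n for n, k in zip(names, keep) if k],
        index=table.index,
    )
    return PcaBlock(
        variables=block,
        eigenvalues=eigvals,
        loadings=eigvecs,
        scores=scores,
        retained=tuple(scores.columns),
    )


def feature_matrix(table: pd.DataFrame, threshold: float = 0.8,
                   decorrelate: bool = True, columns=ALL_VARS):
    """Build the clustering input space from the phenotype table.

    With ``decorrelate=True`` (default), variable groups exceeding the
    correlation threshold are replaced by their retained principal
    components (for the study structure: the cold pair collapses to one
    component, giving a 5-variable space); otherwise all columns pass
    through unchanged.  Returns ``(features, pca_blocks)``.
    """
    cols = [c for c in columns if c in table.columns]
    data = table[cols]
    if not decorrelate:
        return data.copy(), []
    screen = correlation_screen(data, threshold=threshold)
    blocks = [pca_decorrelate(data, blk) for blk in screen.blocks]
    out = data[[c for c in cols if c in screen.singles]].copy()
    for blk in blocks:
        for name in blk.retained:
            out[name] = blk.scores[name]
    return out, blocks


def silhouette_index(data, labels) -> float:
    """Mean silhouette width over subjects (Euclidean metric).

    For each subject, (b - a) / max(a, b) with a = mean within-cluster
    distance and b = smallest mean distance to another cluster; singleton
    clusters and all-identical points contribute 0 (0/0 convention).
    """
    from sklearn.metrics import silhouette_score

    X = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(silhouette_score(X, labels, metric="euclidean"))


@dataclass(frozen=True)
class ClusterStats:
    """Statistical comparison of the phenotype clusters."""

    anova: pd.DataFrame       # effects test / cluster / interaction
    t_tests: pd.DataFrame     # per-variable Welch t, df, p, significance
    alpha: float
    alpha_corrected: float
    sex_chi2: float | None
    sex_df: int | None
    sex_p: float | None


def _mixed_anova(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Two-way mixed ANOVA: within factor = variable ("test"), between =
    cluster, subject as the repeated unit.  Standard sums-of-squares
    decomposition on the complete subjects-by-variables layout."""
    n, k = values.shape
    glabels = np.unique(groups)
    g = glabels.size
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)

    ss_total = ((values - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_cluster = 0.0
    ss_cells = 0.0
    for lab in glabels:
        sel = groups == lab
        ng = sel.sum()
        ss_cluster += k * ng * (subj_means[sel].mean() - grand) ** 2
        cell = values[sel].mean(axis=0)
        ss_cells += ng * ((cell - grand) ** 2).sum()
    ss_err_between = ss_between_subj - ss_cluster
    ss_test = n * ((cond_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_test - ss_cluster
    ss_err_within = ss_total - ss_between_subj - ss_test - ss_inter

    rows = []
    df_eb, df_ew = n - g, (n - g) * (k - 1)
    for name, ss, df1, df2, ss_err in (
        ("test", ss_test, k - 1, df_ew, ss_err_within),
        ("cluster", ss_cluster, g - 1, df_eb, ss_err_between),
        ("test:cluster", ss_inter, (g - 1) * (k - 1), df_ew, ss_err_within),
    ):
        ms, ms_err = ss / df1, ss_err / df2
        F = ms / ms_err if ms_err > 0 else np.inf
        rows.append({
            "effect": name, "ss": ss, "df1": df1, "df2": df2, "F": F,
            "p": float(stats.f.sf(F, df1, df2)),
        })
    return pd.DataFrame(rows)


def cluster_stats(table: pd.DataFrame, labels, sex=None,
                  variables=ALL_VARS, alpha: float = 0.05) -> ClusterStats:
    """Compare phenotype clusters: rm-ANOVA, Welch t-tests, sex chi-square.

    The Bonferroni-corrected alpha is ``alpha / len(variables)`` (0.00833
    for the six thermal-pain variables at alpha = 0.05).
    """
    labels = np.asarray(labels)
    variables = [v for v in variables if v in table.columns]
    values = table[variables].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("cluster statistics require complete rows")
    glabels = np.unique(labels)
    if glabels.size != 2:
        raise ValueError("exactly two clusters required")
    if min((labels == g).sum() for g in glabels) < 2:
        raise ValueError("each cluster needs at least two subjects")

    anova = _mixed_anova(values, labels)
    alpha_corr = alpha / len(variables)
    rows = []
    a, b = (values[labels == g] for g in glabels)
    for j, var in enumerate(variables):
        t, p = stats.ttest_ind(a[:, j], b[:, j], equal_var=False)
        df = _welch_df(a[:, j], b[:, j])
        rows.append({"variable": var, "t": float(t), "df": df, "p": float(p),
                     "significant_corrected": p < alpha_corr})
    sex_chi2 = sex_df = sex_p = None
    if sex is not None:
        contingency = pd.crosstab(np.asarray(sex), labels)
        chi2, p, df, _ = stats.chi2_contingency(contingency, correction=True)
        sex_chi2, sex_df, sex_p = float(chi2), int(df), float(p)
    return ClusterStats(
        anova=anova,
        t_tests=pd.DataFrame(rows),
        alpha=alpha,
        alpha_corrected=alpha_corr,
        sex_chi2=sex_chi2,
        sex_df=sex_df,
        sex_p=sex_p,
    )


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return float((vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1)))
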