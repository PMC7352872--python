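"""Rank-based comparison of functional annotation-score distributions.

Variant sets (e.g. the finally selected variants vs. positive-control
variants from hereditary pain-insensitivity genes vs. a random genome-wide
draw) are compared on per-variant functional scores — such as Eigen scores,
which aggregate many functional annotations into one unsupervised impact
score.  The scores themselves are inputs (database lookups, never computed
here); this module only tests distributional shifts between sets with
Wilcoxon-Mann-Whitney tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["wilcoxon_rank_sum", "compare_score_sets", "read_score_table"]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns ``(W, p)``.

    W follows the first-sample convention: the rank sum of ``x`` minus
    ``n_x(n_x+1)/2`` (so W(x, y) + W(y, x) = n_x * n_y).  The p-value uses
    exact enumeration for small untied samples (n_x + n_y <= 20) and the
    normal approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score sets must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_score_sets(sets: dict) -> dict:
    """Pairwise rank-sum tests plus per-set moments.

    ``sets`` maps a label to its score vector.  Returns a dict with a
    ``moments`` DataFrame (label, n, mean, sd) and a ``tests`` DataFrame
    (set_x, set_y, W, p) over all ordered-by-input pairs.
    """
    if len(sets) < 2:
        raise ValueError("need at least two score sets")
    moments = pd.DataFrame(
        [
            {
                "set": label,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
            for label, vals in sets.items()
        ]
    )
    rows = []
    for a, b in combinations(sets, 2):
        w, p = wilcoxon_rank_sum(sets[a], sets[b])
        rows.append({"set_x": a, "set_y": b, "W": w, "p": p})
    return {"moments": moments, "tests": pd.DataFrame(rows)}


def read_score_table(path) -> pd.Series:
    """Read a variant-id -> score TSV (columns ``variant``, ``score``)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"variant", "score"} <= set(frame.columns):
        raise ValueError("score table needs 'variant' and 'score' columns")
    return frame.set_index("variant")["score"].astype(float)
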