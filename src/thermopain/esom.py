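"""Emergent self-organizing map projection with U-matrix cluster extraction.

An emergent self-organizing map (ESOM) projects data onto a large toroidal
grid of artificial neurons — thousands of neurons, far more than expected
clusters, so the map acts as a continuous projection surface rather than a
k-means surrogate.  Cluster structure is then read off the U-matrix: each
neuron's height is the mean feature-space distance to its grid neighbours,
so "mountain ridges" of large heights separate valleys of similar subjects.

Cluster extraction is automated by a watershed on the U-matrix landscape:
basins are flooded in increasing height order and merged at ridge heights;
the merge level is scanned until exactly the requested number of basins
containing best-matching units remains.  This replaces visual inspection of
the topographic map with a reproducible algorithmic criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EsomModel", "UMatrix", "train_esom", "compute_umatrix",
           "extract_clusters"]


@dataclass(frozen=True)
class EsomModel:
    """Trained toroidal neuron grid.

    ``weights`` has shape (rows, cols, d); training parameters are recorded
    for provenance.
    """

    rows: int
    cols: int
    weights: np.ndarray
    toroidal: bool
    epochs: int
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class UMatrix:
    """Per-neuron neighbour-distance heights plus per-subject BMU mapping."""

    heights: np.ndarray            # (rows, cols), >= 0
    bmu: np.ndarray                # (n_subjects,) flat neuron index
    rows: int
    cols: int


def _axis_dist(size: int, toroidal: bool) -> np.ndarray:
    """Pairwise grid distances along one axis (with optional wrap-around)."""
    idx = np.arange(size)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, size - d) if toroidal else d


def train_esom(data, rows: int = 50, cols: int = 80, epochs: int = 20,
               seed: int = 0, toroidal: bool = True,
               lr: tuple[float, float] = (0.5, 0.05),
               radius: tuple[float, float] | None = None) -> EsomModel:
    """Train a toroidal self-organizing map by online competitive learning.

    Per-sample updates with a Gaussian neighbourhood kernel on toroidal grid
    distance; the neighbourhood radius anneals linearly from half the
    smaller grid dimension down to 1, the learning rate from 0.5 to 0.05.
    Weights are initialized uniformly within each feature's data range.
    Deterministic for a fixed seed.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training data must be 2-D with at least two subjects")
    if np.isnan(X).any():
        raise ValueError("training data must be complete")
    if rows < 1 or cols < 1 or epochs < 1:
        raise ValueError("grid dimensions and epochs must be positive")
    n, d = X.shape
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))

    lo, hi = X.min(axis=0), X.max(axis=0)
    W = rng.uniform(lo, np.where(hi > lo, hi, lo + 1e-12), size=(rows * cols, d))

    rr, cc = np.unravel_index(np.arange(rows * cols), (rows, cols))
    dr_tab = _axis_dist(rows, toroidal)
    dc_tab = _axis_dist(cols, toroidal)

    r0 = radius[0] if radius else max(min(rows, cols) / 2.0, 1.0)
    r1 = radius[1] if radius else 1.0
    lr0, lr1 = lr
    total = epochs * n
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / max(total - 1, 1)
            sigma = r0 + (r1 - r0) * frac
            alpha = lr0 + (lr1 - lr0) * frac
            x = X[i]
            bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            g2 = (dr_tab[rr, rr[bmu]] ** 2 + dc_tab[cc, cc[bmu]] ** 2)
            h = np.exp(-g2 / (2.0 * sigma * sigma))
            W += (alpha * h)[:, None] * (x - W)
            step += 1
    return EsomModel(rows=rows, cols=cols,
                     weights=W.reshape(rows, cols, d),
                     toroidal=toroidal, epochs=epochs, seed=int(seed))


def _neighbor_offsets():
    return [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if not (dr == 0 and dc == 0)]


def _neighbors(idx: int, rows: int, cols: int, toroidal: bool):
    r, c = divmod(idx, cols)
    for dr, dc in _neighbor_offsets():
        nr, nc = r + dr, c + dc
        if toroidal:
            nr, nc = nr % rows, nc % cols
        elif not (0 <= nr < rows and 0 <= nc < cols):
            continue
        yield nr * cols + nc


def compute_umatrix(model: EsomModel, data) -> UMatrix:
    """U-matrix heights and best-matching units for a trained map.

    Each neuron's height is the mean Euclidean distance between its weight
    vector and those of its 8 grid neighbours (toroidal wrap-around); each
    subject maps to the neuron nearest in feature space.
    """
    X = np.asarray(data, dtype=float)
    rows, cols = model.rows, model.cols
    W = model.weights.reshape(rows * cols, -1)
    heights = np.zeros(rows * cols)
    for idx in range(rows * cols):
        nb = list(_neighbors(idx, rows, cols, model.toroidal))
        diffs = W[nb] - W[idx]
        heights[idx] = np.sqrt((diffs ** 2).sum(axis=1)).mean()
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    bmu = np.argmin(d2, axis=1)
    return UMatrix(heights=heights.reshape(rows, cols), bmu=bmu,
                   rows=rows, cols=cols)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def extract_clusters(umatrix: UMatrix, k: int, toroidal: bool = True,
                     min_size: int = 1, smooth: int = 0) -> np.ndarray:
    """Watershed the U-matrix into exactly ``k`` occupied basins.

    Neurons are flooded in increasing height order; a neuron touching two
    existing basins records a merge at its height.  The merge sequence is
    then assembled into a basin dendrogram whose edges carry their ridge's
    topographic persistence (ridge height minus the shallower basin's
    deepest point).  The ``k - 1`` most persistent ridges that leave at
    least ``min_size`` best-matching units on each side are cut, yielding
    exactly ``k`` occupied basins; subjects inherit their BMU's basin label
    (0..k-1, ordered by decreasing cluster size).  Cutting by persistence
    rather than by a flat merge threshold mirrors the visual criterion of a
    "significant mountain ridge": a boundary counts by how deep the valleys
    on both sides are, which keeps single outliers and surface texture from
    masking the main cluster structure.

    ``smooth`` applies a toroidal mean filter of that window size to the
    heights before flooding, consolidating ridges on large, sparsely
    populated maps (0 disables smoothing).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    rows, cols = umatrix.rows, umatrix.cols
    heights = umatrix.heights
    if smooth:
        from scipy.ndimage import uniform_filter

        heights = uniform_filter(heights, size=smooth, mode="wrap")
    h = heights.ravel()
    order = np.argsort(h, kind="stable")
    basin = np.full(h.size, -1, dtype=int)
    uf = _UnionFind(h.size)
    events: list[tuple[float, int, int]] = []  # (ridge height, rootA, rootB)
    for idx in order:
        roots = {uf.find(nb) for nb in _neighbors(idx, rows, cols, toroidal)
                 if basin[nb] >= 0}
        if not roots:
            basin[idx] = idx
            continue
        roots = sorted(roots)
        basin[idx] = roots[0]
        uf.parent[idx] = roots[0]
        for other in roots[1:]:
            events.append((float(h[idx]), roots[0], other))

    # basin dendrogram: replay merges in ridge order, keeping the first
    # event joining two components as a tree edge with its persistence
    # (ridge height minus the shallower component's deepest point)
    seeds = [idx for idx in range(h.size) if basin[idx] == idx]
    minh = {s: float(h[s]) for s in seeds}
    dendro = _UnionFind(h.size)
    tree: list[tuple[float, int, int]] = []  # (persistence, seedA, seedB)
    for r, a, b in events:
        ra, rb = dendro.find(a), dendro.find(b)
        if ra == rb:
            continue
        tree.append((r - max(minh[ra], minh[rb]), a, b))
        dendro.union(a, b)
        minh[dendro.find(a)] = min(minh[ra], minh[rb])

    bmu_basin = np.array([uf.find(int(b)) for b in umatrix.bmu])
    n_bmu = {s: int((bmu_basin == s).sum()) for s in seeds}

    def occupied_sizes(cut_set):
        comp = _UnionFind(h.size)
        for i, (_, a, b) in enumerate(tree):
            if i not in cut_set:
                comp.union(a, b)
        sizes: dict[int, int] = {}
        for s, c in n_bmu.items():
            root = comp.find(s)
            sizes[root] = sizes.get(root, 0) + c
        return comp, sizes

    # cut the most persistent ridges first; a cut counts only if both sides
    # hold at least min_size best-matching units
    by_persistence = sorted(range(len(tree)), key=lambda i: (-tree[i][0], i))
    cuts: set[int] = set()
    for i in by_persistence:
        if len(cuts) + 1 == k:
            break
        trial = cuts | {i}
        comp, sizes = occupied_sizes(trial)
        _, a, b = tree[i]
        if sizes.get(comp.find(a), 0) >= min_size \
                and sizes.get(comp.find(b), 0) >= min_size:
            cuts = trial
    comp, sizes = occupied_sizes(cuts)
    occupied = [c for c, s in sizes.items() if s > 0]
    if len(cuts) + 1 != k or len(occupied) != k:
        raise ValueError(
            f"U-matrix supports only {len(cuts) + 1} occupied basins of "
            f"size >= {min_size}; k={k} requested")

    labels_raw = np.array([comp.find(int(s)) for s in bmu_basin])
    # relabel by decreasing cluster size, ties by first appearance
    uniq, counts = np.unique(labels_raw, return_counts=True)
    order2 = uniq[np.argsort(-counts, kind="stable")]
    remap = {c: i for i, c in enumerate(order2)}
    return np.array([remap[c] for c in labels_raw])
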