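"""Hierarchical and k-means clustering used to classify individuals.

Individuals are clustered on the centred log expression matrix with
correlation distance, d(i, j) = 1 - Pearson(column_i, column_j), and
group-average (UPGMA) linkage.  The first branch of the dendrogram defines
the two top-level clusters; a cluster counts as enriched for a clinical
group when it holds more than 2/3 of that group's individuals and the 2x2
Fisher exact p-value is below 0.05.

UPGMA ties are broken by the lexicographically smallest pair of cluster ids
(leaves 0..n-1, internal nodes numbered n, n+1, ... in merge order), which
makes dendrograms platform independent.  The k-means cluster number is chosen
by the elbow rule formalised as the maximal second difference of the SSE
curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .exact_tests import fisher_exact_2x2

__all__ = [
    "Dendrogram",
    "ClusterCut",
    "correlation_distance",
    "average_linkage",
    "first_branch_split",
    "enriched_cluster_test",
    "cut_k",
    "kmeans_with_elbow",
    "ENRICHMENT_FRACTION",
    "ENRICHMENT_P",
]

ENRICHMENT_FRACTION = 2.0 / 3.0
ENRICHMENT_P = 0.05
DEFAULT_N_INIT = 50


@dataclass
class Dendrogram:
    """Merge sequence over n leaves.

    ``merges[t]`` is (id_a, id_b, height); the cluster created by merge t has
    id ``n + t``.  ``leaf_ids[i]`` is the external label of leaf i.
    """

    n: int
    merges: list
    leaf_ids: list

    def __post_init__(self):
        if len(self.merges) != self.n - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")

    @property
    def root(self) -> int:
        return self.n + len(self.merges) - 1

    def children(self, node: int):
        """Child node ids of an internal node."""
        if node < self.n:
            raise ValueError("leaves have no children")
        a, b, _ = self.merges[node - self.n]
        return a, b

    def members(self, node: int) -> list:
        """External leaf ids under a node."""
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(self.leaf_ids[v])
            else:
                stack.extend(self.children(v))
        return out

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""

        def h(node):
            return 0.0 if node < self.n else self.merges[node - self.n][2]

        def rec(node):
            if node < self.n:
                return str(self.leaf_ids[node])
            a, b = self.children(node)
            ha = h(node) - h(a)
            hb = h(node) - h(b)
            return f"({rec(a)}:{ha:.6g},{rec(b)}:{hb:.6g})"

        return rec(self.root) + ";"


@dataclass
class ClusterCut:
    """Flat clustering: leaf label -> cluster index in [0, k)."""

    labels: dict
    k: int

    def __post_init__(self):
        found = set(self.labels.values())
        if len(found) != self.k:
            raise ValueError("cut must produce exactly k non-empty clusters")

    def members(self, c: int) -> list:
        return [leaf for leaf, lab in self.labels.items() if lab == c]


def correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns of a features x individuals matrix.

    A constant column has undefined correlations; by convention they are set
    to 0 (distance 1) with a warning, and the diagonal stays 0.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("correlation distance requires >= 2 features")
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    if constant.any():
        warnings.warn("constant column(s); their correlations set to 0",
                      stacklevel=2)
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(dist: np.ndarray, leaf_ids=None) -> Dendrogram:
    """Deterministic UPGMA; ties broken by the smallest (id_a, id_b) pair."""
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if n < 2:
        raise ValueError("average_linkage requires at least 2 leaves")
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    d = (d + d.T) / 2.0  # guard against float-level asymmetry
    if leaf_ids is None:
        leaf_ids = list(range(n))
    leaf_ids = list(leaf_ids)

    ids = list(range(n))          # cluster id per active row
    sizes = [1] * n
    big = np.inf
    np.fill_diagonal(d, big)
    merges = []
    for step in range(n - 1):
        m = d.min()
        cand = np.argwhere(d <= m)  # exact minima; matrix is symmetric
        best = None
        for i, j in cand:
            if i >= j:
                continue
            pair = (min(ids[i], ids[j]), max(ids[i], ids[j]))
            if best is None or pair < best[0]:
                best = (pair, i, j)
        _, i, j = best
        merges.append((min(ids[i], ids[j]), max(ids[i], ids[j]), float(m)))
        si, sj = sizes[i], sizes[j]
        new_row = (si * d[i, :] + sj * d[j, :]) / (si + sj)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = big
        d[j, :] = big
        d[:, j] = big
        ids[i] = n + step
        sizes[i] = si + sj
        ids[j] = -1
    return Dendrogram(n=n, merges=merges, leaf_ids=leaf_ids)


def cut_k(dend: Dendrogram, k: int) -> ClusterCut:
    """Flat clustering from cutting the k-1 highest (latest) merges."""
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of leaves")
    removed = set(range(n + (n - 1) - (k - 1), n + (n - 1)))
    roots = []
    if k == 1:
        roots = [dend.root]
    else:
        for node in sorted(removed):
            for child in dend.children(node):
                if child not in removed:
                    roots.append(child)
    groups = [sorted(dend.members(r), key=lambda x: str(x)) for r in roots]
    groups.sort(key=lambda g: str(min(g, key=str)))
    labels = {}
    for c, g in enumerate(groups):
        for leaf in g:
            labels[leaf] = c
    return ClusterCut(labels=labels, k=k)


def first_branch_split(dend: Dendrogram):
    """The two subtrees of the root; the side holding the smallest id first."""
    a, b = dend.children(dend.root)
    ma = sorted(dend.members(a), key=str)
    mb = sorted(dend.members(b), key=str)
    if str(min(mb, key=str)) < str(min(ma, key=str)):
        ma, mb = mb, ma
    return ma, mb


def enriched_cluster_test(cluster_members, labels: dict, group):
    """Does a cluster hold significantly more of one clinical group?

    Criterion: (i) the cluster holds more than 2/3 of the group's individuals
    (strict), and (ii) the 2x2 Fisher exact p-value (cluster membership x
    group membership) is below 0.05.  Returns (passes, p).
    """
    cluster = set(cluster_members)
    unknown = cluster - set(labels)
    if unknown:
        raise ValueError(f"cluster members without labels: {sorted(unknown)[:5]}")
    in_group = {ind for ind, lab in labels.items() if lab == group}
    if not in_group:
        raise ValueError(f"empty group {group!r}")
    a = len(cluster & in_group)
    b = len(cluster) - a
    c = len(in_group) - a
    d = len(labels) - a - b - c
    p = fisher_exact_2x2([[a, b], [c, d]])
    passes = (a > ENRICHMENT_FRACTION * len(in_group)) and (p < ENRICHMENT_P)
    return passes, p


def _elbow(sse: dict) -> int:
    """Cluster number by the maximal second difference of the SSE curve.

    Degenerate limit: when the smallest k already has (numerically) zero SSE
    the elbow is that k.  Grids without an interior point fall back to the
    largest k with a warning.
    """
    ks = sorted(sse)
    if sse[ks[0]] <= 1e-12:
        return ks[0]
    if len(ks) < 3:
        warnings.warn("SSE grid too short for a second difference; using max k",
                      stacklevel=2)
        return ks[-1]
    curv = {k: sse[km] - 2 * sse[k] + sse[kp]
            for km, k, kp in zip(ks[:-2], ks[1:-1], ks[2:])}
    best = max(curv.values())
    return min(k for k, v in curv.items() if v == best)


def kmeans_with_elbow(data: np.ndarray, k_range, seed: int,
                      n_init: int = DEFAULT_N_INIT):
    """Best-of-n_init k-means per k plus elbow selection of k*.

    Returns (k_star, ClusterCut, sse dict).  The per-call seed stream is
    derived from ``seed`` so repeated calls are deterministic.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n = data.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[0] < 1 or k_range[-1] > n:
        raise ValueError("k_range must lie within [1, n]")
    sse, fits = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points trip ConvergenceWarning
            fit = km.fit(data)
        sse[k] = float(fit.inertia_)
        fits[k] = fit.labels_
    k_star = _elbow(sse)
    labels = {i: int(lab) for i, lab in enumerate(fits[k_star])}
    cut = ClusterCut(labels=labels, k=len(set(labels.values())))
    return k_star, cut, sse
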