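"""Partition-connectivity networks over substages.

Individuals are embedded by principal components (all components, an
orthogonal transform of the centred data) and joined into a symmetric
union-of-kNN graph with n_neighbors = 2, the minimum, so that only the
tightest neighbourhood relations survive.  Connection confidence between two
substages follows the partition-based graph-abstraction idea in its simplest
form: the observed number of inter-partition edges divided by the count
expected if the inter-partition edges were placed uniformly at random across
unordered partition pairs (proportional to the product of partition sizes).
Confidences are left unclipped: genuine adjacencies typically exceed 1,
and capping them would collapse the pruning rule (twice the NCI-AD maximum)
into an empty graph whenever any NCI-AD pair reached half the cap.

Pruning removes every connection whose confidence does not exceed twice the
maximum NCI-substage-to-AD-substage confidence (MD_NA): direct NCI-AD
shortcuts are regarded as artefacts because progression is assumed to pass
through MCI.  Networks built from two different gene-set unions are
intersected (minimum confidence on common edges), and cross-stage edges are
oriented along the clinical ordering NCI < MCI < AD.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PartitionGraph",
    "embed_and_knn",
    "partition_connectivity",
    "prune",
    "intersect",
    "orient",
    "DEFAULT_N_NEIGHBORS",
    "PRUNE_MULTIPLIER",
]

DEFAULT_N_NEIGHBORS = 2
PRUNE_MULTIPLIER = 2.0
STAGE_RANK = {"NCI": 0, "MCI": 1, "AD": 2}


@dataclass
class PartitionGraph:
    """Substage nodes with symmetric, non-negative connection confidences."""

    conf: pd.DataFrame  # symmetric, zero diagonal

    def __post_init__(self):
        c = self.conf
        if not c.index.equals(c.columns):
            raise ValueError("confidence matrix must be square with matching labels")
        if not np.allclose(c.to_numpy(), c.to_numpy().T):
            raise ValueError("confidence weights must be symmetric")
        arr = c.to_numpy().copy()
        np.fill_diagonal(arr, 0.0)
        self.conf = pd.DataFrame(arr, index=c.index, columns=c.columns)

    @property
    def nodes(self) -> list:
        return list(self.conf.index)

    def edges(self) -> list:
        """(node_a, node_b, confidence) for every positive-confidence pair."""
        out = []
        nodes = self.nodes
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                w = float(self.conf.loc[a, b])
                if w > 0:
                    out.append((a, b, w))
        return out

    def edge_set(self) -> set:
        return {frozenset((a, b)) for a, b, _ in self.edges()}


def embed_and_knn(x: pd.DataFrame, n_neighbors: int = DEFAULT_N_NEIGHBORS) -> nx.Graph:
    """Full-rank PCA embedding plus a symmetric union-of-kNN graph.

    ``x`` is features x individuals (centred expression).  Using all
    principal components preserves pairwise distances, so the embedding
    serves reproducibility rather than reduction.
    """
    ids = list(x.columns)
    if len(ids) < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 individuals")
    pts = x.to_numpy(dtype=float).T
    pts = pts - pts.mean(axis=0, keepdims=True)
    if not pts.any():
        raise ValueError("degenerate input: zero variance everywhere")
    # full-rank PCA via SVD; an orthogonal rotation of the centred data
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    emb = pts @ vt.T
    d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    g = nx.Graph()
    g.add_nodes_from(ids)
    order = np.argsort(d2, axis=1, kind="stable")
    for i, ind in enumerate(ids):
        for j in order[i, :n_neighbors]:
            g.add_edge(ind, ids[int(j)])
    return g


def partition_connectivity(graph: nx.Graph, labels: pd.Series) -> PartitionGraph:
    """Observed-over-expected inter-partition edge counts (unclipped)."""
    missing = [n for n in graph.nodes if n not in labels.index]
    if missing:
        raise ValueError(f"unlabelled graph nodes: {missing[:5]}")
    parts = sorted(labels.unique())
    sizes = {p: int((labels == p).sum()) for p in parts}
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty partition")
    e = pd.DataFrame(0.0, index=parts, columns=parts)
    for a, b in graph.edges:
        pa, pb = labels[a], labels[b]
        if pa != pb:
            e.loc[pa, pb] += 1
            e.loc[pb, pa] += 1
    total = e.to_numpy()[np.triu_indices(len(parts), 1)].sum()
    denom = sum(sizes[a] * sizes[b]
                for i, a in enumerate(parts) for b in parts[i + 1:])
    conf = pd.DataFrame(0.0, index=parts, columns=parts)
    if total > 0 and denom > 0:
        for i, a in enumerate(parts):
            for b in parts[i + 1:]:
                expected = total * sizes[a] * sizes[b] / denom
                w = e.loc[a, b] / expected if e.loc[a, b] > 0 else 0.0
                conf.loc[a, b] = conf.loc[b, a] = w
    return PartitionGraph(conf=conf)


def _md_na(pg: PartitionGraph, stage_of) -> float:
    best = 0.0
    for a in pg.nodes:
        for b in pg.nodes:
            if stage_of[a] == "NCI" and stage_of[b] == "AD":
                best = max(best, float(pg.conf.loc[a, b]))
    return best


def prune(pg: PartitionGraph, stage_of) -> PartitionGraph:
    """Keep connections with confidence above twice the NCI-AD maximum.

    When no NCI-AD pair carries any confidence (MD_NA = 0) all positive
    connections are kept: there is no shortcut level to prune against.
    """
    missing = [n for n in pg.nodes if n not in stage_of]
    if missing:
        raise ValueError(f"nodes without a stage: {missing[:5]}")
    md = _md_na(pg, stage_of)
    threshold = PRUNE_MULTIPLIER * md
    arr = pg.conf.to_numpy().copy()
    arr[arr <= threshold] = 0.0
    return PartitionGraph(conf=pd.DataFrame(arr, index=pg.conf.index,
                                            columns=pg.conf.columns))


def intersect(a: PartitionGraph, b: PartitionGraph) -> PartitionGraph:
    """Edges present in both graphs, with the smaller confidence."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("partition graphs have different node sets")
    bb = b.conf.loc[a.conf.index, a.conf.columns]
    arr = np.minimum(a.conf.to_numpy(), bb.to_numpy())
    arr[(a.conf.to_numpy() == 0) | (bb.to_numpy() == 0)] = 0.0
    return PartitionGraph(conf=pd.DataFrame(arr, index=a.conf.index,
                                            columns=a.conf.columns))


def orient(pg: PartitionGraph, stage_of, ranks=STAGE_RANK) -> pd.DataFrame:
    """Direct cross-stage edges along increasing clinical stage.

    Returns an edge table (node_a, node_b, confidence, direction) where
    direction is 'forward' (node_a's stage precedes node_b's) or
    'undirected' for same-stage edges.  Idempotent by construction.
    """
    rows = []
    for a, b, w in pg.edges():
        ra, rb = ranks[stage_of[a]], ranks[stage_of[b]]
        if ra == rb:
            rows.append((a, b, w, "undirected"))
        elif ra < rb:
            rows.append((a, b, w, "forward"))
        else:
            rows.append((b, a, w, "forward"))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence",
                                       "direction"])
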