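"""Genomic-interval operations and epigenome-similarity typing.

Peaks are regions where the ChIP-seq fold-change-over-control exceeds 5
(strict inequality; the boundary value is excluded).  Similarity between two
individuals' genome-wide peak distributions is the interval Jaccard
coefficient, intersection length over union length, matching bedtools
semantics.  Individuals are typed by hierarchically clustering the rows of
the Jaccard matrix: the larger side of the first split is the "typical"
genome-wide distribution, the smaller side "untypical"; when the elbow rule
favours three clusters the typical side is split once more into Typical1 and
Typical2.

All coordinates are BED convention: 0-based, half-open, per chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import pearson

__all__ = [
    "IntervalSet",
    "PeakTrack",
    "peaks_from_track",
    "jaccard",
    "jaccard_matrix",
    "epigenome_typing",
    "chromosome_density",
    "promoter_regions",
    "promoter_density",
    "expression_promoter_correlation",
]

DEFAULT_FC_THRESHOLD = 5.0
PROMOTER_LENGTH = 1000


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Sort and merge an (m, 2) array of half-open intervals."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class IntervalSet:
    """Sorted, merged, half-open genomic intervals keyed by chromosome."""

    intervals: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and (arr[:, 0] >= arr[:, 1]).any():
                raise ValueError(f"interval with start >= end on {chrom}")
            if arr.size and (arr[:, 0] < 0).any():
                raise ValueError(f"negative coordinate on {chrom}")
            merged = _merge_intervals(arr)
            if merged.size:
                clean[chrom] = merged
        self.intervals = clean

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end)."""
        by_chrom: dict = {}
        for chrom, start, end in records:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.asarray(v) for c, v in by_chrom.items()})

    def chroms(self):
        return sorted(self.intervals)

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.intervals.values()))

    def chrom_length_covered(self, chrom: str) -> int:
        arr = self.intervals.get(chrom)
        return 0 if arr is None else int((arr[:, 1] - arr[:, 0]).sum())

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self.intervals) & set(other.intervals):
            a, b = self.intervals[chrom], other.intervals[chrom]
            i = j = 0
            pieces = []
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    pieces.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if pieces:
                out[chrom] = np.asarray(pieces)
        return IntervalSet(out)

    def intersection_length(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_length()

    def to_records(self):
        for chrom in self.chroms():
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)

    def __len__(self):
        return int(sum(len(a) for a in self.intervals.values()))


@dataclass
class PeakTrack:
    """Per-chromosome step function of fold-change-over-control values."""

    segments: dict  # chrom -> (starts, ends, values), non-overlapping

    def __post_init__(self):
        clean = {}
        for chrom, (starts, ends, values) in self.segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if (starts >= ends).any():
                raise ValueError(f"segment with start >= end on {chrom}")
            if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping segments on {chrom}")
            clean[chrom] = (starts, ends, values)
        self.segments = clean


def peaks_from_track(track: PeakTrack,
                     fc_threshold: float = DEFAULT_FC_THRESHOLD) -> IntervalSet:
    """Regions with fold change strictly above the threshold, merged."""
    out = {}
    for chrom, (starts, ends, values) in track.segments.items():
        keep = values > fc_threshold
        if keep.any():
            out[chrom] = np.column_stack([starts[keep], ends[keep]])
    return IntervalSet(out)


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Interval Jaccard: |a & b| / |a | b|; 0 when the union is empty."""
    inter = a.intersection_length(b)
    union = a.total_length() + b.total_length() - inter
    return inter / union if union > 0 else 0.0


def jaccard_matrix(sets: dict) -> pd.DataFrame:
    """Symmetric Jaccard matrix (unit diagonal) over a mapping id -> IntervalSet."""
    ids = list(sets)
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            mat[i, j] = mat[j, i] = jaccard(sets[a], sets[ids[j]])
    return pd.DataFrame(mat, index=ids, columns=ids)


def _hierarchical_sse(vectors: np.ndarray, dend, k_values):
    """SSE of the flat clustering at each dendrogram cut."""
    from .clustering import cut_k

    sse = {}
    for k in k_values:
        cut = cut_k(dend, k)
        total = 0.0
        for c in range(cut.k):
            idx = [i for i, lab in enumerate(cut.labels.values()) if lab == c]
            pts = vectors[idx]
            total += ((pts - pts.mean(axis=0)) ** 2).sum()
        sse[k] = total
    return sse


def epigenome_typing(jmat: pd.DataFrame, max_k: int = 6):
    """Type individuals as Typical/Untypical (or Typical1/Typical2/Untypical).

    Rows of the Jaccard matrix are the feature vectors (self-similarity entry
    retained); Euclidean distance with group-average linkage.  The larger side
    of the first split is Typical (tie: the side holding the smallest id, with
    a warning).  The elbow rule on the hierarchical-cut SSE selects the
    cluster number k*; when k* = 3 the Typical side is split at its top merge
    into Typical1 (side holding the smallest id) and Typical2.
    """
    from .clustering import average_linkage, first_branch_split, _elbow

    ids = list(jmat.index)
    if len(ids) < 3:
        raise ValueError("epigenome typing requires at least 3 individuals")
    vectors = jmat.to_numpy(dtype=float)
    diff = vectors[:, None, :] - vectors[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    if np.allclose(dist, 0):
        warnings.warn("all individuals identical; typing degenerates to all-Typical",
                      stacklevel=2)
        return pd.Series("Typical", index=ids), 1
    dend = average_linkage(dist, leaf_ids=ids)
    side_a, side_b = first_branch_split(dend)
    if len(side_a) == len(side_b):
        warnings.warn("first split is a tie; side holding the smallest id "
                      "taken as Typical", stacklevel=2)
        typical, untypical = side_a, side_b
    elif len(side_a) > len(side_b):
        typical, untypical = side_a, side_b
    else:
        typical, untypical = side_b, side_a

    ks = [k for k in range(1, min(max_k, len(ids)) + 1)]
    sse = _hierarchical_sse(vectors, dend, ks)
    k_star = _elbow(sse)

    typing = pd.Series("Typical", index=ids)
    typing[list(untypical)] = "Untypical"
    if k_star == 3 and len(typical) >= 2:
        # the typical side is one child of the root; split it at its own top merge
        child_a, child_b = dend.children(dend.root)
        typical_node = child_a if set(dend.members(child_a)) == set(typical) else child_b
        t1, t2 = (dend.members(c) for c in dend.children(typical_node))
        if str(min(t2, key=str)) < str(min(t1, key=str)):
            t1, t2 = t2, t1
        typing[list(t1)] = "Typical1"
        typing[list(t2)] = "Typical2"
    return typing, k_star


def chromosome_density(peaks: IntervalSet, chrom_lengths: dict) -> pd.Series:
    """Per-chromosome peak coverage density in [0, 1]."""
    unknown = set(peaks.intervals) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"peak chromosome(s) not in the length table: {sorted(unknown)}")
    return pd.Series(
        {c: peaks.chrom_length_covered(c) / chrom_lengths[c] for c in chrom_lengths},
        name="density",
    )


def promoter_regions(annotation: pd.DataFrame,
                     upstream: int = PROMOTER_LENGTH,
                     chrom_lengths: dict | None = None) -> dict:
    """Promoter = the 1 kbp upstream of the TSS, strand-aware, clipped.

    ``annotation`` needs columns gene_id, chrom, strand, tss.  Returns a
    mapping gene_id -> (chrom, start, end).
    """
    out = {}
    for row in annotation.itertuples(index=False):
        if row.strand == "+":
            start, end = row.tss - upstream, row.tss
        elif row.strand == "-":
            start, end = row.tss, row.tss + upstream
        else:
            raise ValueError(f"bad strand {row.strand!r} for {row.gene_id}")
        start = max(0, start)
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[row.chrom])
        if start < end:
            out[row.gene_id] = (row.chrom, int(start), int(end))
    return out


def promoter_density(peaks: IntervalSet, promoters: dict,
                     denominator: int = PROMOTER_LENGTH) -> pd.Series:
    """Per-gene promoter marker density: overlap length / 1000 bp.

    The denominator is fixed at the nominal promoter length even for
    promoters clipped at a chromosome boundary.
    """
    dens = {}
    for gene, (chrom, start, end) in promoters.items():
        arr = peaks.intervals.get(chrom)
        if arr is None:
            dens[gene] = 0.0
            continue
        lo = np.minimum(arr[:, 1], end)
        hi = np.maximum(arr[:, 0], start)
        dens[gene] = float(np.clip(lo - hi, 0, None).sum()) / denominator
    return pd.Series(dens, name="promoter_density")


def expression_promoter_correlation(tpm: pd.DataFrame,
                                    densities: pd.DataFrame,
                                    individuals,
                                    genes) -> pd.Series:
    """Per-gene Pearson r between TPM and promoter marker density.

    ``densities`` is genes x individuals.  Genes whose promoters carry no
    mark in any individual have constant density and give r = 0 by
    convention, producing the histogram spike at zero correlation.
    """
    individuals = list(individuals)
    if len(individuals) < 3:
        raise ValueError("correlation requires at least 3 individuals")
    out = {}
    for g in genes:
        out[g] = pearson(tpm.loc[g, individuals].to_numpy(),
                         densities.loc[g, individuals].to_numpy())
    return pd.Series(out, name="expression_promoter_r")
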