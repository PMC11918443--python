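"""Threshold-grid searches for stage-separating gene sets.

A gene set is selected by comparing two (or three) clinical groups with a
per-gene test and keeping genes whose p-value is at or below a threshold;
directional thresholds P_up / P_down apply separately to genes whose mean
TPM is higher / lower in the later group.  Scanning a grid of thresholds
yields a phase diagram whose cells are flagged when hierarchical clustering
of the two groups on the selected genes separates them completely at the
first dendrogram branch.  Unions of sets obtained with different backends
are grown candidate-by-candidate while separation is preserved.

Backends: Welch's t / one-way ANOVA on TPM ("t"/"A"-type thresholds) or on
counts-per-million (the count-based stand-in for "D"-type thresholds); any
callable producing per-gene p-values can be plugged in for real-data runs.
Thresholds are inclusive (p <= P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    average_linkage,
    correlation_distance,
    cut_k,
    enriched_cluster_test,
    first_branch_split,
    kmeans_with_elbow,
)
from .stats_core import (
    anova_oneway_table,
    bh_fdr,
    center_log_expression,
    welch_t_table,
)

__all__ = [
    "GeneSetRecord",
    "PhaseDiagram",
    "StableMembersResult",
    "ADSubgroupResult",
    "pairwise_results",
    "omnibus_results",
    "directional_select",
    "complete_separation",
    "separation_scan",
    "largest_separating_set",
    "most_downregulated_separating_set",
    "stable_members",
    "union_with_separation",
    "ad_subgroup_discovery",
]

PAIRWISE_BACKENDS = ("welch_tpm", "welch_cpm")
OMNIBUS_BACKENDS = ("anova_tpm", "anova_cpm")
DEFAULT_DEVIANT_FACTOR = 0.5


@dataclass
class GeneSetRecord:
    """A named gene set with per-gene direction and construction provenance."""

    name: str
    genes: pd.Index
    direction: pd.Series  # 'up'/'down': higher/lower mean in the later group
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.genes)

    def up_genes(self) -> pd.Index:
        return self.direction.index[self.direction == "up"]

    def down_genes(self) -> pd.Index:
        return self.direction.index[self.direction == "down"]


@dataclass
class PhaseDiagram:
    """Per-cell results of a threshold-grid separation scan."""

    pair: tuple
    backend: str
    cells: pd.DataFrame        # p_up, p_down, n_genes, n_up, n_down, separates
    results: pd.DataFrame      # the per-gene test table used for selection
    cell_sets: dict            # (p_up, p_down) -> gene Index

    def separating_cells(self) -> pd.DataFrame:
        return self.cells[self.cells.separates]


def _expression(cohort, scale: str) -> pd.DataFrame:
    if scale == "tpm":
        return cohort.tpm
    if scale == "cpm":
        return cohort.cpm()
    raise ValueError(f"unknown expression scale {scale!r}")


def pairwise_results(cohort, pair, backend="welch_tpm", genes=None) -> pd.DataFrame:
    """Per-gene two-group test table for an ordered (earlier, later) pair.

    Direction 'up' means higher mean TPM in the later group, 'down' lower.
    Directions always come from mean TPM regardless of the backend's test
    scale.
    """
    g1, g2 = pair
    s1, s2 = cohort.samples_of(g1), cohort.samples_of(g2)
    if not s1 or not s2:
        raise ValueError("both groups must be non-empty")
    genes = cohort.gene_ids if genes is None else pd.Index(genes)
    if callable(backend):
        stat, p = backend(cohort.counts.loc[genes, s1].to_numpy(),
                          cohort.counts.loc[genes, s2].to_numpy())
    else:
        scale = {"welch_tpm": "tpm", "welch_cpm": "cpm"}.get(backend)
        if scale is None:
            raise ValueError(f"unknown pairwise backend {backend!r}")
        mat = _expression(cohort, scale).loc[genes]
        stat, p = welch_t_table(mat[s1].to_numpy(), mat[s2].to_numpy())
    m1 = cohort.tpm.loc[genes, s1].mean(axis=1)
    m2 = cohort.tpm.loc[genes, s2].mean(axis=1)
    return pd.DataFrame({
        "statistic": stat,
        "p_value": p,
        "mean_first": m1.to_numpy(),
        "mean_second": m2.to_numpy(),
        "direction": np.where(m2.to_numpy() >= m1.to_numpy(), "up", "down"),
    }, index=genes)


def omnibus_results(cohort, backend="anova_tpm", genes=None,
                    groups=("NCI", "MCI", "AD")) -> pd.DataFrame:
    """Per-gene omnibus (three-group) test table."""
    genes = cohort.gene_ids if genes is None else pd.Index(genes)
    sample_sets = [cohort.samples_of(g) for g in groups]
    if callable(backend):
        stat, p = backend(*[cohort.counts.loc[genes, s].to_numpy()
                            for s in sample_sets])
    else:
        scale = {"anova_tpm": "tpm", "anova_cpm": "cpm"}.get(backend)
        if scale is None:
            raise ValueError(f"unknown omnibus backend {backend!r}")
        mat = _expression(cohort, scale).loc[genes]
        stat, p = anova_oneway_table([mat[s].to_numpy() for s in sample_sets])
    return pd.DataFrame({"statistic": stat, "p_value": p}, index=genes)


def directional_select(results: pd.DataFrame, p_up: float, p_down: float) -> pd.Index:
    """Genes up in the later group with p <= P_up, plus down with p <= P_down."""
    up = (results.direction == "up") & (results.p_value <= p_up)
    down = (results.direction == "down") & (results.p_value <= p_down)
    return results.index[up | down]


def complete_separation(cohort, genes, samples_a, samples_b):
    """Cluster the two groups' individuals on a gene set; test first-branch purity.

    Returns (separates, (side_a, side_b)).  Fewer than two genes cannot
    define a correlation distance and never separate.
    """
    genes = pd.Index(genes)
    if len(genes) < 2:
        return False, None
    samples = list(samples_a) + list(samples_b)
    x = center_log_expression(cohort.tpm.loc[genes, samples])
    dist = correlation_distance(x.to_numpy())
    dend = average_linkage(dist, leaf_ids=samples)
    side1, side2 = first_branch_split(dend)
    sa, sb = set(samples_a), set(samples_b)
    separates = ({*side1} == sa and {*side2} == sb) or \
                ({*side1} == sb and {*side2} == sa)
    return separates, (side1, side2)


def separation_scan(cohort, pair, p_up_values, p_down_values,
                    backend="welch_tpm", genes=None) -> PhaseDiagram:
    """Phase diagram of complete first-branch separation over a threshold grid."""
    g1, g2 = pair
    s1, s2 = cohort.samples_of(g1), cohort.samples_of(g2)
    results = pairwise_results(cohort, pair, backend=backend, genes=genes)
    rows, cell_sets = [], {}
    for pu in p_up_values:
        for pdn in p_down_values:
            sel = directional_select(results, pu, pdn)
            sep, _ = complete_separation(cohort, sel, s1, s2)
            n_up = int((results.loc[sel, "direction"] == "up").sum())
            rows.append({"p_up": pu, "p_down": pdn, "n_genes": len(sel),
                         "n_up": n_up, "n_down": len(sel) - n_up,
                         "separates": sep})
            cell_sets[(pu, pdn)] = sel
    return PhaseDiagram(pair=tuple(pair), backend=str(backend),
                        cells=pd.DataFrame(rows), results=results,
                        cell_sets=cell_sets)


def _record_from_cell(diagram: PhaseDiagram, row, name: str) -> GeneSetRecord:
    genes = diagram.cell_sets[(row.p_up, row.p_down)]
    return GeneSetRecord(
        name=name,
        genes=genes,
        direction=diagram.results.loc[genes, "direction"],
        provenance={"backend": diagram.backend, "pair": diagram.pair,
                    "p_up": float(row.p_up), "p_down": float(row.p_down),
                    "rule": "separating cell"},
    )


def largest_separating_set(diagram: PhaseDiagram, name="largest"):
    """The separating cell with the most genes (tie: smallest thresholds)."""
    sep = diagram.separating_cells()
    if sep.empty:
        return None
    sep = sep.sort_values(["n_genes", "p_up", "p_down"],
                          ascending=[False, True, True])
    return _record_from_cell(diagram, sep.iloc[0], name)


def most_downregulated_separating_set(diagram: PhaseDiagram, name="most_down"):
    """The separating cell with the most down-regulated genes."""
    sep = diagram.separating_cells()
    if sep.empty:
        return None
    sep = sep.sort_values(["n_down", "p_up", "p_down"],
                          ascending=[False, True, True])
    return _record_from_cell(diagram, sep.iloc[0], name)


@dataclass
class StableMembersResult:
    group: str
    always_in: list
    deviators: list
    memberships: dict  # (backend, P) -> set of the group's members in its cluster


def stable_members(cohort, group: str, scalar_ps, backends=OMNIBUS_BACKENDS,
                   genes=None) -> StableMembersResult:
    """Group members found inside their enriched cluster in every grid cell.

    For each omnibus backend and scalar threshold P, all individuals are
    clustered on the genes with p <= P; the first-branch cluster enriched for
    ``group`` (if any) is identified.  Members of the group inside that
    cluster in every such cell are the stable ("always-in") members; the
    rest of the group are the deviators.
    """
    labels = cohort.stage.to_dict()
    members_of_group = set(cohort.samples_of(group))
    memberships = {}
    for backend in backends:
        results = omnibus_results(cohort, backend=backend, genes=genes)
        for p_threshold in scalar_ps:
            sel = results.index[results.p_value <= p_threshold]
            if len(sel) < 2:
                continue
            samples = list(cohort.sample_ids)
            x = center_log_expression(cohort.tpm.loc[sel, samples])
            dend = average_linkage(correlation_distance(x.to_numpy()),
                                   leaf_ids=samples)
            for side in first_branch_split(dend):
                passes, _ = enriched_cluster_test(side, labels, group)
                if passes:
                    memberships[(str(backend), p_threshold)] = \
                        set(side) & members_of_group
                    break
    if not memberships:
        raise ValueError(f"no grid cell produced a {group}-enriched cluster")
    always = set.intersection(*memberships.values())
    deviators = sorted(members_of_group - always)
    return StableMembersResult(group=group, always_in=sorted(always),
                               deviators=deviators, memberships=memberships)


def union_with_separation(base: GeneSetRecord, candidates: pd.DataFrame,
                          cohort, pair, name="union") -> GeneSetRecord | None:
    """base plus the largest p-ordered candidate prefix that still separates.

    ``candidates`` is a test-result table (rows sorted by ascending p-value,
    with a ``direction`` column).  The prefix length m is scanned from all
    candidates downwards; the first m whose union with the base completely
    separates the pair is returned.  Returns None when even the base alone
    (m = 0) fails.
    """
    g1, g2 = pair
    s1, s2 = cohort.samples_of(g1), cohort.samples_of(g2)
    cand_ids = candidates.index
    for m in range(len(cand_ids), -1, -1):
        genes = base.genes.union(cand_ids[:m])
        sep, _ = complete_separation(cohort, genes, s1, s2)
        if sep:
            direction = pd.concat([base.direction,
                                   candidates["direction"].iloc[:m]])
            direction = direction[~direction.index.duplicated()]
            return GeneSetRecord(
                name=name, genes=genes, direction=direction.loc[genes],
                provenance={"base": base.name, "n_candidates": m,
                            "rule": "largest separating prefix union"},
            )
    return None


@dataclass
class ADSubgroupResult:
    status: str                      # 'ok' or 'insufficient_signal'
    labels: pd.Series | None         # AD individual -> HH / LL / HL
    ca_genes: pd.Index | None        # low in exactly one subgroup
    cb_genes: pd.Index | None        # high in exactly one subgroup
    n_significant: int
    subgroup_cut: pd.Series | None   # AD individual -> dendrogram subgroup 0..2
    k_gene_clusters: int | None


def ad_subgroup_discovery(cohort, na_set: GeneSetRecord, seed: int = 0,
                          fdr: float = 0.1,
                          deviant_factor: float = DEFAULT_DEVIANT_FACTOR,
                          k_range=range(1, 7)) -> ADSubgroupResult:
    """Split AD individuals into the HH / LL / HL subgroups.

    1. cut the AD-only dendrogram (on the NCI-vs-AD separating set) into 3;
    2. one-way ANOVA across the 3 subgroups on the up-in-AD genes, BH FDR;
    3. k-means over the significant genes' standardised AD-expression
       profiles, k by the elbow rule;
    4. type each gene cluster from its sorted per-subgroup centroid
       (m1 <= m2 <= m3): deviant-low ("CA-like") when m2 - m1 exceeds
       ``deviant_factor`` of the range, deviant-high ("CB-like") when
       m3 - m2 does;
    5. label each AD individual from their own mean expression of the CA and
       CB clusters (high/low by two-means split of each score): high in both
       is HH, low in both is LL, high CA with low CB is HL; the rare
       remaining pattern is assigned to the nearest of the three classes.
    """
    ad = cohort.samples_of("AD")
    if len(ad) < 6:
        raise ValueError("AD subgroup discovery requires at least 6 AD individuals")
    x_ad = center_log_expression(cohort.tpm.loc[na_set.genes, ad])
    dend = average_linkage(correlation_distance(x_ad.to_numpy()), leaf_ids=ad)
    cut = cut_k(dend, 3)
    subgroup = pd.Series({s: cut.labels[s] for s in ad}, name="subgroup")

    up = na_set.up_genes()
    groups = [[s for s in ad if subgroup[s] == c] for c in range(3)]
    if min(len(g) for g in groups) < 2:
        return ADSubgroupResult("insufficient_signal", None, None, None, 0,
                                subgroup, None)
    mats = [cohort.tpm.loc[up, g].to_numpy() for g in groups]
    _, p = anova_oneway_table(mats)
    _, reject = bh_fdr(p, alpha=fdr)
    sig = pd.Index(up)[reject]
    if len(sig) < 2:
        return ADSubgroupResult("insufficient_signal", None, None, None,
                                len(sig), subgroup, None)

    profiles = x_ad.loc[sig].to_numpy()
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (profiles - profiles.mean(axis=1, keepdims=True)) / sd
    k_range = [k for k in k_range if k <= len(sig)]
    _, gene_cut, _ = kmeans_with_elbow(z, k_range, seed=seed)

    ca_clusters, cb_clusters = [], []
    for c in range(gene_cut.k):
        idx = [i for i, lab in gene_cut.labels.items() if lab == c]
        centroid = z[idx].mean(axis=0)
        sub_means = np.sort([centroid[[ad.index(s) for s in g]].mean()
                             for g in groups])
        rng_ = sub_means[2] - sub_means[0]
        if rng_ == 0:
            continue
        if sub_means[1] - sub_means[0] > deviant_factor * rng_:
            ca_clusters.append((len(idx), sig[idx]))
        elif sub_means[2] - sub_means[1] > deviant_factor * rng_:
            cb_clusters.append((len(idx), sig[idx]))
    if not ca_clusters or not cb_clusters:
        return ADSubgroupResult("insufficient_signal", None, None, None,
                                len(sig), subgroup, gene_cut.k)
    ca = max(ca_clusters)[1]
    cb = max(cb_clusters)[1]

    zdf = pd.DataFrame(z, index=sig, columns=ad)
    ca_score = zdf.loc[ca].mean(axis=0)
    cb_score = zdf.loc[cb].mean(axis=0)

    def _high(score: pd.Series) -> pd.Series:
        # two-means split of the per-individual score into high/low
        _, cut2, _ = kmeans_with_elbow(score.to_numpy(), [2], seed=seed)
        means = {c: score.to_numpy()[[i for i, l in cut2.labels.items() if l == c]].mean()
                 for c in range(cut2.k)}
        high_cluster = max(means, key=means.get)
        return pd.Series([cut2.labels[i] == high_cluster
                          for i in range(len(score))], index=score.index)

    hi_ca, hi_cb = _high(ca_score), _high(cb_score)
    labels = {}
    for s in ad:
        if hi_ca[s] and hi_cb[s]:
            labels[s] = "HH"
        elif not hi_ca[s] and not hi_cb[s]:
            labels[s] = "LL"
        elif hi_ca[s]:
            labels[s] = "HL"
        else:
            # low CA / high CB is outside the scheme; join the closest class
            labels[s] = "HH" if cb_score[s] >= ca_score[s] else "LL"
    labels = pd.Series(labels).loc[ad]
    return ADSubgroupResult("ok", labels, ca, cb, len(sig), subgroup,
                            gene_cut.k)
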