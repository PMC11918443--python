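"""Per-individual deviation counting and the 12-substage classification.

Each clinical stage is refined by counting, over a grid of pairwise
threshold cells (both test backends, all (P_up, P_down) combinations), how
often an individual falls inside the neighbouring group's enriched
first-branch cluster.  A cell contributes only when both groups' enriched
clusters formed in it.  K-means with the elbow rule then splits individuals
by their deviation-count profiles:

* NCI -> NCI_Typical / NCI_MCI (counts toward MCI);
* MCI_Major (the stable MCI members) -> MCI_Typical / MCI_NCI / MCI_AD from
  the 2-D (toward-NCI, toward-AD) counts, with the omnibus deviators set
  aside as MCI_NCI_AD;
* AD -> the typical AD substages (AD_HH / AD_LL / AD_HL from the expression
  subgroups) or their MCI-proximal variants AD_*_MCI (counts toward MCI).

APOE carriers are classed as APOE2 (any e2, no e4), APOE3 (e3/e3), APOE4
(any e4, no e2); an e2/e4 genotype is outside the scheme and rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import (
    average_linkage,
    correlation_distance,
    enriched_cluster_test,
    first_branch_split,
    kmeans_with_elbow,
)
from .geneset_search import directional_select, pairwise_results
from .stats_core import center_log_expression

__all__ = [
    "DETAILED_SUBSTAGES",
    "STAGE_OF_SUBSTAGE",
    "PURE_SUBSTAGES",
    "BRIDGE_FLANKS",
    "COARSE_OF_DETAILED",
    "DeviationCounts",
    "deviation_counts",
    "classify_nci",
    "classify_mci",
    "classify_ad",
    "apoe_carrier",
    "SubstageAssignment",
    "assemble_assignment",
]

DETAILED_SUBSTAGES = (
    "NCI_Typical", "NCI_MCI",
    "MCI_Typical", "MCI_NCI", "MCI_AD", "MCI_NCI_AD",
    "AD_HH", "AD_HL", "AD_LL", "AD_HH_MCI", "AD_HL_MCI", "AD_LL_MCI",
)

STAGE_OF_SUBSTAGE = {s: s.split("_")[0] for s in DETAILED_SUBSTAGES}

COARSE_OF_DETAILED = {
    "NCI_Typical": "NCI", "NCI_MCI": "NCI",
    "MCI_Typical": "MCI_Major", "MCI_NCI": "MCI_Major", "MCI_AD": "MCI_Major",
    "MCI_NCI_AD": "MCI_NCI_AD",
    "AD_HH": "AD_HH", "AD_HH_MCI": "AD_HH",
    "AD_HL": "AD_HL", "AD_HL_MCI": "AD_HL",
    "AD_LL": "AD_LL", "AD_LL_MCI": "AD_LL",
}

# pure substages carry their own planted expression profile; bridge substages
# sit between the two flanking profiles ("AD" denotes the mean AD profile)
PURE_SUBSTAGES = ("NCI_Typical", "MCI_Typical", "AD_HH", "AD_HL", "AD_LL")
BRIDGE_FLANKS = {
    "NCI_MCI": ("NCI_Typical", "MCI_Typical"),
    "MCI_NCI": ("MCI_Typical", "NCI_Typical"),
    "MCI_AD": ("MCI_Typical", "AD"),
    "MCI_NCI_AD": ("NCI_Typical", "AD"),
    "AD_HH_MCI": ("AD_HH", "MCI_Typical"),
    "AD_HL_MCI": ("AD_HL", "MCI_Typical"),
    "AD_LL_MCI": ("AD_LL", "MCI_Typical"),
}

DEFAULT_GRID_PS = (0.01, 0.02, 0.03, 0.04, 0.05)
NEAR_ZERO_NORM = 0.5  # centroid norm (in count units) regarded as "no deviation"


@dataclass
class DeviationCounts:
    """Deviation counts for an ordered stage pair (earlier, later)."""

    pair: tuple
    first_toward_second: pd.Series   # earlier-group member -> count
    second_toward_first: pd.Series   # later-group member -> count
    n_valid_cells: int


def deviation_counts(cohort, pair, backends=("welch_cpm", "welch_tpm"),
                     ps=DEFAULT_GRID_PS, genes=None) -> DeviationCounts:
    """Count grid cells in which each individual sat in the other group's cluster.

    A cell is valid only when the first-branch split of the two groups'
    individuals yields an enriched cluster for *both* groups.
    """
    g1, g2 = pair
    s1, s2 = cohort.samples_of(g1), cohort.samples_of(g2)
    samples = s1 + s2
    labels = {s: cohort.stage[s] for s in samples}
    c1 = pd.Series(0, index=s1, dtype=int)
    c2 = pd.Series(0, index=s2, dtype=int)
    n_valid = 0
    for backend in backends:
        results = pairwise_results(cohort, pair, backend=backend, genes=genes)
        for pu in ps:
            for pdn in ps:
                sel = directional_select(results, pu, pdn)
                if len(sel) < 2:
                    continue
                x = center_log_expression(cohort.tpm.loc[sel, samples])
                dend = average_linkage(correlation_distance(x.to_numpy()),
                                       leaf_ids=samples)
                sides = first_branch_split(dend)
                enriched = {}
                for side in sides:
                    for g in pair:
                        ok, _ = enriched_cluster_test(side, labels, g)
                        if ok:
                            enriched[g] = set(side)
                if set(enriched) != {g1, g2}:
                    continue
                n_valid += 1
                for s in s1:
                    if s in enriched[g2]:
                        c1[s] += 1
                for s in s2:
                    if s in enriched[g1]:
                        c2[s] += 1
    if n_valid == 0:
        raise ValueError(f"no valid cells for pair {pair}: enriched clusters "
                         "never formed for both groups")
    return DeviationCounts(pair=tuple(pair), first_toward_second=c1,
                           second_toward_first=c2, n_valid_cells=n_valid)


def _typical_and_rest(counts_2d: np.ndarray, cut) -> tuple[set, dict]:
    """Clusters regarded as deviation-free plus the centroids of the rest."""
    centroids = {c: counts_2d[[i for i, lab in cut.labels.items() if lab == c]]
                 .mean(axis=0) for c in range(cut.k)}
    norms = {c: float(np.linalg.norm(v)) for c, v in centroids.items()}
    typical = {c for c, nv in norms.items() if nv < NEAR_ZERO_NORM}
    typical.add(min(norms, key=norms.get))
    return typical, centroids


def classify_nci(toward_mci: pd.Series, seed: int = 0,
                 k_range=(1, 2, 3)) -> pd.Series:
    """Split NCI individuals into NCI_Typical and the MCI-proximal NCI_MCI."""
    ids = list(toward_mci.index)
    pts = toward_mci.to_numpy(dtype=float)[:, None]
    k_range = [k for k in k_range if k <= len(ids)]
    k_star, cut, _ = kmeans_with_elbow(pts, k_range, seed=seed)
    if cut.k == 1:
        if pts.any():
            warnings.warn("elbow selected one cluster; all NCI labelled typical",
                          stacklevel=2)
        return pd.Series("NCI_Typical", index=ids)
    typical, _ = _typical_and_rest(pts, cut)
    lab = {i: "NCI_Typical" if cut.labels[k] in typical else "NCI_MCI"
           for k, i in enumerate(ids)}
    return pd.Series({i: lab[i] for i in ids})


def classify_mci(toward_nci: pd.Series, toward_ad: pd.Series,
                 deviators, seed: int = 0, k_range=range(1, 6)) -> pd.Series:
    """Label MCI individuals with their detailed substage.

    The omnibus deviators become MCI_NCI_AD.  The remaining (MCI_Major)
    individuals are embedded as 2-D (toward-NCI, toward-AD) count points and
    split by k-means with the elbow rule; clusters are labelled from their
    centroids: near the origin -> MCI_Typical, NCI-axis dominant -> MCI_NCI,
    AD-axis dominant -> MCI_AD.
    """
    deviators = set(deviators)
    ids = list(toward_nci.index)
    out = {}
    major = [i for i in ids if i not in deviators]
    for i in deviators:
        out[i] = "MCI_NCI_AD"
    if major:
        pts = np.column_stack([toward_nci[major].to_numpy(dtype=float),
                               toward_ad[major].to_numpy(dtype=float)])
        ks = [k for k in k_range if k <= len(major)]
        _, cut, _ = kmeans_with_elbow(pts, ks, seed=seed)
        if cut.k == 1:
            warnings.warn("elbow selected one cluster; all MCI_Major labelled "
                          "typical", stacklevel=2)
            for i in major:
                out[i] = "MCI_Typical"
        else:
            typical, centroids = _typical_and_rest(pts, cut)
            for pos, i in enumerate(major):
                c = cut.labels[pos]
                if c in typical:
                    out[i] = "MCI_Typical"
                elif centroids[c][0] >= centroids[c][1]:
                    out[i] = "MCI_NCI"
                else:
                    out[i] = "MCI_AD"
    return pd.Series({i: out[i] for i in list(toward_nci.index) + sorted(deviators - set(ids))})


def classify_ad(toward_mci: pd.Series, subgroup_labels: pd.Series,
                seed: int = 0, k_range=range(1, 6)) -> pd.Series:
    """Refine AD subgroups into typical and MCI-proximal detailed substages."""
    ids = list(toward_mci.index)
    missing = set(ids) - set(subgroup_labels.index)
    if missing:
        raise ValueError(f"AD individuals without a subgroup label: {sorted(missing)[:5]}")
    pts = toward_mci.to_numpy(dtype=float)[:, None]
    ks = [k for k in k_range if k <= len(ids)]
    _, cut, _ = kmeans_with_elbow(pts, ks, seed=seed)
    if cut.k == 1:
        if pts.any():
            warnings.warn("elbow selected one cluster; all AD labelled typical",
                          stacklevel=2)
        return pd.Series({i: f"AD_{subgroup_labels[i]}" for i in ids})
    typical, _ = _typical_and_rest(pts, cut)
    out = {}
    for pos, i in enumerate(ids):
        base = f"AD_{subgroup_labels[i]}"
        out[i] = base if cut.labels[pos] in typical else f"{base}_MCI"
    return pd.Series({i: out[i] for i in ids})


_ALLELES = {"e2", "e3", "e4"}


def apoe_carrier(genotype) -> str:
    """APOE carrier class from an allele pair (e2/e3/e4 notation)."""
    a, b = (str(x).lower().replace("ε", "e") for x in genotype)
    if a not in _ALLELES or b not in _ALLELES:
        raise ValueError(f"unknown APOE allele in {genotype!r}")
    alleles = {a, b}
    if {"e2", "e4"} <= alleles:
        raise ValueError("e2/e4 genotype is unclassifiable in this scheme")
    if "e2" in alleles:
        return "APOE2"
    if "e4" in alleles:
        return "APOE4"
    return "APOE3"


@dataclass
class SubstageAssignment:
    """Stage, coarse substage, and detailed substage per individual."""

    table: pd.DataFrame  # columns: stage, coarse, detailed

    def __post_init__(self):
        bad = set(self.table.detailed.unique()) - set(DETAILED_SUBSTAGES)
        if bad:
            raise ValueError(f"unknown detailed substages: {sorted(bad)}")
        mismatch = self.table.detailed.map(STAGE_OF_SUBSTAGE) != self.table.stage
        if mismatch.any():
            raise ValueError(
                f"substage inconsistent with stage for {list(self.table.index[mismatch])[:5]}")

    @property
    def detailed(self) -> pd.Series:
        return self.table.detailed

    @property
    def coarse(self) -> pd.Series:
        return self.table.coarse

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="individual")


def assemble_assignment(stage: pd.Series, nci_labels: pd.Series,
                        mci_labels: pd.Series, ad_labels: pd.Series) -> SubstageAssignment:
    detailed = pd.concat([nci_labels, mci_labels, ad_labels])
    detailed = detailed.loc[stage.index]
    table = pd.DataFrame({
        "stage": stage,
        "coarse": detailed.map(COARSE_OF_DETAILED),
        "detailed": detailed,
    })
    return SubstageAssignment(table=table)
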