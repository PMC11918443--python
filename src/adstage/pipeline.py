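"""End-to-end orchestration: simulate -> filter/tests -> gene sets ->
substages -> epigenome -> networks.

``run_all`` executes the full analysis on a synthetic cohort (or on tables
loaded from disk in real-data mode) with one master seed fanned out to
per-stage seeds by stable hashing of the stage names, and returns a result
bundle carrying every intermediate the downstream evaluations need.  The
module also hosts the benchmark routines used to characterise the method on
planted cohorts: substage recovery, null calibration, epigenome typing and
promoter-coupling recovery, and chain recovery for the trajectory step.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .epigenome import (
    epigenome_typing,
    expression_promoter_correlation,
    jaccard_matrix,
    promoter_density,
    promoter_regions,
)
from .exact_tests import fisher_exact_rxc
from .geneset_search import (
    GeneSetRecord,
    ad_subgroup_discovery,
    largest_separating_set,
    most_downregulated_separating_set,
    omnibus_results,
    separation_scan,
    stable_members,
    union_with_separation,
)
from .io_formats import ExpressionCohort, save_json
from .stats_core import center_log_expression, low_expression_filter
from .substages import (
    apoe_carrier,
    assemble_assignment,
    classify_ad,
    classify_mci,
    classify_nci,
    deviation_counts,
)
from .synthetic import (
    CohortSpec,
    generate_cohort,
    generate_epigenome,
    generate_genotypes,
    generate_progression_chain,
    synthetic_annotation,
)
from .trajectory import embed_and_knn, intersect, orient, partition_connectivity, prune

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_all",
    "stage_seed",
    "substage_recovery",
    "null_type_i_error",
    "null_separation_cells",
    "chain_recovery",
]

SCALAR_PS = (0.01, 0.02, 0.03, 0.04, 0.05)
T_GRID_PS = tuple(round(0.01 * k, 2) for k in range(1, 11))  # wider t-test grid
MNA_P = 0.04  # omnibus ANOVA threshold defining the majority-MCI set


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    spec: CohortSpec | None = None          # synthetic mode
    tpm_path: str | None = None             # real-data mode
    counts_path: str | None = None
    stage_path: str | None = None
    scalar_ps: tuple = SCALAR_PS
    pair_ps: tuple = SCALAR_PS
    t_grid_ps: tuple = T_GRID_PS
    mna_p: float = MNA_P
    pairwise_backends: tuple = ("welch_cpm", "welch_tpm")
    omnibus_backends: tuple = ("anova_cpm", "anova_tpm")
    seed: int = 0
    outdir: str | None = None
    run_epigenome: bool = True
    run_genotypes: bool = True
    run_networks: bool = True

    def validate(self) -> None:
        synthetic = self.spec is not None
        if not synthetic:
            for label, p in (("tpm", self.tpm_path), ("counts", self.counts_path),
                             ("stage", self.stage_path)):
                if p is None:
                    raise ValueError(f"real-data mode requires a {label} path")
                if not Path(p).exists():
                    raise ValueError(f"missing input path for {label}: {p}")
        else:
            self.spec.validate()
        for ps in (self.scalar_ps, self.pair_ps, self.t_grid_ps):
            if any(not 0 < p <= 1 for p in ps):
                raise ValueError("threshold values must lie in (0, 1]")

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in vars(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: ExpressionCohort
    truth: object | None
    kept_genes: pd.Index
    mna_set: GeneSetRecord
    stable: object
    na_sets: dict
    ad_subgroups: object
    assignment: object
    deviations: dict
    epigenome: dict = field(default_factory=dict)
    genotypes: pd.DataFrame | None = None
    fisher_pvalues: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _fail(stage: str, exc: Exception):
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _build_na_sets(cohort, cfg, genes):
    """N-A style separating sets: count-scale and TPM-scale grids plus unions."""
    diag_d = separation_scan(cohort, ("NCI", "AD"), cfg.pair_ps, cfg.pair_ps,
                             backend="welch_cpm", genes=genes)
    diag_t = separation_scan(cohort, ("NCI", "AD"), cfg.t_grid_ps, cfg.t_grid_ps,
                             backend="welch_tpm", genes=genes)
    na_d1 = largest_separating_set(diag_d, name="N-A_D1")
    na_d2 = most_downregulated_separating_set(diag_d, name="N-A_D2")
    na_t = largest_separating_set(diag_t, name="N-A_t")
    sets = {"N-A_D1": na_d1, "N-A_D2": na_d2, "N-A_t": na_t,
            "diagram_d": diag_d, "diagram_t": diag_t}
    if na_t is None:
        return sets
    for union_name, donor in (("N-A1", na_d1), ("N-A2", na_d2)):
        if donor is None:
            continue
        candidates = diag_d.results.loc[donor.genes].sort_values("p_value")
        rec = union_with_separation(na_t, candidates, cohort, ("NCI", "AD"),
                                    name=union_name)
        if rec is not None:
            sets[union_name] = rec
    return sets


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; deterministic for a fixed config and seed."""
    t0 = time.time()
    config.validate()
    seed = config.seed

    # --- cohort -----------------------------------------------------------
    try:
        if config.spec is not None:
            spec = replace(config.spec, seed=stage_seed(seed, "simulate"))
            cohort, truth = generate_cohort(spec)
        else:
            from .io_formats import read_expression_table, read_stage_table
            counts = read_expression_table(config.counts_path, "counts")
            tpm = read_expression_table(config.tpm_path, "tpm")
            stage = read_stage_table(config.stage_path)
            cohort = ExpressionCohort(counts=counts, tpm=tpm, stage=stage)
            truth = None
            spec = None
    except Exception as exc:  # noqa: BLE001
        _fail("cohort", exc)

    # --- filtering and majority-MCI structure -----------------------------
    try:
        kept = low_expression_filter(cohort.tpm, cohort.stage)
        stable = stable_members(cohort, "MCI", config.scalar_ps,
                                backends=config.omnibus_backends, genes=kept)
        mna_results = omnibus_results(cohort, backend="anova_tpm", genes=kept)
        mna_genes = mna_results.index[mna_results.p_value <= config.mna_p]
        mci = cohort.samples_of("MCI")
        rest = [s for s in cohort.sample_ids if s not in set(mci)]
        m_mean = cohort.tpm.loc[mna_genes, mci].mean(axis=1)
        r_mean = cohort.tpm.loc[mna_genes, rest].mean(axis=1)
        mna_set = GeneSetRecord(
            name="M-NA", genes=mna_genes,
            direction=pd.Series(np.where(m_mean >= r_mean, "up", "down"),
                                index=mna_genes),
            provenance={"backend": "anova_tpm", "p": config.mna_p,
                        "rule": "omnibus threshold"},
        )
    except Exception as exc:  # noqa: BLE001
        _fail("mna", exc)

    # --- NCI-vs-AD separating sets and AD subgroups -----------------------
    try:
        na_sets = _build_na_sets(cohort, config, kept)
        primary_na = na_sets.get("N-A1") or na_sets.get("N-A2") or na_sets["N-A_t"]
        if primary_na is None:
            raise ValueError("no NCI-vs-AD separating gene set found")
        ad_res = ad_subgroup_discovery(cohort, primary_na,
                                       seed=stage_seed(seed, "ad_subgroups"))
        if ad_res.status != "ok":
            raise ValueError("AD subgroup discovery found insufficient signal")
    except Exception as exc:  # noqa: BLE001
        _fail("genesets", exc)

    # --- deviation counting and detailed substages ------------------------
    try:
        dev_nm = deviation_counts(cohort, ("NCI", "MCI"),
                                  backends=config.pairwise_backends,
                                  ps=config.pair_ps, genes=kept)
        dev_ma = deviation_counts(cohort, ("MCI", "AD"),
                                  backends=config.pairwise_backends,
                                  ps=config.pair_ps, genes=kept)
        nci_labels = classify_nci(dev_nm.first_toward_second,
                                  seed=stage_seed(seed, "classify_nci"))
        mci_labels = classify_mci(dev_nm.second_toward_first,
                                  dev_ma.first_toward_second,
                                  deviators=stable.deviators,
                                  seed=stage_seed(seed, "classify_mci"))
        ad_labels = classify_ad(dev_ma.second_toward_first, ad_res.labels,
                                seed=stage_seed(seed, "classify_ad"))
        assignment = assemble_assignment(cohort.stage, nci_labels, mci_labels,
                                         ad_labels)
    except Exception as exc:  # noqa: BLE001
        _fail("substages", exc)

    result = PipelineResult(
        config=config, cohort=cohort, truth=truth, kept_genes=kept,
        mna_set=mna_set, stable=stable, na_sets=na_sets, ad_subgroups=ad_res,
        assignment=assignment, deviations={"NCI_MCI": dev_nm, "MCI_AD": dev_ma},
    )

    # --- epigenome --------------------------------------------------------
    if config.run_epigenome and spec is not None:
        try:
            tracks, planted_typing = generate_epigenome(spec, truth)
            jmat = jaccard_matrix(tracks)
            typing, k_star = epigenome_typing(jmat)
            annot = synthetic_annotation(spec)
            promoters = promoter_regions(annot, chrom_lengths=spec.chrom_lengths)
            cb = truth.module.index[truth.module == "cb_like"]
            dens = pd.DataFrame({ind: promoter_density(tracks[ind], promoters)
                                 for ind in cohort.sample_ids}).loc[cb]
            corr = expression_promoter_correlation(cohort.tpm, dens,
                                                   cohort.sample_ids, cb)
            result.epigenome = {"tracks": tracks, "jaccard": jmat,
                                "typing": typing, "k_star": k_star,
                                "planted_typing": planted_typing,
                                "promoter_density": dens,
                                "coupling_r": corr}
        except Exception as exc:  # noqa: BLE001
            _fail("epigenome", exc)

    # --- genotypes and association tests ----------------------------------
    if config.run_genotypes and truth is not None:
        try:
            geno = generate_genotypes(truth, seed=stage_seed(seed, "genotypes"))
            carrier = geno.apply(lambda r: apoe_carrier((r.allele1, r.allele2)),
                                 axis=1)
            result.genotypes = geno.assign(carrier=carrier)
            tab = pd.crosstab(carrier, cohort.stage)
            result.fisher_pvalues["carrier_by_stage"] = fisher_exact_rxc(
                tab.to_numpy())
            coarse = assignment.coarse
            mci_tab = pd.crosstab(carrier[coarse.index[coarse.isin(
                ["MCI_Major", "MCI_NCI_AD"])]],
                coarse[coarse.isin(["MCI_Major", "MCI_NCI_AD"])])
            if mci_tab.shape[0] >= 2 and mci_tab.shape[1] >= 2:
                result.fisher_pvalues["carrier_by_mci_substage"] = \
                    fisher_exact_rxc(mci_tab.to_numpy())
        except Exception as exc:  # noqa: BLE001
            _fail("genotypes", exc)

    # --- adjacency networks -----------------------------------------------
    if config.run_networks:
        try:
            nets = {}
            for level in ("coarse", "detailed"):
                labels = getattr(assignment, level)
                graphs = {}
                for name in ("N-A1", "N-A2"):
                    rec = na_sets.get(name)
                    if rec is None:
                        continue
                    features = mna_set.genes.union(rec.genes)
                    x = center_log_expression(
                        cohort.tpm.loc[features, cohort.sample_ids])
                    knn = embed_and_knn(x)
                    graphs[name] = partition_connectivity(knn, labels)
                stage_of = {node: node.split("_")[0]
                            for node in labels.unique()}
                pruned = {k: prune(g, stage_of) for k, g in graphs.items()}
                if len(pruned) == 2:
                    common = intersect(*pruned.values())
                else:
                    common = next(iter(pruned.values()))
                nets[level] = {"raw": graphs, "pruned": pruned,
                               "common": common,
                               "oriented": orient(common, stage_of)}
            result.networks = nets
        except Exception as exc:  # noqa: BLE001
            _fail("networks", exc)

    result.manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_samples": int(len(cohort.sample_ids)),
        "n_genes": int(len(cohort.gene_ids)),
        "n_kept_genes": int(len(kept)),
        "runtime_s": round(time.time() - t0, 2),
    }

    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.assignment.to_tsv(outdir / "substages.tsv")
    rows = []
    for name in ("N-A_D1", "N-A_D2", "N-A_t", "N-A1", "N-A2"):
        rec = result.na_sets.get(name)
        if rec is None:
            continue
        for g in rec.genes:
            rows.append((name, g, rec.direction[g]))
    for g in result.mna_set.genes:
        rows.append(("M-NA", g, result.mna_set.direction[g]))
    pd.DataFrame(rows, columns=["set", "gene_id", "direction"]).to_csv(
        outdir / "gene_sets.tsv", sep="\t", index=False)
    if result.epigenome:
        result.epigenome["jaccard"].to_csv(outdir / "jaccard.tsv", sep="\t")
        result.epigenome["typing"].to_csv(outdir / "epigenome_typing.tsv",
                                          sep="\t", header=["typing"])
    for level, nets in result.networks.items():
        nets["oriented"].to_csv(outdir / f"network_{level}.tsv", sep="\t",
                                index=False)
    save_json(result.manifest, outdir / "manifest.json")


# ---------------------------------------------------------------------------
# benchmark routines on planted cohorts


def _typing_accuracy(found: pd.Series, planted: pd.Series) -> float:
    """Agreement of recovered and planted epigenome typing.

    The Typical1/Typical2 naming is arbitrary up to a swap, so the better of
    the two label mappings is scored; a two-level recovery (Typical only) is
    scored against the planted typical/untypical dichotomy.
    """
    planted = planted.loc[found.index]
    if set(found.unique()) <= {"Typical", "Untypical"}:
        coarse = planted.replace({"Typical1": "Typical", "Typical2": "Typical"})
        return float((found == coarse).mean())
    swap = {"Typical1": "Typical2", "Typical2": "Typical1"}
    direct = float((found == planted).mean())
    swapped = float((found.replace(swap) == planted).mean())
    return max(direct, swapped)


def substage_recovery(seed: int, spec: CohortSpec | None = None) -> dict:
    """Run the pipeline on a planted cohort and score recovery of the truth."""
    cfg = PipelineConfig(spec=spec or CohortSpec(), seed=seed)
    res = run_all(cfg)
    ari = adjusted_rand_score(res.truth.substage.loc[res.assignment.table.index],
                              res.assignment.detailed)
    out = {"detailed_ari": float(ari)}
    if res.epigenome:
        found = res.epigenome["typing"]
        planted = res.epigenome["planted_typing"]
        out["typing_accuracy"] = _typing_accuracy(found, planted)
        out["binary_typing_accuracy"] = float(
            (found.str.startswith("Typical")
             == planted.loc[found.index].str.startswith("Typical")).mean())
        out["coupling_median_r"] = float(res.epigenome["coupling_r"].median())
    return out


def null_type_i_error(seed: int, n_genes: int = 2500, alpha: float = 0.05) -> dict:
    """Fraction of null genes with p < alpha for each test backend."""
    spec = CohortSpec(n_genes=n_genes,
                      module_sizes={"null": n_genes},
                      effect_log2={}, seed=seed)
    cohort, _ = generate_cohort(spec)
    from .geneset_search import pairwise_results
    rates = {}
    welch = pairwise_results(cohort, ("NCI", "AD"), backend="welch_tpm")
    rates["welch_tpm"] = float((welch.p_value < alpha).mean())
    anova = omnibus_results(cohort, backend="anova_tpm")
    rates["anova_tpm"] = float((anova.p_value < alpha).mean())
    return rates


def null_separation_cells(seed: int, n_genes: int = 800,
                          ps=SCALAR_PS) -> int:
    """Separating cells found after permuting the NCI/AD labels (expect 0)."""
    spec = CohortSpec(n_genes=n_genes, module_sizes={"null": n_genes},
                      effect_log2={}, seed=seed)
    cohort, _ = generate_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    permuted = pd.Series(rng.permutation(cohort.stage.to_numpy()),
                         index=cohort.stage.index)
    shuffled = ExpressionCohort(counts=cohort.counts, tpm=cohort.tpm,
                                stage=permuted)
    diag = separation_scan(shuffled, ("NCI", "AD"), ps, ps,
                           backend="welch_tpm")
    return int(diag.cells.separates.sum())


def chain_recovery(seed: int, n_nodes: int = 6) -> bool:
    """Does prune+intersect recover a planted linear progression chain?"""
    edge_sets = []
    for run in (0, 1):
        x, labels, stage_of = generate_progression_chain(
            n_nodes=n_nodes, seed=stage_seed(seed, f"chain{run}"))
        knn = embed_and_knn(x)
        pg = prune(partition_connectivity(knn, labels), stage_of)
        edge_sets.append(pg)
    common = intersect(*edge_sets)
    names = [f"S{t}" for t in range(n_nodes)]
    wanted = {frozenset((names[t], names[t + 1])) for t in range(n_nodes - 1)}
    return common.edge_set() == wanted
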