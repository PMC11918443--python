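"""Threshold-grid gene-set searches and AD subgroup discovery."""

import numpy as np
import pandas as pd
import pytest

from adstage.geneset_search import (
    GeneSetRecord,
    ad_subgroup_discovery,
    directional_select,
    largest_separating_set,
    most_downregulated_separating_set,
    separation_scan,
    stable_members,
    union_with_separation,
)
from adstage.stats_core import low_expression_filter
from adstage.synthetic import CohortSpec, generate_cohort

PS = (0.01, 0.02, 0.03, 0.04, 0.05)


@pytest.fixture(scope="module")
def kept(planted_cohort):
    _, cohort, _ = planted_cohort
    return low_expression_filter(cohort.tpm, cohort.stage)


@pytest.fixture(scope="module")
def na_diagram(planted_cohort, kept):
    _, cohort, _ = planted_cohort
    return separation_scan(cohort, ("NCI", "AD"), PS, PS,
                           backend="welch_tpm", genes=kept)


class TestDirectionalSelect:
    @pytest.fixture()
    def toy(self):
        return pd.DataFrame({
            "p_value": [0.005, 0.02, 0.2, 0.004, 0.03, 0.6],
            "direction": ["up", "up", "up", "down", "down", "down"],
        }, index=[f"g{i}" for i in range(6)])

    def test_zero_thresholds_give_empty_set(self, toy):
        assert len(directional_select(toy, 0.0, 0.0)) == 0

    def test_unit_thresholds_give_all(self, toy):
        assert len(directional_select(toy, 1.0, 1.0)) == 6

    def test_hand_membership(self, toy):
        sel = set(directional_select(toy, 0.01, 0.05))
        assert sel == {"g0", "g3", "g4"}

    def test_monotone_in_both_thresholds(self, toy):
        small = set(directional_select(toy, 0.01, 0.01))
        big = set(directional_select(toy, 0.05, 0.05))
        assert small <= big


class TestSeparationScan:
    def test_planted_effect_separates(self, na_diagram):
        assert na_diagram.cells.separates.sum() >= 1

    def test_permuted_labels_never_separate(self):
        from adstage.pipeline import null_separation_cells

        assert null_separation_cells(101) == 0
        assert null_separation_cells(102) == 0

    def test_empty_gene_set_is_not_separating(self, planted_cohort, kept):
        _, cohort, _ = planted_cohort
        diag = separation_scan(cohort, ("NCI", "AD"), [1e-300], [1e-300],
                               backend="welch_tpm", genes=kept)
        assert not diag.cells.separates.any()

    def test_sample_order_invariance(self, planted_cohort, kept):
        from adstage.io_formats import ExpressionCohort

        _, cohort, _ = planted_cohort
        perm = list(cohort.sample_ids[::-1])
        shuffled = ExpressionCohort(counts=cohort.counts[perm],
                                    tpm=cohort.tpm[perm],
                                    stage=cohort.stage[perm])
        diag1 = separation_scan(cohort, ("NCI", "AD"), [0.02], [0.02],
                                backend="welch_tpm", genes=kept)
        diag2 = separation_scan(shuffled, ("NCI", "AD"), [0.02], [0.02],
                                backend="welch_tpm", genes=kept)
        assert diag1.cells.separates.equals(diag2.cells.separates)


class TestLargestSeparatingSet:
    def test_picks_maximal_cell(self, na_diagram):
        rec = largest_separating_set(na_diagram)
        assert rec is not None
        assert len(rec) == na_diagram.separating_cells().n_genes.max()

    def test_down_variant_picks_most_down(self, na_diagram):
        rec = most_downregulated_separating_set(na_diagram)
        sep = na_diagram.separating_cells()
        n_down = (rec.direction == "down").sum()
        assert n_down == sep.n_down.max()

    def test_none_when_no_separating_cell(self, planted_cohort, kept):
        _, cohort, _ = planted_cohort
        diag = separation_scan(cohort, ("NCI", "AD"), [1e-300], [1e-300],
                               backend="welch_tpm", genes=kept)
        assert largest_separating_set(diag) is None


class TestStableMembers:
    def test_planted_omnibus_deviators_found(self, planted_cohort, kept):
        _, cohort, truth = planted_cohort
        res = stable_members(cohort, "MCI", PS, genes=kept)
        planted = set(truth.substage[truth.substage == "MCI_NCI_AD"].index)
        assert planted <= set(res.deviators)
        assert set(res.always_in) <= set(cohort.samples_of("MCI"))
        typical = set(truth.substage[truth.substage == "MCI_Typical"].index)
        assert typical <= set(res.always_in)

    def test_no_enriched_cluster_raises(self):
        spec = CohortSpec(n_genes=300, module_sizes={"null": 300},
                          effect_log2={}, seed=77)
        cohort, _ = generate_cohort(spec)
        with pytest.raises(ValueError, match="enriched"):
            stable_members(cohort, "MCI", (0.2, 0.3))


class TestUnionWithSeparation:
    def test_planted_candidates_fully_absorbed(self, planted_cohort, kept,
                                               na_diagram):
        _, cohort, truth = planted_cohort
        base = largest_separating_set(na_diagram, name="base")
        extra = truth.module.index[truth.module == "na_up"][:20]
        extra = pd.Index([g for g in extra if g not in set(base.genes)])
        candidates = na_diagram.results.loc[extra].sort_values("p_value")
        rec = union_with_separation(base, candidates, cohort, ("NCI", "AD"))
        assert rec is not None
        assert set(extra) <= set(rec.genes)

    def test_result_verified_to_separate(self, planted_cohort, na_diagram):
        from adstage.geneset_search import complete_separation

        _, cohort, _ = planted_cohort
        base = largest_separating_set(na_diagram, name="base")
        rec = union_with_separation(base, na_diagram.results.iloc[:0], cohort,
                                    ("NCI", "AD"))
        sep, _ = complete_separation(cohort, rec.genes,
                                     cohort.samples_of("NCI"),
                                     cohort.samples_of("AD"))
        assert sep


class TestADSubgroupDiscovery:
    def test_planted_subgroups_recovered(self, pipeline_result):
        res = pipeline_result
        assert res.ad_subgroups.status == "ok"
        truth = res.truth.substage
        planted = truth[res.ad_subgroups.labels.index].str.replace(
            "_MCI", "", regex=False).str.replace("AD_", "", regex=False)
        assert (res.ad_subgroups.labels == planted).mean() >= 0.9
        # recovered CA/CB gene clusters are dominated by the planted modules
        modules = res.truth.module
        assert (modules[res.ad_subgroups.ca_genes] == "ca_like").mean() > 0.5
        assert (modules[res.ad_subgroups.cb_genes] == "cb_like").mean() > 0.5

    def test_effectless_cohort_has_insufficient_signal(self):
        spec = CohortSpec(n_genes=500, module_sizes={"null": 500},
                          effect_log2={}, seed=13)
        cohort, _ = generate_cohort(spec)
        fake = GeneSetRecord(
            name="noise", genes=cohort.gene_ids[:100],
            direction=pd.Series("up", index=cohort.gene_ids[:100]))
        res = ad_subgroup_discovery(cohort, fake, seed=0)
        assert res.status == "insufficient_signal"

    def test_control_split_has_fewer_significant_genes(self, pipeline_result):
        """Splitting NCI the same way finds far fewer significant genes."""
        from adstage.clustering import (average_linkage, correlation_distance,
                                        cut_k)
        from adstage.stats_core import (anova_oneway_table, bh_fdr,
                                        center_log_expression)

        res = pipeline_result
        cohort = res.cohort
        na = res.na_sets["N-A1"]
        nci = cohort.samples_of("NCI")
        x = center_log_expression(cohort.tpm.loc[na.genes, nci])
        dend = average_linkage(correlation_distance(x.to_numpy()), leaf_ids=nci)
        cut = cut_k(dend, 3)
        groups = [cut.members(c) for c in range(3)]
        if min(len(g) for g in groups) < 2:
            pytest.skip("degenerate NCI split")
        up = na.up_genes()
        _, p = anova_oneway_table([cohort.tpm.loc[up, g].to_numpy()
                                   for g in groups])
        _, rej = bh_fdr(p, alpha=0.1)
        assert rej.sum() < res.ad_subgroups.n_significant / 3
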