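"""Statistical primitives against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adstage.stats_core import (
    anova_oneway,
    anova_oneway_table,
    bh_fdr,
    center_log_expression,
    low_expression_filter,
    pearson,
    size_factors,
    welch_t,
    welch_t_table,
)


class TestCenterLogExpression:
    def test_constant_gene_becomes_zero(self):
        x = center_log_expression(np.full((1, 4), 3.0))
        assert np.allclose(x, 0.0)

    def test_two_sample_hand_value(self):
        # log2(0+1)=0, log2(3+1)=2, mean 1 -> (-1, +1)
        x = center_log_expression(np.array([[0.0, 3.0]]))
        assert np.allclose(x, [[-1.0, 1.0]])

    def test_row_means_zero(self, rng):
        x = center_log_expression(rng.gamma(2.0, 10.0, size=(50, 12)))
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-12)

    def test_dataframe_round_trip(self):
        df = pd.DataFrame([[0.0, 3.0]], index=["g"], columns=["a", "b"])
        out = center_log_expression(df)
        assert list(out.columns) == ["a", "b"]
        assert np.allclose(out.to_numpy(), [[-1.0, 1.0]])


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_clear_shift_is_significant(self):
        _, p = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.01

    def test_matches_scipy(self, rng):
        a = rng.normal(0, 1, (30, 10))
        b = rng.normal(0.2, 2, (30, 12))
        t, p = welch_t_table(a, b)
        ref = sps.ttest_ind(a, b, axis=1, equal_var=False)
        assert np.allclose(np.abs(t), np.abs(ref.statistic), atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        t_obs, p = welch_t(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm, _ = welch_t(perm[:10], perm[10:])
            if abs(t_perm) >= abs(t_obs):
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.02)

    def test_zero_variance_conventions(self):
        t, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            t, p = welch_t([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and np.isinf(t)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([[1.0, 2.0, 3.0]] * 3)
        assert f == 0.0 and p == 1.0

    def test_two_groups_equal_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        f, p = anova_oneway([a, b])
        t_ref = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t_ref.statistic**2, abs=1e-10)
        assert p == pytest.approx(t_ref.pvalue, abs=1e-10)

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = [rng.normal(i * 0.3, 1.0, 8) for i in range(3)]
        f, p = anova_oneway(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_ref = (ssb / 2) / (ssw / (len(allv) - 3))
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(sps.f.sf(f_ref, 2, len(allv) - 3), abs=1e-10)

    def test_vectorised_matches_scipy(self, rng):
        mats = [rng.normal(i, 1, (25, 7)) for i in range(3)]
        f, p = anova_oneway_table(mats)
        ref = sps.f_oneway(*mats, axis=1)
        assert np.allclose(f, ref.statistic, atol=1e-9)
        assert np.allclose(p, ref.pvalue, atol=1e-9)


class TestBH:
    def test_single_p(self):
        q, rej = bh_fdr([0.04], alpha=0.1)
        assert q[0] == pytest.approx(0.04) and rej[0]

    def test_hand_step_up(self):
        q, _ = bh_fdr([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_all_ones_rejects_nothing(self):
        _, rej = bh_fdr(np.ones(10), alpha=0.1)
        assert not rej.any()

    def test_rejections_monotone_in_alpha(self, rng):
        p = rng.uniform(0, 1, 200) ** 2
        _, r1 = bh_fdr(p, alpha=0.05)
        _, r2 = bh_fdr(p, alpha=0.2)
        assert (r2 | ~r1).all()  # r1 subset of r2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSizeFactors:
    def test_identical_samples_have_zero_dispersion(self):
        counts = np.tile([[10], [20], [30]], (1, 4))
        s = size_factors(counts)
        assert np.allclose(s.factors, 1.0) and s.dispersion_ratio == 0.0

    def test_scale_equivariance(self, rng):
        counts = rng.poisson(50, size=(40, 3)) + 1
        doubled = np.hstack([counts, counts[:, :1] * 2])
        s = size_factors(doubled)
        assert s.factors.iloc[3] == pytest.approx(2 * s.factors.iloc[0])

    def test_hand_oracle_four_genes(self):
        counts = np.array([[2, 4, 8], [3, 6, 12], [10, 20, 40], [5, 10, 20]])
        ref = np.exp(np.log(counts).mean(axis=1))
        expected = np.median(counts / ref[:, None], axis=0)
        s = size_factors(counts, quantile=0.5)
        assert np.allclose(s.factors, expected)

    def test_gene_permutation_invariance(self, rng):
        counts = rng.poisson(30, size=(50, 4)) + 1
        s1 = size_factors(counts).factors
        s2 = size_factors(counts[rng.permutation(50)]).factors
        assert np.allclose(s1, s2)

    def test_requires_all_positive_gene(self):
        with pytest.raises(ValueError):
            size_factors(np.array([[0, 1], [1, 0]]))


class TestLowExpressionFilter:
    @pytest.fixture()
    def stage(self):
        return pd.Series(["NCI", "NCI", "MCI", "MCI", "AD", "AD"],
                         index=list("abcdef"))

    def test_gene_low_everywhere_dropped(self, stage):
        tpm = pd.DataFrame([[0.05] * 6], index=["g1"], columns=list("abcdef"))
        assert len(low_expression_filter(tpm, stage)) == 0

    def test_gene_high_in_one_group_kept(self, stage):
        tpm = pd.DataFrame([[0.05, 0.05, 0.2, 0.2, 0.05, 0.05]],
                           index=["g1"], columns=list("abcdef"))
        assert list(low_expression_filter(tpm, stage)) == ["g1"]

    def test_spike_in_dropped_regardless_of_level(self, stage):
        tpm = pd.DataFrame([[50.0] * 6], index=["ERCC-00002"],
                           columns=list("abcdef"))
        assert len(low_expression_filter(tpm, stage)) == 0


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_convention(self):
        assert pearson([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0
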