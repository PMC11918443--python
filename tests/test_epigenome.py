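"""Interval arithmetic, Jaccard similarity, typing, and promoter densities."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from adstage.epigenome import (
    IntervalSet,
    PeakTrack,
    chromosome_density,
    epigenome_typing,
    expression_promoter_correlation,
    jaccard,
    jaccard_matrix,
    peaks_from_track,
    promoter_density,
    promoter_regions,
)


def _track(segs):
    by = {}
    for chrom, s, e, v in segs:
        by.setdefault(chrom, ([], [], []))
        by[chrom][0].append(s)
        by[chrom][1].append(e)
        by[chrom][2].append(v)
    return PeakTrack({c: tuple(np.array(x) for x in t) for c, t in by.items()})


class TestPeaksFromTrack:
    def test_boundary_value_excluded(self):
        peaks = peaks_from_track(_track([("chr1", 0, 10, 5.0)]))
        assert len(peaks) == 0

    def test_threshold_rule(self):
        peaks = peaks_from_track(_track([
            ("chr1", 0, 10, 6.0), ("chr1", 10, 20, 4.0), ("chr1", 20, 30, 7.0)]))
        assert list(peaks.to_records()) == [("chr1", 0, 10), ("chr1", 20, 30)]

    def test_all_below_threshold(self):
        peaks = peaks_from_track(_track([("chr1", 0, 100, 1.0)]))
        assert len(peaks) == 0


class TestJaccard:
    def test_identical_sets(self):
        a = IntervalSet.from_records([("chr1", 0, 100), ("chr2", 50, 80)])
        assert jaccard(a, a) == 1.0

    def test_hand_overlap(self):
        a = IntervalSet.from_records([("chr1", 0, 10)])
        b = IntervalSet.from_records([("chr1", 5, 20)])
        # intersection 5, union 10 + 15 - 5 = 20
        assert jaccard(a, b) == pytest.approx(5 / 20)

    def test_disjoint_chromosomes(self):
        a = IntervalSet.from_records([("chr1", 0, 10)])
        b = IntervalSet.from_records([("chr2", 0, 10)])
        assert jaccard(a, b) == 0.0

    def test_matches_bitmap_oracle_on_toy_genome(self, rng):
        def random_set():
            return IntervalSet.from_records(
                [("toy", int(s), int(s) + int(rng.integers(1, 60)))
                 for s in rng.integers(0, 950, size=12)])

        def bitmap(iv):
            m = np.zeros(1000, dtype=bool)
            for _, s, e in iv.to_records():
                m[s:min(e, 1000)] = True
            return m

        for _ in range(25):
            a, b = random_set(), random_set()
            ma, mb = bitmap(a), bitmap(b)
            inter = (ma & mb).sum()
            union = (ma | mb).sum()
            expected = inter / union if union else 0.0
            assert jaccard(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_bedtools_jaccard(self, tmp_path, rng):
        from adstage.io_formats import write_bed

        a = IntervalSet.from_records(
            [("chr1", int(s), int(s) + 40) for s in rng.integers(0, 5000, 20)])
        b = IntervalSet.from_records(
            [("chr1", int(s), int(s) + 60) for s in rng.integers(0, 5000, 20)])
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a, fa)
        write_bed(b, fb)
        try:
            out = subprocess.run(["bedtools", "jaccard", "-a", fa, "-b", fb],
                                 capture_output=True, text=True, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("bedtools unavailable")
        ref = float(out.stdout.splitlines()[1].split("\t")[2])  # printed rounded
        assert jaccard(a, b) == pytest.approx(ref, abs=1e-6)

    def test_matrix_symmetric_unit_diagonal(self, rng):
        sets = {f"i{k}": IntervalSet.from_records(
            [("chr1", int(s), int(s) + 30) for s in rng.integers(0, 2000, 10)])
            for k in range(5)}
        m = jaccard_matrix(sets)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)


class TestTyping:
    def test_planted_templates_recovered_exactly(self, rng):
        base = [("chr1", 100 * k, 100 * k + 60) for k in range(0, 40, 2)]
        other = [("chr1", 100 * k + 4000, 100 * k + 4060) for k in range(0, 40, 2)]

        def jitter(tmpl):
            return IntervalSet.from_records(
                [(c, max(0, s + int(rng.integers(-5, 6))),
                  e + int(rng.integers(-5, 6))) for c, s, e in tmpl])

        sets = {f"T{i}": jitter(base) for i in range(8)}
        sets.update({f"U{i}": jitter(other) for i in range(3)})
        typing, _ = epigenome_typing(jaccard_matrix(sets))
        assert (typing[[f"T{i}" for i in range(8)]].str.startswith("Typical")).all()
        assert (typing[[f"U{i}" for i in range(3)]] == "Untypical").all()

    def test_identical_individuals_degenerate(self):
        s = IntervalSet.from_records([("chr1", 0, 50)])
        jmat = jaccard_matrix({"a": s, "b": s, "c": s})
        with pytest.warns(UserWarning):
            typing, k = epigenome_typing(jmat)
        assert (typing == "Typical").all() and k == 1

    def test_three_cluster_structure_selects_k3(self):
        # block Jaccard matrix with three clear groups
        blocks = [np.full((4, 4), 0.9), np.full((4, 4), 0.9), np.full((4, 4), 0.9)]
        m = np.full((12, 12), 0.1)
        for i, b in enumerate(blocks):
            m[i * 4:(i + 1) * 4, i * 4:(i + 1) * 4] = b
        np.fill_diagonal(m, 1.0)
        ids = [f"x{i}" for i in range(12)]
        typing, k = epigenome_typing(pd.DataFrame(m, index=ids, columns=ids))
        assert k == 3
        assert set(typing.unique()) == {"Typical1", "Typical2", "Untypical"}


class TestDensities:
    def test_chromosome_density_extremes(self):
        full = IntervalSet.from_records([("chr1", 0, 1000)])
        half = IntervalSet.from_records([("chr2", 0, 500)])
        dens = chromosome_density(
            IntervalSet({**full.intervals, **half.intervals}),
            {"chr1": 1000, "chr2": 1000, "chr3": 1000})
        assert dens["chr1"] == 1.0 and dens["chr2"] == 0.5 and dens["chr3"] == 0.0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            chromosome_density(IntervalSet.from_records([("chrX", 0, 10)]),
                               {"chr1": 1000})

    def test_promoter_regions_strand_and_clipping(self):
        annot = pd.DataFrame({
            "gene_id": ["plus", "minus", "edge"],
            "chrom": ["chr1"] * 3,
            "strand": ["+", "-", "+"],
            "tss": [5000, 5000, 400],
        })
        regions = promoter_regions(annot)
        assert regions["plus"] == ("chr1", 4000, 5000)
        assert regions["minus"] == ("chr1", 5000, 6000)
        assert regions["edge"] == ("chr1", 0, 400)

    def test_promoter_density_fixed_denominator(self):
        peaks = IntervalSet.from_records([("chr1", 4000, 5000), ("chr1", 7500, 8000)])
        promoters = {"full": ("chr1", 4000, 5000), "half": ("chr1", 7000, 8000),
                     "none": ("chr1", 9000, 10000)}
        dens = promoter_density(peaks, promoters)
        assert dens["full"] == 1.0 and dens["half"] == 0.5 and dens["none"] == 0.0


class TestExpressionPromoterCorrelation:
    def test_no_mark_genes_have_zero_correlation(self, rng):
        inds = [f"i{k}" for k in range(6)]
        tpm = pd.DataFrame(rng.gamma(2, 10, (3, 6)),
                           index=["g0", "g1", "g2"], columns=inds)
        dens = pd.DataFrame(0.0, index=tpm.index, columns=inds)
        r = expression_promoter_correlation(tpm, dens, inds, tpm.index)
        assert (r == 0.0).all()

    def test_anti_coupled_genes(self):
        inds = [f"i{k}" for k in range(5)]
        expr = np.array([10.0, 20, 30, 40, 50])
        tpm = pd.DataFrame([expr], index=["g"], columns=inds)
        dens = pd.DataFrame([1.0 - expr / 100], index=["g"], columns=inds)
        r = expression_promoter_correlation(tpm, dens, inds, ["g"])
        assert r["g"] == pytest.approx(-1.0)

    def test_requires_three_individuals(self):
        tpm = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            expression_promoter_correlation(tpm, tpm, ["a", "b"], ["g"])
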