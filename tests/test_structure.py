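import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from isoscribe.core import ExonChain, GenomicInterval, TranscriptModel
from isoscribe.structure import (
    end_overlap_stats,
    intergenic_proximity_test,
    nearest_gene_distance,
    rank_sum_test,
    shuffle_intervals,
)
from oracles import oracle_exact_ranksum_p, oracle_nearest


def _model(mid, exons, strand="+"):
    return TranscriptModel(mid, "chr1", strand, ExonChain(exons), 3, "L")


class TestEndOverlap:
    def test_exact_tss_counted(self):
        m = _model("m", [(1000, 1500)])
        summary, _ = end_overlap_stats([m], [("ref", [("chr1", "+", 1000)])], window=0)
        assert summary.iloc[0]["fraction_tss_overlap"] == 1.0

    def test_101_bp_away_not_counted_at_window_100(self):
        m = _model("m", [(1101, 1500)])
        summary, _ = end_overlap_stats([m], [("ref", [("chr1", "+", 1000)])], window=100)
        assert summary.iloc[0]["fraction_tss_overlap"] == 0.0

    def test_matched_reference_offsets_are_signed_downstream(self):
        m_plus = _model("m1", [(1200, 1500)], "+")
        m_minus = TranscriptModel("m2", "chr1", "-", ExonChain([(1000, 1300)]), 3, "L")
        _, matched = end_overlap_stats(
            [m_plus, m_minus],
            [("ref", [])],
            matched_ref_ends={"m1": (1000, 1600), "m2": (1500, 900)},
        )
        tab = matched.set_index("model_id")
        assert tab.loc["m1", "tss_offset"] == 200  # downstream on +
        assert tab.loc["m2", "tss_offset"] == 200  # 1300 vs 1500 on '-': downstream
        assert bool(tab.loc["m1", "tss_within"])

    def test_empty_reference_set_is_missing_not_error(self):
        summary, _ = end_overlap_stats([_model("m", [(0, 10)])], [("empty", [])])
        assert np.isnan(summary.iloc[0]["fraction_tss_overlap"])


class TestShuffle:
    GENOME = {"chr1": 100_000, "chr2": 50_000}

    def test_deterministic_and_length_preserving(self):
        ivs = [GenomicInterval("chr1", 100, 600), GenomicInterval("chr2", 0, 2000)]
        a = shuffle_intervals(ivs, self.GENOME, seed=3)
        b = shuffle_intervals(ivs, self.GENOME, seed=3)
        assert a == b
        assert [len(x) for x in a] == [500, 2000]

    def test_forced_placement_into_single_gap(self):
        genome = {"chr1": 1000}
        excluded = [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 500, 1000)]
        (placed,) = shuffle_intervals(
            [GenomicInterval("chr1", 0, 100)], genome, excluded, seed=0, same_chrom=True
        )
        assert (placed.start, placed.end) == (400, 500)

    def test_never_overlaps_exclusions(self):
        rng_seed = 5
        excluded = [GenomicInterval("chr1", 10_000, 60_000)]
        placed = shuffle_intervals(
            [GenomicInterval("chr1", 0, 1000)] * 200, self.GENOME, excluded, seed=rng_seed
        )
        for iv in placed:
            assert not (iv.chrom == "chr1" and iv.start < 60_000 and 10_000 < iv.end)

    def test_unplaceable_interval_errors(self):
        with pytest.raises(RuntimeError, match="could not place"):
            shuffle_intervals(
                [GenomicInterval("chr1", 0, 99_999)],
                self.GENOME,
                [GenomicInterval("chr1", 40_000, 60_000), GenomicInterval("chr2", 0, 50_000)],
                seed=1,
                max_tries=200,
            )

    def test_placement_frequencies_length_proportional(self):
        placed = shuffle_intervals(
            [GenomicInterval("chr1", 0, 100)] * 1000, self.GENOME, seed=11
        )
        n1 = sum(1 for iv in placed if iv.chrom == "chr1")
        lo, hi = sps.binom.interval(0.99, 1000, 100_000 / 150_000)
        assert lo <= n1 <= hi


class TestNearestDistance:
    GENES = [
        GenomicInterval("chr1", 1000, 2000),
        GenomicInterval("chr1", 5000, 6000),
        GenomicInterval("chr2", 0, 100),
    ]

    def test_overlap_is_zero(self):
        d = nearest_gene_distance([GenomicInterval("chr1", 1500, 1600)], self.GENES)
        assert d[0] == 0

    def test_between_two_genes_takes_minimum(self):
        iv = GenomicInterval("chr1", 2500, 2600)  # 500 gap left, 2400 right
        assert nearest_gene_distance([iv], self.GENES)[0] == 501

    def test_bookended_is_one(self):
        assert nearest_gene_distance([GenomicInterval("chr1", 2000, 2100)], self.GENES)[0] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        genes = [
            GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 50_000, size=12)
        ]
        ivs = [
            GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 50_000, size=30)
        ]
        assert list(nearest_gene_distance(ivs, genes)) == oracle_nearest(ivs, genes)

    def test_agrees_with_bedtools_closest(self, tmp_path):
        if shutil.which("bedtools") is None:
            pytest.fail("bedtools binary expected on PATH")
        rng = np.random.default_rng(7)
        genes = sorted(
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 800)))
            for s in rng.integers(0, 80_000, size=10)
        )
        ivs = sorted(
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 80_000, size=20)
        )
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        a.write_text("".join(f"chr1\t{i.start}\t{i.end}\n" for i in ivs))
        b.write_text("".join(f"chr1\t{g.start}\t{g.end}\n" for g in genes))
        res = subprocess.run(
            ["bedtools", "closest", "-a", a, "-b", b, "-d", "-t", "first"],
            capture_output=True,
            text=True,
            check=True,
        )
        bed_d = [int(line.split("\t")[-1]) for line in res.stdout.strip().split("\n")]
        assert list(nearest_gene_distance(ivs, genes)) == bed_d


class TestRankSum:
    def test_complete_separation(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.U == 0 and res.method == "exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-9)  # 2/C(6,3)*... two-sided

    def test_identical_samples_p_one(self):
        res = rank_sum_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_u_complementarity(self):
        x, y = [1.5, 3.2, 9.9, 4.4], [2.2, 8.8, 0.1]
        rx = rank_sum_test(x, y)
        ry = rank_sum_test(y, x)
        assert rx.U + ry.U == len(x) * len(y)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = rank_sum_test(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(oracle_exact_ranksum_p(x, y), abs=1e-12)
        scipy_p = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert res.p_value == pytest.approx(scipy_p, abs=1e-9)

    def test_large_sample_near_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(0.6, size=35)
        res = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert res.method == "normal_approx"
        assert res.p_value == pytest.approx(ref, rel=1e-6)


def test_intergenic_proximity_pipeline_runs():
    genes = [GenomicInterval("chr1", s, s + 2000) for s in range(0, 80_000, 20_000)]
    intergenic = [GenomicInterval("chr1", s + 2500, s + 2800) for s in range(0, 80_000, 20_000)]
    out = intergenic_proximity_test(intergenic, genes, {"chr1": 100_000}, seed=4)
    assert out["n_observed"] == len(intergenic)
    assert 0 <= out["p_value"] <= 1
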