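import numpy as np
import pytest

from isoscribe.builder import (
    BuildStats,
    ReadCluster,
    absorbable,
    assign_loci,
    build_transcripts,
    cluster_alignments,
    collapse_models,
    consensus_model,
)
from isoscribe.core import AlignedRead, ExonChain, ToleranceSet, TranscriptModel
from oracles import oracle_collapse


def _read(rid, exons, strand="+", chrom="chr1"):
    return AlignedRead(rid, "s1", chrom, strand, ExonChain(exons))


def _model(mid, exons, support=1, strand="+", chrom="chr1", locus="L1"):
    return TranscriptModel(mid, chrom, strand, ExonChain(exons), support, locus)


class TestClustering:
    def test_three_identical_reads_form_one_cluster(self):
        reads = [_read(f"r{i}", [(100, 200), (300, 400)]) for i in range(3)]
        clusters = cluster_alignments(reads)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_deviant_boundary_beyond_tolerance_breaks_threshold(self):
        # two reads agree; the third's intron start is 25 bp off (tol 20),
        # so a 2-read cluster remains and nothing reaches the size-3 floor
        reads = [
            _read("r1", [(100, 200), (300, 400)]),
            _read("r2", [(100, 200), (300, 400)]),
            _read("r3", [(100, 225), (300, 400)]),
        ]
        assert cluster_alignments(reads) == []

    def test_single_exon_terminal_tolerance(self):
        base = [_read(f"r{i}", [(1000, 1500)]) for i in range(3)]
        near = [_read("r3", [(1050, 1550)])]  # within 60 bp both ends
        far = [_read("r4", [(1070, 1570)])]  # beyond 60 bp
        clusters = cluster_alignments(base + near + far)
        assert [c.size for c in clusters] == [4]

    def test_jittered_reads_from_one_transcript_yield_one_cluster(self):
        # jitter truncated at half the 20 bp tolerance: any two reads are
        # then pairwise compatible (triangle inequality), so exactly one
        # cluster must emerge regardless of scan order
        rng = np.random.default_rng(0)
        true = [(1000, 1180), (2000, 2150), (3000, 3120), (4000, 4200)]
        reads = []
        for i in range(100):
            exons = [
                (int(s + np.clip(rng.normal(0, 5), -10, 10)), int(e + np.clip(rng.normal(0, 5), -10, 10)))
                for s, e in true
            ]
            reads.append(_read(f"r{i}", exons))
        clusters = cluster_alignments(reads)
        assert len(clusters) == 1 and clusters[0].size == 100
        # brute-force pairwise-compatibility oracle: all reads mutually
        # within tolerance of each other
        for a in reads:
            for b in reads:
                assert all(
                    abs(x0 - y0) <= 20 and abs(x1 - y1) <= 20
                    for (x0, x1), (y0, y1) in zip(a.chain.introns, b.chain.introns)
                )

    def test_order_invariance(self, default_dataset):
        reads = list(default_dataset.reads[:2000])
        a = cluster_alignments(reads)
        rng = np.random.default_rng(1)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        b = cluster_alignments(shuffled)
        key = lambda c: (c.chrom, c.strand, sorted(m.read_id for m in c.members))
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestConsensus:
    def _cluster(self, chains, strand="+"):
        return ReadCluster(
            [_read(f"r{i}", ex, strand) for i, ex in enumerate(chains)], "chr1", strand
        )

    def test_median_odd(self):
        chains = [[(s, 200), (300, 400)] for s in (100, 102, 104)]
        m = consensus_model(self._cluster(chains))
        assert m.chain.start == 102

    def test_median_even_takes_lower(self):
        chains = [[(s, 200), (300, 400)] for s in (100, 102)]
        m = consensus_model(self._cluster(chains))
        assert m.chain.start == 100

    def test_median_of_jittered_boundary_near_truth(self):
        rng = np.random.default_rng(42)
        chains = []
        for _ in range(101):
            b = int(round(500 + rng.normal(0, 3)))
            chains.append([(100, b), (600, 700)])
        m = consensus_model(self._cluster(chains))
        assert abs(m.chain.exons[0][1] - 500) <= 1

    def test_support_equals_cluster_size(self):
        chains = [[(100, 200)]] * 5
        m = consensus_model(self._cluster(chains))
        assert m.support == 5


class TestLoci:
    def test_nearby_3prime_ends_share_locus(self):
        a = _model("a", [(0, 1000)])
        b = _model("b", [(500, 1050)])
        assign_loci([a, b])
        assert a.locus_id == b.locus_id

    def test_opposite_strands_never_share(self):
        a = _model("a", [(0, 1000)], strand="+")
        b = _model("b", [(0, 1000)], strand="-")
        assign_loci([a, b])
        assert a.locus_id != b.locus_id

    def test_transitive_chain_is_one_component(self):
        # 3' ends at 1000, 1090, 1180: consecutive gaps <= 100 but extremes 180 apart
        models = [_model(str(i), [(0, 1000 + 90 * i)]) for i in range(3)]
        assign_loci(models)
        assert len({m.locus_id for m in models}) == 1
        # union-find oracle over the pairwise relation
        parent = list(range(3))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(3):
            for j in range(3):
                if abs(models[i].tes - models[j].tes) <= 100:
                    parent[find(i)] = find(j)
        assert len({find(i) for i in range(3)}) == 1


class TestCollapse:
    def test_terminal_fragment_absorbed_with_support_transfer(self):
        b = _model("b", [(0, 100), (1000, 1100), (2000, 2100), (3000, 3100)], support=5)
        a = _model("a", [(1800, 2100), (3000, 3100)], support=3)  # 5' end 800 bp into b
        out = collapse_models([a, b])
        assert len(out) == 1 and out[0].model_id == "b" and out[0].support == 8

    def test_3prime_offset_beyond_tolerance_blocks_collapse(self):
        b = _model("b", [(0, 100), (1000, 1100)], support=5)
        a = _model("a", [(0, 100), (1000, 1250)], support=3)  # 3' ends 150 apart
        assert not absorbable(a, b, ToleranceSet())
        assert len(collapse_models([a, b])) == 2

    def test_minus_strand_fragment_uses_genomic_head(self):
        b = _model("b", [(0, 100), (1000, 1100), (2000, 2100)], support=5, strand="-")
        a = _model("a", [(0, 100), (1000, 1080)], support=3, strand="-")
        assert absorbable(a, b, ToleranceSet())

    def test_output_is_absorption_free(self):
        models = _random_locus(np.random.default_rng(7))
        out = collapse_models(models, ToleranceSet())
        tol = ToleranceSet()
        for a in out:
            for b in out:
                if a is not b:
                    assert not absorbable(a, b, tol)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        models = _random_locus(rng)
        import copy

        mine = collapse_models(copy.deepcopy(models), ToleranceSet())
        ref = oracle_collapse(copy.deepcopy(models), ToleranceSet())
        assert sorted(m.chain.exons for m in mine) == sorted(m.chain.exons for m in ref)
        assert sum(m.support for m in mine) == sum(m.support for m in models)


def _random_locus(rng, n_models=10):
    """Random fragments/variants of a shared 4-intron backbone in one locus."""
    bounds = sorted(rng.choice(np.arange(100, 5000, 10), size=10, replace=False))
    exons = [(bounds[i], bounds[i + 1]) for i in range(0, 10, 2)]
    models = []
    for i in range(n_models):
        k = int(rng.integers(0, len(exons)))  # drop k 5'-most exons
        sub = [list(e) for e in exons[k:]]
        sub[0][0] += int(rng.integers(0, 40))  # truncate into first kept exon
        for e in sub[:-1]:
            e[1] += int(rng.integers(-3, 4))
        sub[-1][1] += int(rng.integers(-30, 31))
        try:
            chain = ExonChain([tuple(e) for e in sub])
        except ValueError:
            continue
        models.append(
            TranscriptModel(f"m{i}", "chr1", "+", chain, int(rng.integers(3, 50)), "L1")
        )
    return models


class TestEndToEnd:
    def test_support_conservation_and_recovery(self, default_dataset):
        ds = default_dataset
        models, stats = build_transcripts(ds.reads)
        assert sum(m.support for m in models) == stats.reads_in_emitted_clusters
        assert stats.reads_in_emitted_clusters <= len(ds.reads)

    def test_every_supported_transcript_recovered_exactly_once(self, default_dataset):
        from isoscribe import evaluate

        ds = default_dataset
        models, _ = build_transcripts(ds.reads)
        rec = evaluate.isoform_recovery(models, ds.full_annotation, ds.read_truth)
        assert rec["recovery_rate_pct"] == 100.0
        assert rec["n_duplicated"] == 0
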