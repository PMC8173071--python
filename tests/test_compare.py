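import numpy as np
import pytest

from isoscribe.compare import (
    AnnotationIndex,
    ClassCode,
    accuracy_metrics,
    assign_class_code,
    categorize,
    classify_models,
    filter_single_exon,
)
from isoscribe.core import ExonChain, ReferenceTranscript, TranscriptModel
from oracles import oracle_class_code


def _ref(tid, exons, strand="+", chrom="chr1", gene=None, biotype="protein_coding"):
    return ReferenceTranscript(tid, gene or f"g_{tid}", chrom, strand, ExonChain(exons), biotype)


def _model(mid, exons, strand="+", chrom="chr1", support=3, locus=""):
    return TranscriptModel(mid, chrom, strand, ExonChain(exons), support, locus)


class TestClassCodes:
    def test_exact_match_ignores_terminal_ends(self):
        ref = _ref("t1", [(100, 200), (300, 400), (500, 600)])
        q = _model("m", [(150, 200), (300, 400), (500, 650)])  # shorter first exon
        cc = assign_class_code(q, AnnotationIndex([ref]))
        assert cc.code == "=" and cc.matched_ref_transcript == "t1"

    def test_single_exon_inside_intron_is_i(self):
        ref = _ref("t1", [(100, 200), (900, 1000)])
        q = _model("m", [(300, 500)])
        assert assign_class_code(q, AnnotationIndex([ref])).code == "i"

    def test_missing_chromosome_is_u(self):
        ref = _ref("t1", [(100, 200), (300, 400)])
        q = _model("m", [(100, 200), (300, 400)], chrom="chrX")
        assert assign_class_code(q, AnnotationIndex([ref])).code == "u"

    @pytest.mark.parametrize("seed", range(6))
    def test_random_queries_match_exhaustive_oracle(self, seed):
        refs, queries = _random_instance(np.random.default_rng(seed))
        index = AnnotationIndex(refs)
        for q in queries:
            assert assign_class_code(q, index).code == oracle_class_code(q, refs)


def _random_instance(rng, n_refs=6, n_queries=50):
    """A toy annotation plus random queries spanning every code's regime."""
    refs = []
    for i in range(n_refs):
        start = int(rng.integers(0, 20000))
        n_ex = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(np.arange(start, start + 4000, 10), 2 * n_ex, replace=False))
        exons = [(int(bounds[j]), int(bounds[j + 1])) for j in range(0, 2 * n_ex, 2)]
        strand = "+" if rng.random() < 0.5 else "-"
        refs.append(_ref(f"t{i}", exons, strand))
    queries = []
    for i in range(n_queries):
        r = refs[int(rng.integers(len(refs)))]
        mode = rng.random()
        if mode < 0.35:  # perturbed copy / fragment of a reference
            exons = [list(e) for e in r.chain.exons]
            if len(exons) > 1 and rng.random() < 0.5:
                exons = exons[int(rng.integers(0, len(exons))):]
            exons[0][0] += int(rng.integers(-200, 200))
            exons[-1][1] += int(rng.integers(-200, 200))
            strand = r.strand
        elif mode < 0.55:  # random mono-exon near the reference
            s = int(r.chain.start + rng.integers(-3000, 3000))
            exons = [[s, s + int(rng.integers(50, 600))]]
            strand = r.strand if rng.random() < 0.7 else ("-" if r.strand == "+" else "+")
        else:  # random multi-exon structure in the area
            s = int(r.chain.start + rng.integers(-3000, 3000))
            bounds = np.sort(rng.choice(np.arange(max(0, s), max(0, s) + 3000, 7), 6, replace=False))
            exons = [[int(bounds[j]), int(bounds[j + 1])] for j in range(0, 6, 2)]
            strand = "+" if rng.random() < 0.5 else "-"
        try:
            chain = ExonChain([tuple(e) for e in exons])
        except ValueError:
            continue
        queries.append(TranscriptModel(f"q{i}", "chr1", strand, chain, 3, ""))
    return refs, queries


class TestCategorize:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ({"ens": "=", "ncbi": "j"}, "known_isoform"),
            ({"ens": "u", "ncbi": "u"}, "novel_locus"),
            ({"ens": "e", "ncbi": "p"}, "artifact"),
            ({"ens": "c"}, "novel_isoform"),
            ({"ens": "x", "ncbi": "s"}, "novel_locus"),
        ],
    )
    def test_category_mapping(self, codes, expected):
        assert categorize({k: ClassCode(v) for k, v in codes.items()}) == expected

    def test_empty_codes_error(self):
        with pytest.raises(ValueError):
            categorize({})

    def test_partition_property(self, default_dataset):
        from isoscribe.builder import build_transcripts

        ds = default_dataset
        models, _ = build_transcripts(ds.reads)
        cls = classify_models(models, {"public": ds.public_reference})
        assert len(cls) == len(models)
        assert set(cls["category"]) <= {
            "known_isoform",
            "novel_isoform",
            "novel_locus",
            "artifact",
        }


class TestSingleExonFilter:
    def _ann(self):
        return {
            "ens": [
                _ref("pc", [(100, 500), (900, 1200)], biotype="protein_coding"),
                _ref("nc", [(5000, 5400)], biotype="lncRNA"),
            ]
        }

    def test_low_support_coding_overlap_retained(self):
        m = _model("m", [(150, 300)], support=3)
        retained, _ = filter_single_exon([m], self._ann())
        assert retained == [m]

    def test_intronic_below_threshold_removed(self):
        m = _model("m", [(600, 800)], support=99)
        retained, removed = filter_single_exon([m], self._ann())
        assert retained == [] and removed["single_exon_no_coding_overlap"] == 1

    def test_intergenic_at_support_threshold_retained(self):
        m = _model("m", [(9000, 9400)], support=100)
        retained, _ = filter_single_exon([m], self._ann())
        assert retained == [m]

    def test_noncoding_overlap_does_not_rescue(self):
        m = _model("m", [(5100, 5200)], support=3)
        assert filter_single_exon([m], self._ann())[0] == []

    def test_multi_exon_always_kept(self):
        m = _model("m", [(600, 700), (750, 800)], support=3)
        assert filter_single_exon([m], self._ann())[0] == [m]


class TestAccuracyMetrics:
    def test_identity_gives_100_everywhere(self):
        refs = [
            _ref("t1", [(100, 200), (300, 400), (500, 600)], gene="g1"),
            _ref("t2", [(1000, 1100), (1300, 1400)], gene="g2"),
        ]
        preds = [
            _model(f"m{i}", r.chain.exons, r.strand, locus=f"L{i}")
            for i, r in enumerate(refs)
        ]
        df = accuracy_metrics(preds, refs).set_index("level")
        assert (df["sensitivity"] == 100).all() and (df["precision"] == 100).all()
        assert df.attrs["missed_exons"][0] == 0
        assert df.attrs["novel_introns"][0] == 0

    def test_spurious_extra_model_costs_intron_precision(self):
        refs = [_ref("t1", [(100, 200), (300, 400), (500, 600)], gene="g1")]
        preds = [
            _model("m1", [(100, 200), (300, 400), (500, 600)], locus="L1"),
            _model("m2", [(5000, 5100), (5300, 5400)], locus="L2"),
        ]
        df = accuracy_metrics(preds, refs).set_index("level")
        assert df.loc["intron", "sensitivity"] == 100
        assert df.loc["intron", "precision"] == pytest.approx(100 * 2 / 3)
        assert df.attrs["novel_introns"] == (1, 3)

    def test_terminal_exons_match_on_internal_boundary_only(self):
        refs = [_ref("t1", [(100, 200), (300, 400), (500, 600)], gene="g1")]
        preds = [_model("m1", [(150, 200), (300, 400), (500, 650)], locus="L1")]
        df = accuracy_metrics(preds, refs).set_index("level")
        assert df.loc["exon", "sensitivity"] == 100
        assert df.loc["transcript", "sensitivity"] == 100

    def test_toy_counts_match_set_comparison_oracle(self):
        rng = np.random.default_rng(3)
        refs, _ = _random_instance(rng, n_refs=8, n_queries=0)
        refs = [r for r in refs if len(r.chain) > 1]
        preds = [
            _model(f"m{i}", r.chain.exons, r.strand, locus=f"L{i}")
            for i, r in enumerate(refs[: len(refs) // 2 + 1])
        ]
        df = accuracy_metrics(preds, refs).set_index("level")
        ref_introns = {(r.chrom, r.strand, i) for r in refs for i in r.chain.introns}
        pred_introns = {(p.chrom, p.strand, i) for p in preds for i in p.chain.introns}
        assert df.loc["intron", "sensitivity"] == pytest.approx(
            100 * len(ref_introns & pred_introns) / len(ref_introns)
        )
        assert df.loc["intron", "precision"] == pytest.approx(
            100 * len(ref_introns & pred_introns) / len(pred_introns)
        )
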