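import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoscribe.core import ExonChain, TranscriptModel
from isoscribe.io_formats import SampleSheet
from isoscribe.specificity import (
    categorize_value,
    tissue_means,
    tsi,
    tsi_summary,
    tsi_table,
    unique_tss,
)


def _sheet(tissue_reps: dict[str, int]) -> SampleSheet:
    rows = []
    for tissue, n in tissue_reps.items():
        for r in range(n):
            rows.append(
                {
                    "sample_id": f"{tissue}_r{r + 1}",
                    "tissue": tissue,
                    "individual": f"i{r + 1}",
                    "include_flag": "1",
                }
            )
    return SampleSheet(pd.DataFrame(rows))


class TestTissueMeans:
    def test_replicate_average(self):
        sheet = _sheet({"liver": 2, "testis": 2})
        tpm = pd.DataFrame(
            {"liver_r1": [10.0], "liver_r2": [20.0], "testis_r1": [0.0], "testis_r2": [0.0]},
            index=["t1"],
        )
        means, excluded, dropped = tissue_means(tpm, sheet)
        assert means.loc["t1", "liver"] == 15.0
        assert dropped == []

    def test_single_sample_transcript_flagged(self):
        sheet = _sheet({"liver": 2, "testis": 2})
        tpm = pd.DataFrame(
            {"liver_r1": [5.0], "liver_r2": [0.0], "testis_r1": [0.0], "testis_r2": [0.0]},
            index=["t1"],
        )
        _, excluded, _ = tissue_means(tpm, sheet)
        assert bool(excluded.loc["t1"])

    def test_tissue_with_one_replicate_dropped(self):
        sheet = _sheet({"liver": 2, "duodenum": 2})
        tpm = pd.DataFrame(
            {c: [1.0] for c in ["liver_r1", "liver_r2", "duodenum_r1", "duodenum_r2"]},
            index=["t1"],
        )
        means, _, dropped = tissue_means(tpm, sheet, exclusions=["duodenum_r2"])
        assert dropped == ["duodenum"]
        assert list(means.columns) == ["liver"]

    def test_all_samples_excluded_is_error(self):
        sheet = _sheet({"liver": 2})
        tpm = pd.DataFrame({"liver_r1": [1.0], "liver_r2": [1.0]}, index=["t1"])
        with pytest.raises(ValueError):
            tissue_means(tpm, sheet, exclusions=["liver_r1", "liver_r2"])


class TestTsi:
    def test_single_tissue_expression_is_one(self):
        assert tsi([10, 0, 0, 0, 0]) == 1.0

    def test_uniform_is_reciprocal_n(self):
        assert tsi([1.0] * 25) == pytest.approx(0.04)

    @pytest.mark.parametrize(
        "x,value,category",
        [
            ([8, 1, 1], 0.8, "tissue_specific"),  # boundary inclusive
            ([5, 5, 0], 0.5, "intermediate"),  # left-closed
            ([4.9999, 5, 0.0002], None, "broad"),
        ],
    )
    def test_boundaries(self, x, value, category):
        v = tsi(x)
        if value is not None:
            assert v == pytest.approx(value)
        assert categorize_value(v) == category

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            tsi([0, 0, 0])

    @given(
        st.lists(st.floats(0, 1e4), min_size=2, max_size=20).filter(lambda x: sum(x) > 0),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_scale_invariance(self, x, scale):
        v = tsi(x)
        assert 1 / len(x) - 1e-12 <= v <= 1 + 1e-12
        assert tsi([xi * scale for xi in x]) == pytest.approx(v, rel=1e-9)


class TestTsiTable:
    def test_categories_partition_and_strata(self):
        sheet = _sheet({"a": 2, "b": 2, "c": 2})
        tpm = pd.DataFrame(
            {
                "a_r1": [100.0, 5.0, 0.5],
                "a_r2": [100.0, 5.0, 0.5],
                "b_r1": [0.0, 5.0, 0.5],
                "b_r2": [0.0, 5.0, 0.5],
                "c_r1": [0.0, 5.0, 0.5],
                "c_r2": [0.0, 5.0, 0.5],
            },
            index=["specific", "flat", "low"],
        )
        records = tsi_table(tpm, sheet)
        by_id = records.set_index("transcript_id")
        assert by_id.loc["specific", "tsi"] == 1.0
        assert by_id.loc["specific", "category"] == "tissue_specific"
        assert by_id.loc["flat", "category"] == "broad"
        summary = tsi_summary(records)
        overall = summary[summary["stratum"] == "all"]
        assert overall["count"].sum() == len(records)
        assert overall["percent"].sum() == pytest.approx(100)

    def test_noise_cannot_break_exact_zeros(self):
        # 20% multiplicative replicate noise on a single-tissue transcript
        # leaves off-tissue means at exactly zero, so TSI stays 1 >= 0.8
        rng = np.random.default_rng(0)
        sheet = _sheet({"a": 2, "b": 2, "c": 2})
        base = 50.0
        noisy = base * (1 + rng.uniform(-0.2, 0.2, size=2))
        tpm = pd.DataFrame(
            {
                "a_r1": [noisy[0]],
                "a_r2": [noisy[1]],
                "b_r1": [0.0],
                "b_r2": [0.0],
                "c_r1": [0.0],
                "c_r2": [0.0],
            },
            index=["t"],
        )
        records = tsi_table(tpm, sheet)
        assert records.iloc[0]["tsi"] == 1.0


class TestUniqueTss:
    def _m(self, mid, start, end, strand="+"):
        return TranscriptModel(mid, "chr1", strand, ExonChain([(start, end)]), 3, "L")

    def test_lone_transcript_unique(self):
        m = self._m("a", 100, 500)
        out = unique_tss({"liver": [m]}, [m])
        assert out.iloc[0]["fraction_unique"] == 1.0

    def test_windows_80_apart_clash(self):
        a, b = self._m("a", 100, 500), self._m("b", 180, 600)
        out = unique_tss({"liver": [a], "testis": [b]}, [a, b])
        assert (out["fraction_unique"] == 0.0).all()

    def test_windows_101_apart_unique(self):
        a, b = self._m("a", 100, 500), self._m("b", 201, 600)
        out = unique_tss({"liver": [a], "testis": [b]}, [a, b])
        assert (out["fraction_unique"] == 1.0).all()

    def test_opposite_strand_never_clashes(self):
        a = self._m("a", 100, 500, "+")
        b = self._m("b", 30, 140, "-")  # '-' TSS at 140: 40 bp from a's TSS
        out = unique_tss({"liver": [a]}, [a, b])
        assert out.iloc[0]["fraction_unique"] == 1.0
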