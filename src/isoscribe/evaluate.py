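"""Truth-based evaluation of a run on simulated data.

Matching rule: a multi-exon model matches a true transcript when their
intron chains are identical on the same chromosome/strand; a single-exon
model matches when it overlaps a true single-exon transcript on the same
strand with both ends within the 60 bp terminal tolerance.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .core import ReferenceTranscript, TranscriptModel

END_TOL = 60


def match_models_to_truth(
    models: Sequence[TranscriptModel],
    truth_annotation: Sequence[ReferenceTranscript],
) -> dict[str, str]:
    """model_id -> true transcript_id for structurally matching models."""
    multi = {
        (t.chrom, t.strand, t.chain.introns): t.transcript_id
        for t in truth_annotation
        if len(t.chain) > 1
    }
    singles = [t for t in truth_annotation if len(t.chain) == 1]
    out: dict[str, str] = {}
    for m in models:
        if not m.is_single_exon:
            tid = multi.get((m.chrom, m.strand, m.chain.introns))
            if tid is not None:
                out[m.model_id] = tid
            continue
        for t in singles:
            if (
                t.chrom == m.chrom
                and t.strand == m.strand
                and abs(t.chain.start - m.chain.start) <= END_TOL
                and abs(t.chain.end - m.chain.end) <= END_TOL
            ):
                out[m.model_id] = t.transcript_id
                break
    return out


def recoverable_transcripts(
    read_truth: pd.DataFrame, min_reads: int = 3
) -> set[str]:
    """True transcripts with at least ``min_reads`` non-noise reads."""
    counts = read_truth[read_truth["transcript_id"] != "noise"][
        "transcript_id"
    ].value_counts()
    return set(counts[counts >= min_reads].index)


def isoform_recovery(
    models: Sequence[TranscriptModel],
    truth_annotation: Sequence[ReferenceTranscript],
    read_truth: pd.DataFrame,
    min_reads: int = 3,
) -> dict:
    """Fraction of recoverable true transcripts matched by exactly one model."""
    matches = match_models_to_truth(models, truth_annotation)
    expected = recoverable_transcripts(read_truth, min_reads)
    hits_per_truth: dict[str, int] = {}
    for tid in matches.values():
        hits_per_truth[tid] = hits_per_truth.get(tid, 0) + 1
    recovered = {t for t in expected if hits_per_truth.get(t, 0) >= 1}
    duplicated = {t for t in expected if hits_per_truth.get(t, 0) > 1}
    return {
        "n_expected": len(expected),
        "n_recovered": len(recovered),
        "n_duplicated": len(duplicated),
        "recovery_rate_pct": 100.0 * len(recovered) / len(expected) if expected else float("nan"),
    }


def category_accuracy(
    classification: pd.DataFrame,
    model_truth: Mapping[str, str],
    truth_transcripts: pd.DataFrame,
) -> dict:
    """Agreement between predicted novelty category and simulation truth,
    over models matched to a true transcript."""
    truth_cat = dict(
        zip(truth_transcripts["transcript_id"], truth_transcripts["category"])
    )
    n = correct = 0
    for _, row in classification.iterrows():
        tid = model_truth.get(row["model_id"])
        if tid is None:
            continue
        n += 1
        if row["category"] == truth_cat[tid]:
            correct += 1
    return {
        "n_evaluated": n,
        "n_correct": correct,
        "accuracy_pct": 100.0 * correct / n if n else float("nan"),
    }


def tsi_recovery(
    tsi_records: pd.DataFrame, truth_transcripts: pd.DataFrame
) -> dict:
    """How designed single-tissue transcripts score on the specificity index."""
    designed = truth_transcripts[truth_transcripts["tissue_label"] != "broad"]
    scored = tsi_records.set_index("transcript_id")
    hits = total = 0
    for tid in designed["transcript_id"]:
        if tid not in scored.index:
            continue
        total += 1
        if scored.loc[tid, "tsi"] >= 0.8:
            hits += 1
    return {
        "n_designed_specific_scored": total,
        "n_recovered_specific": hits,
        "specific_recovery_pct": 100.0 * hits / total if total else float("nan"),
    }
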