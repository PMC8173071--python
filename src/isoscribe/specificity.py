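"""Tissue-specificity scoring of quantified transcripts.

The tissue specificity index of a transcript with per-tissue mean TPM
x_1..x_n is TSI = max_i(x_i) / sum_i(x_i): 1/n for uniform expression, 1 for
single-tissue expression.  Transcripts are categorised as tissue-specific
(TSI >= 0.8), intermediate (0.5 <= TSI < 0.8) or broad (TSI < 0.5); the
boundaries are closed/open exactly as written.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core import TranscriptModel, five_prime
from .io_formats import SampleSheet

log = logging.getLogger(__name__)

TSI_SPECIFIC = 0.8
TSI_BROAD = 0.5


def tissue_means(
    tpm: pd.DataFrame,
    samples: SampleSheet,
    exclusions: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Per-transcript mean TPM by tissue, after sample exclusions.

    Samples listed in ``exclusions`` or flagged not-include in the sheet are
    dropped; tissues left with fewer than two replicates are dropped with a
    log entry.  Returns (tissue_means, excluded_from_tsi flag, dropped
    tissues); the flag marks transcripts expressed (TPM > 0) in at most one
    included sample, which are not scored.
    """
    meta = samples.included
    keep = [s for s in meta["sample_id"] if s in tpm.columns and s not in set(exclusions)]
    if not keep:
        raise ValueError("all samples excluded")
    meta = meta[meta["sample_id"].isin(keep)]
    reps = meta.groupby("tissue")["sample_id"].count()
    dropped = sorted(reps[reps < 2].index)
    if dropped:
        log.info("dropping tissues with <2 replicates: %s", ", ".join(dropped))
    meta = meta[~meta["tissue"].isin(dropped)]
    if meta.empty:
        raise ValueError("no tissue has two included replicates")
    sub = tpm[list(meta["sample_id"])]
    tissue_of = dict(zip(meta["sample_id"], meta["tissue"]))
    means = sub.T.groupby(sub.columns.map(tissue_of)).mean().T
    excluded = (sub > 0).sum(axis=1) <= 1
    return means, excluded, dropped


def tsi(x: np.ndarray | Sequence[float]) -> float:
    """max(x)/sum(x); undefined (ValueError) for an all-zero vector."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("TSI needs at least two tissues")
    total = x.sum()
    if total <= 0:
        raise ValueError("TSI undefined for all-zero expression")
    return float(x.max() / total)


def categorize_value(value: float) -> str:
    if value >= TSI_SPECIFIC:
        return "tissue_specific"
    if value < TSI_BROAD:
        return "broad"
    return "intermediate"


def tsi_table(
    tpm: pd.DataFrame,
    samples: SampleSheet,
    exclusions: Sequence[str] = (),
) -> pd.DataFrame:
    """Full TSI analysis: one row per scored transcript.

    Columns: transcript_id, per-tissue mean TPM, mean_tpm (over included
    samples), tsi, category, top_tissue.  Transcripts expressed in at most
    one sample, or with zero expression everywhere, are skipped with a log
    count.
    """
    means, excluded, _ = tissue_means(tpm, samples, exclusions)
    rows = []
    skipped = 0
    mean_tpm_all = means.mean(axis=1)
    for tid in means.index:
        x = means.loc[tid].to_numpy(dtype=float)
        if excluded.loc[tid] or x.sum() <= 0:
            skipped += 1
            continue
        value = tsi(x)
        rows.append(
            {
                "transcript_id": tid,
                **{f"mean_{t}": v for t, v in means.loc[tid].items()},
                "mean_tpm": float(mean_tpm_all.loc[tid]),
                "tsi": value,
                "category": categorize_value(value),
                "top_tissue": means.columns[int(np.argmax(x))],
            }
        )
    if skipped:
        log.info("TSI: skipped %d transcripts (single-sample or zero)", skipped)
    return pd.DataFrame(rows)


def tsi_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Category counts/percentages, overall and by expression band.

    Bands follow the standard TPM cutoffs: < 1, [1, 10), >= 10.
    """
    def band(v: float) -> str:
        if v < 1:
            return "tpm_lt_1"
        if v < 10:
            return "tpm_1_10"
        return "tpm_ge_10"

    frames = []
    for name, sub in [("all", records)] + [
        (b, records[records["mean_tpm"].map(band) == b])
        for b in ("tpm_lt_1", "tpm_1_10", "tpm_ge_10")
    ]:
        counts = sub["category"].value_counts()
        total = int(counts.sum())
        for cat in ("tissue_specific", "intermediate", "broad"):
            n = int(counts.get(cat, 0))
            frames.append(
                {
                    "stratum": name,
                    "category": cat,
                    "count": n,
                    "percent": 100 * n / total if total else float("nan"),
                }
            )
    return pd.DataFrame(frames)


def unique_tss(
    specific_by_tissue: dict[str, list[TranscriptModel]],
    all_models: Sequence[TranscriptModel],
    window: int = 50,
) -> pd.DataFrame:
    """Fraction of tissue-specific transcripts whose TSS is uniquely active.

    A TSS (+-window) is unique when it has no same-strand overlap with the
    +-window interval of any other predicted transcript's TSS.  Two TSS d bp
    apart overlap iff d <= 2*window.
    """
    rows = []
    for tissue, models in sorted(specific_by_tissue.items()):
        n_unique = 0
        for m in models:
            clash = any(
                o.model_id != m.model_id
                and o.chrom == m.chrom
                and o.strand == m.strand
                and abs(o.tss - m.tss) <= 2 * window
                for o in all_models
            )
            if not clash:
                n_unique += 1
        rows.append(
            {
                "tissue": tissue,
                "n_specific": len(models),
                "n_unique_tss": n_unique,
                "fraction_unique": n_unique / len(models) if models else float("nan"),
            }
        )
    return pd.DataFrame(rows)
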