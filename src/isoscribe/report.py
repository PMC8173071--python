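"""Ratio/partition arithmetic and run-summary rendering.

Every number in a rendered report is computed by these helpers from stage
tables — the report layer performs no computation of its own beyond them.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd


def ratio_pct(numerator: float, denominator: float, digits: int | None = None) -> float:
    """100 * numerator / denominator, optionally rounded."""
    if denominator == 0:
        raise ZeroDivisionError("ratio_pct denominator is zero")
    value = 100.0 * numerator / denominator
    return round(value, digits) if digits is not None else value


def partition_percentages(
    counts: Mapping[str, int], digits: int | None = None
) -> dict[str, float]:
    """Percentage share of each part of a partition (sums to ~100)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty partition")
    return {k: ratio_pct(v, total, digits) for k, v in counts.items()}


def per_unit_ratio(numerator: float, denominator: float, digits: int | None = None) -> float:
    """Plain ratio (e.g. expressed transcripts per locus)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    value = numerator / denominator
    return round(value, digits) if digits is not None else value


def category_counts(classification: pd.DataFrame) -> dict[str, int]:
    order = ("known_isoform", "novel_isoform", "novel_locus", "artifact")
    counts = classification["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in order}


def expressed_per_sample(tpm: pd.DataFrame, locus_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample expressed locus count and transcripts-per-locus ratio."""
    rows = []
    for sample in tpm.columns:
        expressed = tpm.index[tpm[sample] > 0]
        loci = {locus_of[t] for t in expressed if t in locus_of}
        rows.append(
            {
                "sample": sample,
                "expressed_transcripts": int(len(expressed)),
                "expressed_loci": len(loci),
                "transcripts_per_locus": (
                    per_unit_ratio(len(expressed), len(loci)) if loci else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def render_report(summary: Mapping, truth_section: Mapping | None = None) -> str:
    """Markdown report of a pipeline run; regeneration is idempotent."""
    lines = ["# isoscribe run report", ""]
    lines.append("## Stage counts")
    for key in (
        "reads_in",
        "reads_assigned",
        "clusters_emitted",
        "clusters_discarded",
        "models_pre_collapse",
        "models_post_collapse",
        "single_exon_retained",
        "single_exon_removed",
    ):
        if key in summary:
            lines.append(f"- {key}: {summary[key]}")
    if "category_counts" in summary:
        lines += ["", "## Novelty categories"]
        pcts = partition_percentages(summary["category_counts"], digits=1)
        for k, v in summary["category_counts"].items():
            lines.append(f"- {k}: {v} ({pcts[k]}%)")
    if "event_counts" in summary:
        lines += ["", "## Local splicing events"]
        for k, v in summary["event_counts"].items():
            lines.append(f"- {k}: {v}")
    if "tsi_category_counts" in summary:
        lines += ["", "## Tissue specificity"]
        pcts = partition_percentages(summary["tsi_category_counts"], digits=1)
        for k, v in summary["tsi_category_counts"].items():
            lines.append(f"- {k}: {v} ({pcts[k]}%)")
    if "structure" in summary:
        lines += ["", "## Intergenic proximity"]
        for k, v in summary["structure"].items():
            lines.append(f"- {k}: {v}")
    if truth_section:
        lines += ["", "## Recovery vs simulation truth"]
        for k, v in truth_section.items():
            lines.append(f"- {k}: {v}")
    lines.append("")
    return "\n".join(lines)
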