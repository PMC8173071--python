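"""End-to-end orchestration: simulate -> build -> compare -> quantify ->
tsi -> events -> structure -> report.

Each stage writes its outputs under the run directory and contributes to a
machine-readable run summary; read/model conservation is asserted at stage
boundaries.  The configuration (a single YAML-serialisable dataclass) is
echoed verbatim into the output directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluate, report
from .builder import build_transcripts
from .compare import classify_models, filter_single_exon
from .core import GenomicInterval, ToleranceSet
from .events import enumerate_events, event_counts, events_table
from .io_formats import write_outputs
from .quantify import quantify
from .simulate import SimulationConfig, simulate_dataset, write_simulation
from .specificity import tsi_summary, tsi_table, unique_tss
from .structure import end_overlap_stats, intergenic_proximity_test, model_ends

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All run parameters; defaults are the pipeline's standard settings."""

    outdir: str = "isoscribe_run"
    seed: int = 1
    tolerances: ToleranceSet = field(default_factory=ToleranceSet)
    min_support: int = 100
    tss_window: int = 100
    unique_tss_window: int = 50
    near_kb: int = 2
    exclude_samples: list[str] = field(default_factory=list)
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        # the simulation inherits the run seed unless set explicitly
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a fresh simulated dataset; returns the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    summary: dict = {"seed": config.seed}

    # --- simulate
    ds = simulate_dataset(config.sim)
    write_simulation(ds, out / "sim")
    summary["reads_in"] = len(ds.reads)

    # --- build
    models, stats = build_transcripts(ds.reads, config.tolerances)
    if not models:
        raise PipelineError("build", "no transcript models emitted")
    summary.update(
        clusters_emitted=stats.clusters_emitted,
        clusters_discarded=stats.clusters_discarded,
        models_pre_collapse=stats.models_pre_collapse,
        models_post_collapse=len(models),
    )
    total_support = sum(m.support for m in models)
    if total_support > len(ds.reads):
        raise PipelineError("build", "support exceeds read count (double-counting)")

    # --- compare + single-exon filter
    annotations = {"public": ds.public_reference}
    retained, removed = filter_single_exon(models, annotations, config.min_support)
    classification = classify_models(retained, annotations)
    summary["single_exon_removed"] = sum(removed.values())
    summary["single_exon_retained"] = sum(1 for m in retained if m.is_single_exon)
    cat_counts = report.category_counts(classification)
    if sum(cat_counts.values()) != len(retained):
        raise PipelineError("compare", "categories do not partition the model set")
    summary["category_counts"] = cat_counts
    summary["category_percent"] = report.partition_percentages(cat_counts, digits=1)

    # --- quantify
    matrix = quantify(
        ds.reads, retained, ds.sample_sheet.sample_ids, config.tolerances
    )
    summary["reads_assigned"] = len(ds.reads) - matrix.unassigned

    # --- tissue specificity
    tsi_records = tsi_table(matrix.tpm, ds.sample_sheet, config.exclude_samples)
    tsi_cats = (
        tsi_records["category"].value_counts().to_dict() if not tsi_records.empty else {}
    )
    summary["tsi_category_counts"] = {
        k: int(tsi_cats.get(k, 0)) for k in ("tissue_specific", "intermediate", "broad")
    }
    tsi_strata = tsi_summary(tsi_records) if not tsi_records.empty else pd.DataFrame()

    model_by_id = {m.model_id: m for m in retained}
    specific_by_tissue: dict[str, list] = {}
    if not tsi_records.empty:
        for _, row in tsi_records[tsi_records["category"] == "tissue_specific"].iterrows():
            specific_by_tissue.setdefault(row["top_tissue"], []).append(
                model_by_id[row["transcript_id"]]
            )
    unique_tss_tab = unique_tss(
        specific_by_tissue, retained, window=config.unique_tss_window
    )

    # --- events
    events = enumerate_events(retained)
    summary["event_counts"] = event_counts(events)

    # --- structure: end concordance and intergenic proximity
    ref_ends = [("public", model_ends(ds.public_reference))]
    end_summary, _ = end_overlap_stats(
        retained, ref_ends, window=config.tss_window, near_kb=config.near_kb
    )
    summary["tss_overlap"] = {
        row["set"]: row["fraction_tss_overlap"] for _, row in end_summary.iterrows()
    }
    code_cols = [c for c in classification.columns if c.startswith("code_")]
    intergenic_ids = classification.loc[
        (classification[code_cols] == "u").all(axis=1), "model_id"
    ]
    intergenic = [
        GenomicInterval(m.chrom, m.chain.start, m.chain.end, m.strand)
        for m in (model_by_id[i] for i in intergenic_ids)
    ]
    genes = [
        GenomicInterval(t.chrom, t.chain.start, t.chain.end, t.strand)
        for t in ds.public_reference
    ]
    if intergenic and genes:
        summary["structure"] = intergenic_proximity_test(
            intergenic, genes, ds.genome, seed=config.seed
        )

    # --- per-sample complexity
    locus_of = {m.model_id: m.locus_id for m in retained}
    complexity = report.expressed_per_sample(matrix.tpm, locus_of)

    # --- truth recovery
    model_truth = evaluate.match_models_to_truth(models, ds.full_annotation)
    recovery = evaluate.isoform_recovery(models, ds.full_annotation, ds.read_truth)
    accuracy = evaluate.category_accuracy(
        classification, model_truth, ds.truth_transcripts
    )
    tsi_truth = tsi_records.copy()
    if not tsi_truth.empty:
        retained_truth = {
            m: t for m, t in model_truth.items() if m in set(tsi_truth["transcript_id"])
        }
        tsi_truth = tsi_truth[tsi_truth["transcript_id"].isin(retained_truth)]
        tsi_truth = tsi_truth.assign(
            transcript_id=tsi_truth["transcript_id"].map(retained_truth)
        )
    tsi_rec = evaluate.tsi_recovery(tsi_truth, ds.truth_transcripts)
    truth_section = {**recovery, **accuracy, **tsi_rec}
    summary["recovery"] = truth_section

    # --- outputs
    tpm_out = matrix.tpm.reset_index().rename(columns={"index": "model_id"})
    write_outputs(
        out,
        retained,
        classifications=classification,
        expression_tpm=tpm_out,
        tsi=tsi_records,
        events=events_table(events),
    )
    matrix.counts.reset_index().rename(columns={"index": "model_id"}).to_csv(
        out / "counts.tsv", sep="\t", index=False
    )
    if not tsi_strata.empty:
        tsi_strata.to_csv(out / "tsi_summary.tsv", sep="\t", index=False)
    unique_tss_tab.to_csv(out / "unique_tss.tsv", sep="\t", index=False)
    complexity.to_csv(out / "complexity.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(out / "report.md", "w") as fh:
        fh.write(report.render_report(summary, truth_section))
    return summary
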