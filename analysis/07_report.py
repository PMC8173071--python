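#!/usr/bin/env python
"""Assemble the run report and truth-recovery section from the stage tables.

Reads results/, writes results/report.md."""
from pathlib import Path

import pandas as pd

from isoscribe import evaluate
from isoscribe.events import enumerate_events, event_counts
from isoscribe.io_formats import read_gtf, read_predicted_models
from isoscribe.report import category_counts, render_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    models = read_predicted_models(ROOT / "models.gtf")
    classification = pd.read_csv(ROOT / "classification.tsv", sep="\t")
    tsi = pd.read_csv(ROOT / "tsi.tsv", sep="\t")
    truth_ann = read_gtf(ROOT / "sim" / "truth_annotation.gtf")
    truth_tx = pd.read_csv(ROOT / "sim" / "truth_transcripts.tsv", sep="\t")
    read_truth = pd.read_csv(ROOT / "sim" / "truth_reads.tsv", sep="\t")

    summary = {
        "models_post_collapse": len(models),
        "category_counts": category_counts(classification),
        "event_counts": event_counts(enumerate_events(models)),
        "tsi_category_counts": tsi["category"].value_counts().to_dict(),
    }
    model_truth = evaluate.match_models_to_truth(models, truth_ann)
    recovery = evaluate.isoform_recovery(models, truth_ann, read_truth)
    accuracy = evaluate.category_accuracy(classification, model_truth, truth_tx)
    truth_section = {**recovery, **accuracy}
    (ROOT / "report.md").write_text(render_report(summary, truth_section))
    print(f"recovery: {recovery['recovery_rate_pct']:.1f}% "
          f"({recovery['n_recovered']}/{recovery['n_expected']} designed transcripts)")
    print(f"category accuracy: {accuracy['accuracy_pct']:.1f}% "
          f"over {accuracy['n_evaluated']} truth-matched models")
    print(f"report written to {ROOT / 'report.md'}")


if __name__ == "__main__":
    main()
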