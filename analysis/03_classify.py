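#!/usr/bin/env python
"""Classify predicted models against the public reference annotation:
gffcompare-style class codes -> novelty categories, single-exon retention
filter, and multi-exon sensitivity/precision at five levels.

Reads results/models.gtf + results/sim/, writes results/classification.tsv
and results/accuracy.tsv."""
from pathlib import Path

from isoscribe.compare import accuracy_metrics, classify_models, filter_single_exon
from isoscribe.io_formats import read_gtf, read_predicted_models
from isoscribe.report import category_counts, partition_percentages

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    models = read_predicted_models(ROOT / "models.gtf")
    annotations = {"public": read_gtf(ROOT / "sim" / "public_reference.gtf")}
    retained, removed = filter_single_exon(models, annotations, min_support=100)
    classification = classify_models(retained, annotations)
    classification.to_csv(ROOT / "classification.tsv", sep="\t", index=False)
    counts = category_counts(classification)
    pcts = partition_percentages(counts, digits=1)
    print(f"single-exon removed: {sum(removed.values())}; retained models: {len(retained)}")
    for cat, n in counts.items():
        print(f"  {cat}: {n} ({pcts[cat]}%)")
    acc = accuracy_metrics(retained, annotations["public"])
    acc.to_csv(ROOT / "accuracy.tsv", sep="\t", index=False)
    print(acc.round(1).to_string(index=False))
    for key in ("missed_exons", "novel_exons", "missed_introns", "novel_introns"):
        n, d = acc.attrs[key]
        print(f"  {key}: {n}/{d}")


if __name__ == "__main__":
    main()
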