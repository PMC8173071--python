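#!/usr/bin/env python
"""Score tissue specificity: per-tissue mean TPM, TSI = max/sum, categories
(specific >= 0.8, broad < 0.5), expression-band stratification and
unique-TSS attribution (+-50 bp, same strand).

Writes results/tsi.tsv, results/tsi_summary.tsv, results/unique_tss.tsv."""
from pathlib import Path

import pandas as pd

from isoscribe.io_formats import read_predicted_models, read_sample_sheet
from isoscribe.specificity import tsi_summary, tsi_table, unique_tss

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sheet = read_sample_sheet(ROOT / "sim" / "sample_sheet.tsv")
    tpm = pd.read_csv(ROOT / "expression.tsv", sep="\t").set_index("model_id")
    records = tsi_table(tpm, sheet)
    records.to_csv(ROOT / "tsi.tsv", sep="\t", index=False)
    summary = tsi_summary(records)
    summary.to_csv(ROOT / "tsi_summary.tsv", sep="\t", index=False)
    overall = summary[summary["stratum"] == "all"]
    for _, row in overall.iterrows():
        print(f"{row['category']}: {row['count']} ({row['percent']:.1f}%)")

    models = {m.model_id: m for m in read_predicted_models(ROOT / "models.gtf")}
    specific = records[records["category"] == "tissue_specific"]
    by_tissue: dict[str, list] = {}
    for _, row in specific.iterrows():
        by_tissue.setdefault(row["top_tissue"], []).append(models[row["transcript_id"]])
    tss = unique_tss(by_tissue, list(models.values()))
    tss.to_csv(ROOT / "unique_tss.tsv", sep="\t", index=False)
    if not tss.empty:
        print(tss.to_string(index=False))


if __name__ == "__main__":
    main()
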