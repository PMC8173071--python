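#!/usr/bin/env python
"""Quantify model expression per sample: 3'-anchored read/model
compatibility, EM apportioning of ambiguous reads, TPM without length
normalisation (full-length counting).

Writes results/expression.tsv (TPM) and results/counts.tsv."""
from pathlib import Path

from isoscribe.io_formats import read_bed12, read_predicted_models, read_sample_sheet
from isoscribe.quantify import quantify

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sheet = read_sample_sheet(ROOT / "sim" / "sample_sheet.tsv")
    reads, _ = read_bed12(ROOT / "sim" / "reads.bed12", sheet)
    models = read_predicted_models(ROOT / "models.gtf")
    matrix = quantify(reads, models, sheet.sample_ids)
    matrix.tpm.rename_axis("model_id").reset_index().to_csv(
        ROOT / "expression.tsv", sep="\t", index=False
    )
    matrix.counts.rename_axis("model_id").reset_index().to_csv(
        ROOT / "counts.tsv", sep="\t", index=False
    )
    assigned = len(reads) - matrix.unassigned
    print(f"assigned {assigned}/{len(reads)} reads "
          f"({matrix.unassigned} compatible with no model)")
    print(f"expression matrix: {matrix.tpm.shape[0]} models x {matrix.tpm.shape[1]} samples")


if __name__ == "__main__":
    main()
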