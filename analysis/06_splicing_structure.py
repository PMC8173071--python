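#!/usr/bin/env python
"""Structural characterisation: local splicing events per locus, 5'-end
concordance with the reference (+-100 bp), and the intergenic-proximity
permutation test (shuffle + nearest-gene distance + rank sum).

Writes results/events.tsv and results/structure_summary.tsv."""
import json
from pathlib import Path

import pandas as pd

from isoscribe.core import GenomicInterval
from isoscribe.events import enumerate_events, event_counts, events_table
from isoscribe.io_formats import read_gtf, read_predicted_models
from isoscribe.structure import end_overlap_stats, intergenic_proximity_test, model_ends

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    models = read_predicted_models(ROOT / "models.gtf")
    reference = read_gtf(ROOT / "sim" / "public_reference.gtf")

    events = enumerate_events(models)
    events_table(events).to_csv(ROOT / "events.tsv", sep="\t", index=False)
    print("splicing events:", dict(event_counts(events)))

    summary, _ = end_overlap_stats(models, [("public", model_ends(reference))])
    frac = summary.iloc[0]["fraction_tss_overlap"]
    print(f"model 5' ends within 100 bp of a reference 5' end: {100 * frac:.1f}%")

    classification = pd.read_csv(ROOT / "classification.tsv", sep="\t")
    code_cols = [c for c in classification.columns if c.startswith("code_")]
    intergenic_ids = set(
        classification.loc[(classification[code_cols] == "u").all(axis=1), "model_id"]
    )
    genome = dict(
        pd.read_csv(ROOT / "sim" / "genome.tsv", sep="\t").itertuples(index=False)
    )
    intergenic = [
        GenomicInterval(m.chrom, m.chain.start, m.chain.end, m.strand)
        for m in models
        if m.model_id in intergenic_ids
    ]
    genes = [
        GenomicInterval(t.chrom, t.chain.start, t.chain.end, t.strand)
        for t in reference
    ]
    out = {"n_intergenic_models": len(intergenic)}
    if intergenic:
        out.update(intergenic_proximity_test(intergenic, genes, genome, seed=seed))
        print(
            f"intergenic models: mean distance {out['mean_observed_distance']:.0f} bp "
            f"vs shuffled {out['mean_shuffled_distance']:.0f} bp "
            f"(rank-sum p = {out['p_value']:.3g})"
        )
    with open(ROOT / "structure_summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in out.items():
            fh.write(f"{k}\t{v}\n")


if __name__ == "__main__":
    main()
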