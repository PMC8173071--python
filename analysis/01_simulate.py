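#!/usr/bin/env python
"""Generate the study's synthetic dataset: a 20-gene annotation over two
chromosomes, 5 tissues x 2 replicates of full-length read alignments with
degradation and splice jitter, and a public reference with 10% of
transcripts withheld as novel isoforms plus 10% of genes as novel loci.

Writes results/sim/ (truth and public GTFs, reads.bed12, sample sheet,
truth tables, config echo)."""
import sys
from pathlib import Path

from isoscribe.simulate import SimulationConfig, simulate_dataset, write_simulation

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed)
    ds = simulate_dataset(cfg)
    write_simulation(ds, OUT)
    n_noise = int((ds.read_truth["transcript_id"] == "noise").sum())
    withheld = ds.truth_transcripts["category"] != "known_isoform"
    print(f"genes: {cfg.n_genes}; transcripts: {len(ds.full_annotation)} "
          f"({int(withheld.sum())} withheld from the public reference)")
    print(f"reads: {len(ds.reads)} ({n_noise} intronic/intergenic noise)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
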