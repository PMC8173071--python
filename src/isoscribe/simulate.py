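"""Synthetic ground-truth annotation and read-alignment simulator.

Emulates the statistical regime of a multiplexed full-length cDNA study:
multi-isoform genes on a small synthetic genome, per-tissue replicate
structure, full-length reads of ~759 b mean mature length, stochastic 5'
truncation (RNA degradation modelled as a geometric base loss in transcript
coordinates), splice-boundary wobble, intronic/intergenic single-exon noise
reads, and designed tissue-specific vs broadly expressed isoforms.  A
configurable fraction of transcripts is withheld from the emitted "public"
reference annotation as novel isoforms and novel loci, giving every
downstream stage a known truth.

Splice-boundary noise is modelled as: each boundary independently wobbles
with probability ``jitter_prob``, by a discretised Gaussian of scale
``jitter_sd`` (most junctions of real spliced alignments are snapped exactly
by the aligner; a minority wobble by a few bases).  Terminal ends always
wobble, with scale ``2 * jitter_sd``.

All randomness flows from a single integer seed through per-component
``numpy`` generator streams, so outputs are byte-identical across runs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlignedRead, ExonChain, ReferenceTranscript, is_terminal_suffix
from .io_formats import SampleSheet, write_bed12, write_gtf, write_sample_sheet

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the desk-scale study regime."""

    n_genes: int = 20
    n_chroms: int = 2
    isoform_probs: dict = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15}
    )
    exon_count_probs: dict = field(
        default_factory=lambda: {1: 0.10, 3: 0.15, 4: 0.25, 5: 0.25, 6: 0.15, 8: 0.10}
    )
    target_read_length: int = 759  # mean mature-transcript length (bases)
    exon_len_sigma: float = 0.45
    intron_len_mean: float = 700.0
    intron_len_sigma: float = 0.6
    n_tissues: int = 5
    replicates_per_tissue: int = 2
    tissue_specific_fraction: float = 0.3
    mean_reads_per_sample: float = 40.0  # per expressing transcript, log-normal
    expr_sigma: float = 0.7
    nb_dispersion: float = 0.3
    truncation_prob: float = 0.3
    truncation_mean_bp: float = 300.0
    jitter_sd: float = 3.0
    jitter_prob: float = 0.15
    noise_read_rate: float = 0.02
    novel_isoform_fraction: float = 0.1
    novel_locus_fraction: float = 0.1
    min_read_length: int = 50
    coding_fraction: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "tissue_specific_fraction",
            "truncation_prob",
            "jitter_prob",
            "novel_isoform_fraction",
            "novel_locus_fraction",
            "coding_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, int]
    full_annotation: list[ReferenceTranscript]
    public_reference: list[ReferenceTranscript]
    truth_transcripts: pd.DataFrame
    sample_sheet: SampleSheet
    reads: list[AlignedRead]
    read_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _categorical(rng: np.random.Generator, probs: dict) -> int:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


def _gene_exons(
    rng: np.random.Generator, cfg: SimulationConfig, start: int, n_exons: int
) -> list[tuple[int, int]]:
    # size exons so each gene's full-length transcript targets the mean
    # mature read length; derived isoforms and degradation sit slightly below
    exon_mean = cfg.target_read_length / n_exons
    mu = math.log(exon_mean) - cfg.exon_len_sigma**2 / 2
    exons = []
    pos = start
    for k in range(n_exons):
        elen = int(np.clip(rng.lognormal(mu, cfg.exon_len_sigma), 30, 2000))
        exons.append((pos, pos + elen))
        pos += elen
        if k < n_exons - 1:
            imu = math.log(cfg.intron_len_mean) - cfg.intron_len_sigma**2 / 2
            pos += int(np.clip(rng.lognormal(imu, cfg.intron_len_sigma), 120, 4000))
    return exons


#: minimum separation (bp) between corresponding intron boundaries of two
#: same-intron-count sibling isoforms: twice the 20 bp clustering tolerance,
#: so reads of one isoform can never satisfy the other's cluster
#: representative and the design stays resolvable by the builder
MIN_BOUNDARY_SEP = 40


def _separable(
    a: tuple[tuple[int, int], ...], b: tuple[tuple[int, int], ...]
) -> bool:
    if len(a) != len(b):
        return True  # different intron counts never share a cluster group
    return any(
        abs(x0 - y0) >= MIN_BOUNDARY_SEP or abs(x1 - y1) >= MIN_BOUNDARY_SEP
        for (x0, x1), (y0, y1) in zip(a, b)
    )


def _derive_isoform(
    rng: np.random.Generator, master: list[tuple[int, int]]
) -> list[tuple[int, int]] | None:
    """One structural variant of the master chain (skip / alt splice site /
    alternative terminal exon)."""
    n = len(master)
    ops = []
    if n >= 3:
        ops.append("skip")
    if n >= 2:
        ops += ["alt5", "alt3", "alt_first", "alt_last"]
    if not ops:
        return None
    op = ops[int(rng.integers(len(ops)))]
    exons = [list(e) for e in master]
    if op == "skip":
        k = int(rng.integers(1, n - 1))
        del exons[k]
    elif op == "alt5":  # move an exon's right edge (a donor on +)
        k = int(rng.integers(0, n - 1))
        delta = int(rng.integers(30, 81)) * (1 if rng.random() < 0.5 else -1)
        new_end = exons[k][1] + delta
        if not (exons[k][0] + 30 <= new_end <= exons[k + 1][0] - 30):
            return None
        exons[k][1] = new_end
    elif op == "alt3":  # move an exon's left edge
        k = int(rng.integers(1, n))
        delta = int(rng.integers(30, 81)) * (1 if rng.random() < 0.5 else -1)
        new_start = exons[k][0] + delta
        if not (exons[k - 1][1] + 30 <= new_start <= exons[k][1] - 30):
            return None
        exons[k][0] = new_start
    elif op == "alt_first":  # new first exon inside the first intron
        gap_s, gap_e = master[0][1], master[1][0]
        elen = int(rng.integers(60, 160))
        if gap_e - gap_s < elen + 80:
            return None
        s = gap_s + 40
        exons = [[s, s + elen]] + exons[1:]
    elif op == "alt_last":  # new last exon inside the last intron
        gap_s, gap_e = master[-2][1], master[-1][0]
        elen = int(rng.integers(60, 160))
        if gap_e - gap_s < elen + 80:
            return None
        e = gap_e - 40
        exons = exons[:-1] + [[e - elen, e]]
    return [tuple(e) for e in exons]


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[ReferenceTranscript], list[ReferenceTranscript], pd.DataFrame, dict]:
    """Build the full (truth) annotation, the public reference with the
    planned novelties withheld, the transcript truth table and genome sizes.

    Genes never overlap; withheld novel isoforms keep a same-strand
    exon-overlapping sibling in the public reference, withheld novel loci
    lose every isoform.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    cursors = {f"chr{c + 1}": 5000 for c in range(cfg.n_chroms)}
    genes: list[dict] = []
    for g in range(cfg.n_genes):
        chrom = f"chr{(g % cfg.n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = _categorical(rng, cfg.exon_count_probs)
        master = _gene_exons(rng, cfg, cursors[chrom], n_exons)
        k_iso = 1 if n_exons == 1 else _categorical(rng, cfg.isoform_probs)
        chains = [master]
        tries = 0
        while len(chains) < k_iso and tries < 50:
            tries += 1
            cand = _derive_isoform(rng, master)
            if cand is None:
                continue
            ok = True
            for other in chains:
                if cand == other:
                    ok = False
                    break
                ci = ExonChain(cand).introns
                oi = ExonChain(other).introns
                if is_terminal_suffix(ci, oi, strand, 5) or is_terminal_suffix(
                    oi, ci, strand, 5
                ):
                    ok = False
                    break
                if not _separable(ci, oi):
                    ok = False
                    break
            if ok:
                chains.append(cand)
        biotype = (
            "protein_coding"
            if (n_exons == 1 or rng.random() < cfg.coding_fraction)
            else "lncRNA"
        )
        genes.append(
            {
                "gene_id": f"G{g + 1:03d}",
                "chrom": chrom,
                "strand": strand,
                "chains": chains,
                "biotype": biotype,
                "multi_exon": n_exons > 1,
            }
        )
        span_end = max(e for ch in chains for _, e in ch)
        cursors[chrom] = span_end + int(rng.integers(8000, 20000))
    genome = {c: cursors[c] + 5000 for c in cursors}

    full: list[ReferenceTranscript] = []
    rows = []
    for gene in genes:
        for j, chain in enumerate(gene["chains"]):
            tid = f"{gene['gene_id']}.t{j + 1}"
            full.append(
                ReferenceTranscript(
                    transcript_id=tid,
                    gene_id=gene["gene_id"],
                    chrom=gene["chrom"],
                    strand=gene["strand"],
                    chain=ExonChain(chain),
                    biotype=gene["biotype"],
                )
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene["gene_id"],
                    "chrom": gene["chrom"],
                    "strand": gene["strand"],
                    "n_exons": len(chain),
                    "length": ExonChain(chain).length,
                    "multi_exon_gene": gene["multi_exon"],
                }
            )
    truth = pd.DataFrame(rows)

    # novelty plan: whole multi-exon genes for novel loci, non-first isoforms
    # of multi-isoform genes for novel isoforms
    multi_genes = [g["gene_id"] for g in genes if g["multi_exon"]]
    n_novel_loci = int(math.floor(cfg.novel_locus_fraction * cfg.n_genes))
    novel_locus_genes = set(
        rng.choice(multi_genes, size=min(n_novel_loci, len(multi_genes)), replace=False)
    )
    eligible = [
        r["transcript_id"]
        for r in rows
        if r["gene_id"] not in novel_locus_genes
        and not r["transcript_id"].endswith(".t1")
        and r["multi_exon_gene"]
    ]
    n_novel_iso = int(math.floor(cfg.novel_isoform_fraction * len(rows)))
    novel_isoforms = set(
        rng.choice(eligible, size=min(n_novel_iso, len(eligible)), replace=False)
    )

    def category(row) -> str:
        if row["gene_id"] in novel_locus_genes:
            return "novel_locus"
        if row["transcript_id"] in novel_isoforms:
            return "novel_isoform"
        return "known_isoform"

    truth["category"] = truth.apply(category, axis=1)
    public = [
        t
        for t in full
        if truth.set_index("transcript_id").loc[t.transcript_id, "category"]
        == "known_isoform"
    ]
    return full, public, truth, genome


# ---------------------------------------------------------------------------
# expression design
# ---------------------------------------------------------------------------

def design_expression(
    cfg: SimulationConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Assign each transcript a tissue label and per-tissue mean read count.

    Tissue-specific transcripts are expressed in exactly one tissue; broad
    transcripts in all tissues at a common mean — exact off-tissue zeros, so
    the designed specificity is recoverable."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 22]))
    tissues = cfg.tissues
    truth = truth.copy()
    labels = []
    means = np.zeros((len(truth), len(tissues)))
    for i in range(len(truth)):
        base = rng.lognormal(math.log(cfg.mean_reads_per_sample), cfg.expr_sigma)
        if rng.random() < cfg.tissue_specific_fraction:
            t = int(rng.integers(len(tissues)))
            labels.append(tissues[t])
            means[i, t] = base
        else:
            labels.append("broad")
            means[i, :] = base
    truth["tissue_label"] = labels
    for j, t in enumerate(tissues):
        truth[f"mean_reads_{t}"] = means[:, j]
    return truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _truncate_5p(
    exons: list[tuple[int, int]], strand: str, lost: int
) -> list[tuple[int, int]]:
    """Remove ``lost`` transcript bases from the 5' end (genomic left on +)."""
    if strand == "+":
        out = []
        for s, e in exons:
            if lost >= e - s:
                lost -= e - s
                continue
            out.append((s + lost, e))
            lost = 0
        return out
    out = []
    for s, e in reversed(exons):
        if lost >= e - s:
            lost -= e - s
            continue
        out.append((s, e - lost))
        lost = 0
    return list(reversed(out))


def _jitter_chain(
    rng: np.random.Generator,
    exons: list[tuple[int, int]],
    jitter_sd: float,
    jitter_prob: float,
) -> list[tuple[int, int]]:
    if jitter_sd <= 0:
        return exons
    bounds = [b for ex in exons for b in ex]
    new = list(bounds)
    for i in range(len(bounds)):
        terminal = i == 0 or i == len(bounds) - 1
        if terminal:
            delta = int(round(rng.normal(0, 2 * jitter_sd)))
        elif rng.random() < jitter_prob:
            delta = int(round(rng.normal(0, jitter_sd)))
        else:
            delta = 0
        lo = new[i - 1] + 1 if i > 0 else 0
        hi = bounds[i + 1] - 1 if i < len(bounds) - 1 else bounds[i] + 10_000
        new[i] = int(np.clip(bounds[i] + delta, lo, hi))
    return [(new[i], new[i + 1]) for i in range(0, len(new), 2)]


def simulate_reads(
    cfg: SimulationConfig,
    full_annotation: list[ReferenceTranscript],
    truth: pd.DataFrame,
    genome: dict[str, int],
) -> tuple[list[AlignedRead], pd.DataFrame, SampleSheet]:
    """Draw per-sample read counts and emit degraded, jittered alignments
    plus uniform intronic/intergenic single-exon noise reads."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 33]))
    tissues = cfg.tissues
    sheet_rows = []
    samples = []
    for t in tissues:
        for r in range(cfg.replicates_per_tissue):
            sid = f"{t}_rep{r + 1}"
            samples.append(sid)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "tissue": t,
                    "individual": f"ind{r + 1}",
                    "include_flag": "1",
                }
            )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    by_tid = {t.transcript_id: t for t in full_annotation}
    reads: list[AlignedRead] = []
    truth_rows = []
    counter = 0
    skipped_short = 0
    for _, row in truth.iterrows():
        t = by_tid[row["transcript_id"]]
        if t.chain.length < cfg.min_read_length:
            skipped_short += 1
            continue
        for tissue in tissues:
            mean = float(row[f"mean_reads_{tissue}"])
            if mean <= 0:
                continue
            counts = _nb_counts(
                rng, mean, cfg.nb_dispersion, cfg.replicates_per_tissue
            )
            for rep, n in enumerate(counts):
                sample = f"{tissue}_rep{rep + 1}"
                for _ in range(int(n)):
                    exons = list(t.chain.exons)
                    truncated = False
                    cap = t.chain.length - cfg.min_read_length
                    if cap > 0 and rng.random() < cfg.truncation_prob:
                        lost = int(rng.geometric(1.0 / cfg.truncation_mean_bp))
                        lost = min(lost, cap)
                        exons = _truncate_5p(exons, t.strand, lost)
                        truncated = True
                    exons = _jitter_chain(rng, exons, cfg.jitter_sd, cfg.jitter_prob)
                    counter += 1
                    rid = f"r{counter:07d}"
                    reads.append(
                        AlignedRead(
                            read_id=rid,
                            sample_id=sample,
                            chrom=t.chrom,
                            strand=t.strand,
                            chain=ExonChain(exons),
                        )
                    )
                    truth_rows.append(
                        {
                            "read_id": rid,
                            "sample_id": sample,
                            "transcript_id": t.transcript_id,
                            "truncated": truncated,
                        }
                    )
    if skipped_short:
        log.warning(
            "%d transcripts shorter than the %d b read floor were skipped",
            skipped_short,
            cfg.min_read_length,
        )

    # noise reads: uniform over non-exonic space
    n_noise = int(round(cfg.noise_read_rate * len(reads)))
    exon_space: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for t in full_annotation:
        exon_space[t.chrom].extend(t.chain.exons)
    chroms = sorted(genome)
    lens = np.array([genome[c] for c in chroms], dtype=float)
    placed = 0
    while placed < n_noise:
        chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        size = int(np.clip(rng.lognormal(math.log(300), 0.5), 60, 2000))
        if genome[chrom] <= size:
            continue
        start = int(rng.integers(0, genome[chrom] - size))
        if any(start < e and s < start + size for s, e in exon_space[chrom]):
            continue
        counter += 1
        placed += 1
        rid = f"r{counter:07d}"
        sample = samples[int(rng.integers(len(samples)))]
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(
            AlignedRead(
                read_id=rid,
                sample_id=sample,
                chrom=chrom,
                strand=strand,
                chain=ExonChain([(start, start + size)]),
            )
        )
        truth_rows.append(
            {
                "read_id": rid,
                "sample_id": sample,
                "transcript_id": "noise",
                "truncated": False,
            }
        )
    read_truth = pd.DataFrame(truth_rows)
    log.info("simulated %d reads (%d noise)", len(reads), n_noise)
    return reads, read_truth, sheet


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """End-to-end simulation under one config/seed."""
    full, public, truth, genome = simulate_annotation(cfg)
    truth = design_expression(cfg, truth)
    reads, read_truth, sheet = simulate_reads(cfg, full, truth, genome)
    return SimulatedDataset(
        config=cfg,
        genome=genome,
        full_annotation=full,
        public_reference=public,
        truth_transcripts=truth,
        sample_sheet=sheet,
        reads=reads,
        read_truth=read_truth,
    )


def write_simulation(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset as plain-text files (GTF/BED12/TSV/YAML)."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth_annotation": out / "truth_annotation.gtf",
        "public_reference": out / "public_reference.gtf",
        "reads": out / "reads.bed12",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth_transcripts": out / "truth_transcripts.tsv",
        "truth_reads": out / "truth_reads.tsv",
        "config": out / "config.yaml",
        "genome": out / "genome.tsv",
    }
    write_gtf(ds.full_annotation, paths["truth_annotation"])
    if ds.public_reference:
        write_gtf(ds.public_reference, paths["public_reference"])
    write_bed12(ds.reads, paths["reads"])
    write_sample_sheet(ds.sample_sheet, paths["sample_sheet"])
    ds.truth_transcripts.to_csv(paths["truth_transcripts"], sep="\t", index=False)
    ds.read_truth.to_csv(paths["truth_reads"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh, sort_keys=False)
    pd.DataFrame(
        {"chrom": list(ds.genome), "length": list(ds.genome.values())}
    ).to_csv(paths["genome"], sep="\t", index=False)
    return paths
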