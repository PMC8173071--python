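"""Readers/writers for GTF, BED12 and the pipeline's TSV tables.

GTF is 1-based closed on disk and converted to the package's 0-based
half-open convention on read; writers convert back on output.  Attribute
parsing of GTF lines is delegated to :mod:`gffutils`.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .core import AlignedRead, ExonChain, ReferenceTranscript, TranscriptModel

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input records; message names the offending line."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike) -> list[ReferenceTranscript]:
    """Read exon features of a GTF into ReferenceTranscript records.

    Exons are grouped per transcript_id and sorted; the biotype is taken from
    the ``transcript_biotype`` or ``gene_biotype`` attribute (``unknown`` if
    absent).  Coordinates are converted from 1-based closed to 0-based
    half-open.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - wrap any parse failure
                raise FormatError(f"{path}:{lineno}: malformed GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise FormatError(f"{path}:{lineno}: exon end < start")
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise FormatError(f"{path}:{lineno}: missing attribute {exc}")
            biotype = "unknown"
            for key in ("transcript_biotype", "gene_biotype"):
                if key in feat.attributes:
                    biotype = feat.attributes[key][0]
                    break
            start0, end0 = feat.start - 1, feat.end  # GTF closed -> half-open
            if tid in meta:
                chrom, strand, _, old_bt = meta[tid]
                if chrom != feat.seqid:
                    raise FormatError(
                        f"{path}:{lineno}: transcript {tid} spans two chromosomes"
                    )
                if biotype == "unknown":
                    biotype = old_bt
            meta[tid] = (feat.seqid, feat.strand, gid, biotype)
            exons.setdefault(tid, []).append((start0, end0))
    out = []
    for tid, ex in exons.items():
        chrom, strand, gid, biotype = meta[tid]
        out.append(
            ReferenceTranscript(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                chain=ExonChain(sorted(ex)),
                biotype=biotype,
            )
        )
    out.sort(key=lambda t: (t.chrom, t.chain.start, t.chain.end, t.transcript_id))
    return out


def write_gtf(
    transcripts: Iterable[ReferenceTranscript],
    path: str | os.PathLike,
    source: str = "isoscribe",
    extra_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write transcripts as GTF exon (plus transcript) features.

    ``extra_attrs`` maps transcript_id -> additional attribute key/values
    (e.g. the novelty category of a predicted model).
    """
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        for t in sorted(
            transcripts, key=lambda t: (t.chrom, t.chain.start, t.transcript_id)
        ):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{t.biotype}";'
            )
            for key, val in extra_attrs.get(t.transcript_id, {}).items():
                attrs += f' {key} "{val}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.chain.start + 1}\t"
                f"{t.chain.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.chain:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: sample_id -> (tissue, individual, include_flag)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue", "individual", "include_flag")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("sample sheet has duplicate sample_id values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["include_flag"].astype(bool)]

    def tissue_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["tissue"].iloc[0])


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def read_bed12(
    path: str | os.PathLike,
    samples: SampleSheet | None = None,
    default_sample: str | None = None,
) -> tuple[list[AlignedRead], int]:
    """Read aligned reads from BED12.

    The sample id is resolved from the read name prefix ``<sample>|<read>``
    when present, else from ``default_sample``, else from the file stem.
    Returns (reads, n_rejected) where rejected records are strand-``.`` ones.
    """
    path = Path(path)
    known = set(samples.sample_ids) if samples is not None else None
    fallback = default_sample or path.stem
    reads: list[AlignedRead] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand == ".":
                rejected += 1
                continue
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={n_blocks} but "
                    f"{len(sizes)} sizes / {len(offsets)} starts"
                )
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            if exons[-1][1] != end:
                raise FormatError(f"{path}:{lineno}: blocks do not span chromEnd")
            if "|" in name:
                sample_id, read_id = name.split("|", 1)
            else:
                sample_id, read_id = fallback, name
            if known is not None and sample_id not in known:
                raise FormatError(
                    f"{path}:{lineno}: sample {sample_id!r} not in sample sheet"
                )
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    sample_id=sample_id,
                    chrom=chrom,
                    strand=strand,
                    chain=ExonChain(exons),
                )
            )
    if rejected:
        log.warning("%s: rejected %d strand-unknown records", path, rejected)
    return reads, rejected


def write_bed12(reads: Iterable[AlignedRead], path: str | os.PathLike) -> None:
    """Write reads as BED12, sample id carried as a ``sample|read`` name."""
    with open(path, "w") as fh:
        for r in reads:
            ex = r.chain.exons
            start = ex[0][0]
            sizes = ",".join(str(e - s) for s, e in ex)
            offsets = ",".join(str(s - start) for s, _ in ex)
            fh.write(
                f"{r.chrom}\t{start}\t{ex[-1][1]}\t{r.sample_id}|{r.read_id}\t0\t"
                f"{r.strand}\t{start}\t{ex[-1][1]}\t0\t{len(ex)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Pipeline outputs
# ---------------------------------------------------------------------------

def models_to_reference(
    models: Sequence[TranscriptModel],
) -> list[ReferenceTranscript]:
    """View predicted models as ReferenceTranscript records (for write_gtf)."""
    return [
        ReferenceTranscript(
            transcript_id=m.model_id,
            gene_id=m.locus_id or m.model_id,
            chrom=m.chrom,
            strand=m.strand,
            chain=m.chain,
            biotype="predicted",
        )
        for m in models
    ]


def read_predicted_models(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read a models.gtf written by this package back into TranscriptModel
    records, recovering read support and locus id from the attributes."""
    support: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line.rstrip("\n"), dialect=None)
            if feat.featuretype != "transcript" or "support" not in feat.attributes:
                continue
            support[feat.attributes["transcript_id"][0]] = int(
                feat.attributes["support"][0]
            )
    return [
        TranscriptModel(
            model_id=t.transcript_id,
            chrom=t.chrom,
            strand=t.strand,
            chain=t.chain,
            support=support.get(t.transcript_id, 0),
            locus_id=t.gene_id,
        )
        for t in read_gtf(path)
    ]


def write_outputs(
    out_dir: str | os.PathLike,
    models: Sequence[TranscriptModel],
    classifications: pd.DataFrame | None = None,
    expression_tpm: pd.DataFrame | None = None,
    tsi: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write models.gtf plus the available TSV tables into ``out_dir``."""
    if not models:
        raise ValueError("refusing to write outputs for an empty model set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    extra: dict[str, dict[str, str]] = {}
    if classifications is not None:
        if classifications.empty:
            raise ValueError("empty classification set")
        extra = {
            row["model_id"]: {"category": row["category"]}
            for _, row in classifications.iterrows()
        }
    gtf = out_dir / "models.gtf"
    write_gtf(models_to_reference(models), gtf, extra_attrs=extra)
    written["models_gtf"] = gtf
    tables = {
        "classification": classifications,
        "expression": expression_tpm,
        "tsi": tsi,
        "events": events,
    }
    for name, df in tables.items():
        if df is None:
            continue
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p
    return written
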