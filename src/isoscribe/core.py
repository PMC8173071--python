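"""Core genomic data model.

All coordinates are 0-based half-open throughout the package; file readers
and writers convert at the boundary (GTF is 1-based closed on disk).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval, sortable by (chrom, start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ExonChain:
    """An ordered, non-overlapping exon structure on one chromosome/strand.

    Exons are (start, end) pairs in genomic order with at least a 1 bp gap
    (an intron) between consecutive exons.  The intron chain — the ordered
    list of (donor_side, acceptor_side) genomic gaps — is the identity key
    used for isoform matching throughout the package.
    """

    __slots__ = ("exons",)

    def __init__(self, exons: Sequence[tuple[int, int]]):
        exons = tuple((int(s), int(e)) for s, e in exons)
        if not exons:
            raise ValueError("ExonChain needs at least one exon")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"invalid exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"exons overlap or touch: ({s1},{e1}) ({s2},{e2})")
        self.exons = exons

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        """Total exonic length (the mature-transcript length)."""
        return sum(e - s for s, e in self.exons)

    def __len__(self) -> int:
        return len(self.exons)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExonChain) and self.exons == other.exons

    def __hash__(self) -> int:
        return hash(self.exons)

    def __repr__(self) -> str:
        return f"ExonChain({list(self.exons)})"

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.exons)


def five_prime(chain_or_start_end, strand: str) -> int:
    """Strand-aware 5' genomic coordinate (start on +, end on -)."""
    s, e = _ends(chain_or_start_end)
    return s if strand == "+" else e


def three_prime(chain_or_start_end, strand: str) -> int:
    """Strand-aware 3' genomic coordinate (end on +, start on -)."""
    s, e = _ends(chain_or_start_end)
    return e if strand == "+" else s


def _ends(obj) -> tuple[int, int]:
    if isinstance(obj, ExonChain):
        return obj.start, obj.end
    s, e = obj
    return s, e


def is_terminal_suffix(
    a: Sequence[tuple[int, int]],
    b: Sequence[tuple[int, int]],
    strand: str,
    tol: int,
) -> bool:
    """True if intron chain ``a`` is a contiguous 3'-terminal subsequence of
    ``b`` (equality allowed), each boundary within ``tol`` bp.

    The 3'-terminal introns of a chain in genomic order are the last ones on
    the + strand and the first ones on the - strand.  The empty chain is a
    suffix of any chain (a single-exon fragment of a multi-exon model).
    """
    la, lb = len(a), len(b)
    if la > lb:
        return False
    seg = b[lb - la :] if strand == "+" else b[:la]
    return all(
        abs(x0 - y0) <= tol and abs(x1 - y1) <= tol
        for (x0, x1), (y0, y1) in zip(a, seg)
    )


@dataclass(frozen=True)
class AlignedRead:
    """One genome-aligned full-length cDNA read."""

    read_id: str
    sample_id: str
    chrom: str
    strand: str
    chain: ExonChain


@dataclass(frozen=True)
class ReferenceTranscript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    chain: ExonChain
    biotype: str = "unknown"


@dataclass
class TranscriptModel:
    """A predicted transcript: consensus exon chain plus provenance."""

    model_id: str
    chrom: str
    strand: str
    chain: ExonChain
    support: int
    locus_id: str = ""
    members: tuple[str, ...] = ()

    @property
    def is_single_exon(self) -> bool:
        return len(self.chain) == 1

    @property
    def tss(self) -> int:
        return five_prime(self.chain, self.strand)

    @property
    def tes(self) -> int:
        return three_prime(self.chain, self.strand)


@dataclass(frozen=True)
class ToleranceSet:
    """Boundary tolerances (bp) of the clustering/collapse stage.

    Defaults are the pipeline's standard settings: 20 bp internal / 60 bp
    terminal at clustering, 5 bp internal / 100 bp 3' / 5,000 bp 5' at the
    degradation collapse, minimum cluster size 3.
    """

    cluster_internal: int = 20
    cluster_terminal: int = 60
    collapse_internal: int = 5
    collapse_3prime: int = 100
    collapse_5prime: int = 5000
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        for name in (
            "cluster_internal",
            "cluster_terminal",
            "collapse_internal",
            "collapse_3prime",
            "collapse_5prime",
            "min_cluster_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
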