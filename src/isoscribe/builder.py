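"""Transcript-model construction from aligned full-length reads.

Four stages mirror the standard long-read isoform pipeline:

1. greedy intron-chain clustering of reads (internal boundary tolerance
   20 bp, terminal tolerance 60 bp for single-exon reads, minimum cluster
   size 3);
2. coordinate consensus per cluster (per-boundary median, ties low);
3. locus grouping by strand-aware 3' ends (within 100 bp, connected
   components);
4. degradation-aware collapse: a model whose intron chain is a boundary-
   compatible 3'-terminal fragment of a longer model in the same locus is
   absorbed into it (5 bp internal / 100 bp 3' / 5,000 bp 5' tolerances),
   attributing it to 5'-truncated cDNA.

Clustering is greedy first-fit in a canonical scan order, so the output is
independent of input read order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (
    AlignedRead,
    ExonChain,
    ToleranceSet,
    TranscriptModel,
    is_terminal_suffix,
    three_prime,
)

log = logging.getLogger(__name__)


@dataclass
class ReadCluster:
    members: list[AlignedRead]
    chrom: str
    strand: str

    @property
    def representative(self) -> AlignedRead:
        return self.members[0]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class BuildStats:
    reads_in: int = 0
    clusters_emitted: int = 0
    clusters_discarded: int = 0
    reads_in_emitted_clusters: int = 0
    consensus_rejected: int = 0
    models_pre_collapse: int = 0
    models_post_collapse: int = 0


def _scan_key(read: AlignedRead) -> tuple:
    introns = read.chain.introns
    first = introns[0][0] if introns else read.chain.start
    return (
        read.chrom,
        read.strand,
        len(introns),
        first,
        read.chain.start,
        read.chain.end,
        read.read_id,
    )


def _boundaries_compatible(a: ExonChain, b: ExonChain, tol: int) -> bool:
    return all(
        abs(x0 - y0) <= tol and abs(x1 - y1) <= tol
        for (x0, x1), (y0, y1) in zip(a.introns, b.introns)
    )


def cluster_alignments(
    reads: list[AlignedRead],
    tol: ToleranceSet = ToleranceSet(),
    stats: BuildStats | None = None,
) -> list[ReadCluster]:
    """Group reads with the same intron structure into clusters.

    A read joins the first cluster (in scan order) whose representative has
    the same chrom/strand/intron count and every intron boundary within
    ``cluster_internal`` bp; single-exon reads additionally need both ends
    within ``cluster_terminal`` bp.  Multi-exon terminal ends are left free
    here — 5' variability from degradation is resolved at collapse.  Only
    clusters of at least ``min_cluster_size`` reads are emitted.
    """
    if stats is not None:
        stats.reads_in += len(reads)
    emitted: list[ReadCluster] = []
    discarded = 0

    # group by (chrom, strand, intron count); scan each group sorted by the
    # first boundary so stale clusters can be retired (first boundary is
    # itself constrained by the tolerance, making the scan near-linear)
    groups: dict[tuple, list[AlignedRead]] = {}
    for read in sorted(reads, key=_scan_key):
        key = (read.chrom, read.strand, len(read.chain.introns))
        groups.setdefault(key, []).append(read)

    for (chrom, strand, n_introns), members in groups.items():
        single = n_introns == 0
        first_tol = tol.cluster_terminal if single else tol.cluster_internal
        active: list[ReadCluster] = []
        done: list[ReadCluster] = []
        for read in members:
            fb = read.chain.introns[0][0] if n_introns else read.chain.start
            still = []
            for cl in active:
                rep = cl.representative.chain
                rep_fb = rep.introns[0][0] if n_introns else rep.start
                if rep_fb < fb - first_tol:
                    done.append(cl)
                else:
                    still.append(cl)
            active = still
            placed = False
            for cl in active:
                rep = cl.representative.chain
                if not _boundaries_compatible(read.chain, rep, tol.cluster_internal):
                    continue
                if single and (
                    abs(read.chain.start - rep.start) > tol.cluster_terminal
                    or abs(read.chain.end - rep.end) > tol.cluster_terminal
                ):
                    continue
                cl.members.append(read)
                placed = True
                break
            if not placed:
                active.append(ReadCluster([read], chrom, strand))
        for cl in done + active:
            if cl.size >= tol.min_cluster_size:
                emitted.append(cl)
            else:
                discarded += 1
    if stats is not None:
        stats.clusters_emitted += len(emitted)
        stats.clusters_discarded += discarded
        stats.reads_in_emitted_clusters += sum(c.size for c in emitted)
    log.info("clustering: %d clusters emitted, %d discarded", len(emitted), discarded)
    emitted.sort(key=lambda c: _scan_key(c.representative))
    return emitted


def _median_low(values: list[int]) -> int:
    """Median with even-count ties resolved to the lower middle value."""
    vals = sorted(values)
    return vals[(len(vals) - 1) // 2]


def consensus_model(cluster: ReadCluster, model_id: str = "") -> TranscriptModel | None:
    """Coordinate consensus of a cluster: per-boundary median (ties low).

    Returns None (with a warning) if the consensus would produce an empty
    exon or intron — possible only for adversarial member combinations.
    """
    chains = [m.chain for m in cluster.members]
    n_introns = len(chains[0].introns)
    boundaries = [_median_low([c.start for c in chains])]
    for i in range(n_introns):
        boundaries.append(_median_low([c.introns[i][0] for c in chains]))
        boundaries.append(_median_low([c.introns[i][1] for c in chains]))
    boundaries.append(_median_low([c.end for c in chains]))
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        log.warning("consensus rejected: degenerate exon/intron in %s", model_id)
        return None
    exons = [(boundaries[i], boundaries[i + 1]) for i in range(0, len(boundaries) - 1, 2)]
    return TranscriptModel(
        model_id=model_id,
        chrom=cluster.chrom,
        strand=cluster.strand,
        chain=ExonChain(exons),
        support=cluster.size,
        members=tuple(m.read_id for m in cluster.members),
    )


def assign_loci(
    models: list[TranscriptModel], tol: ToleranceSet = ToleranceSet()
) -> list[TranscriptModel]:
    """Group models into loci by strand-aware 3' ends.

    Loci are the connected components of "same chrom/strand and 3' ends
    within ``collapse_3prime`` bp"; on sorted 3' ends this is exactly the
    chain of consecutive gaps <= tolerance.  The locus id is
    ``chrom:<leftmost 3' end>:strand``.
    """
    by_group: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        by_group.setdefault((m.chrom, m.strand), []).append(m)
    for (chrom, strand), group in by_group.items():
        group.sort(key=lambda m: (m.tes, m.chain.start, m.chain.end))
        component: list[TranscriptModel] = []
        for m in group:
            if component and m.tes - component[-1].tes > tol.collapse_3prime:
                _name_locus(component)
                component = []
            component.append(m)
        if component:
            _name_locus(component)
    return models


def _name_locus(component: list[TranscriptModel]) -> None:
    leftmost = min(m.tes for m in component)
    locus_id = f"{component[0].chrom}:{leftmost}:{component[0].strand}"
    for m in component:
        m.locus_id = locus_id


def absorbable(
    a: TranscriptModel, b: TranscriptModel, tol: ToleranceSet = ToleranceSet()
) -> bool:
    """True if model ``a`` is a degradation fragment of ``b``.

    Requires: (a) a's intron chain is a contiguous 3'-terminal subsequence
    of b's (equality allowed) with boundaries within ``collapse_internal``
    bp; (b) strand-aware 3' ends within ``collapse_3prime`` bp; (c) a's 5'
    end within ``collapse_5prime`` bp of its projected position on b — the
    5' end of the b exon its first exon aligns to.
    """
    if a is b or a.chrom != b.chrom or a.strand != b.strand:
        return False
    ia, ib = a.chain.introns, b.chain.introns
    if not is_terminal_suffix(ia, ib, a.strand, tol.collapse_internal):
        return False
    if abs(a.tes - b.tes) > tol.collapse_3prime:
        return False
    # exon of b that a's 5'-most exon corresponds to
    k = len(ib) - len(ia)
    if a.strand == "+":
        proj = b.chain.exons[k][0]
        d5 = abs(a.chain.start - proj)
    else:
        proj = b.chain.exons[len(ia)][1]
        d5 = abs(a.chain.end - proj)
    return d5 <= tol.collapse_5prime


def _survivor_rank(m: TranscriptModel) -> tuple:
    # most introns, then higher support, then longer span, then smaller start
    return (
        -len(m.chain.introns),
        -m.support,
        -m.chain.span,
        m.chain.start,
    )


def collapse_models(
    models: list[TranscriptModel],
    tol: ToleranceSet = ToleranceSet(),
    stats: BuildStats | None = None,
) -> list[TranscriptModel]:
    """Absorb 5'-degradation fragments into their parent models.

    Within each locus, fragments are processed fewest-introns-first so each
    meets its longest compatible superset; support transfers to the
    survivor.  Iterates to a fixed point (absorption can cascade when a
    fragment's own support changes the survivor ranking).
    """
    by_locus: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_locus.setdefault(m.locus_id, []).append(m)
    out: list[TranscriptModel] = []
    for locus_models in by_locus.values():
        alive = list(locus_models)
        changed = True
        while changed:
            changed = False
            alive.sort(key=lambda m: (len(m.chain.introns), _survivor_rank(m)))
            for a in list(alive):
                candidates = [
                    b for b in alive if absorbable(a, b, tol) and _survivor_rank(b) < _survivor_rank(a)
                ]
                if not candidates:
                    continue
                b = min(candidates, key=_survivor_rank)
                b.support += a.support
                b.members = b.members + a.members
                alive.remove(a)
                changed = True
        out.extend(alive)
    if stats is not None:
        stats.models_post_collapse += len(out)
    out.sort(key=lambda m: (m.chrom, m.chain.start, m.chain.end, m.strand))
    return out


def build_transcripts(
    reads: list[AlignedRead], tol: ToleranceSet = ToleranceSet()
) -> tuple[list[TranscriptModel], BuildStats]:
    """Full builder stage: cluster, consensus, loci, collapse, final ids."""
    stats = BuildStats()
    clusters = cluster_alignments(reads, tol, stats)
    models = []
    for i, cl in enumerate(clusters):
        m = consensus_model(cl, model_id=f"tmp.{i}")
        if m is None:
            stats.consensus_rejected += 1
        else:
            models.append(m)
    stats.models_pre_collapse = len(models)
    assign_loci(models, tol)
    final = collapse_models(models, tol, stats)
    for i, m in enumerate(final):
        m.model_id = f"ISO.{i + 1:05d}"
    return final, stats
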