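"""Local alternative-splicing event enumeration.

Within each locus, pairs of transcript structures are compared to emit the
seven standard local events: skipped exon (SE), mutually exclusive exons
(MX), retained intron (RI), alternative 5'/3' splice site (A5/A3) and
alternative first/last exon (AF/AL).  Events are deduplicated on their
defining coordinate tuple within (locus, type), and each event records the
transcripts witnessing its inclusion and exclusion forms.

Conventions (documented because they disambiguate overlapping definitions):

* A5/A3 — two introns share one boundary and differ at the other, and the
  exons flanking the differing boundary overlap each other.  The genomic
  side is translated to 5'/3' strand-awareness (left boundary = 5' splice
  site on +).
* AF/AL — the two terminal exons are distinct AND non-overlapping, their
  inner junctions differ, and both splice into overlapping partner exons
  (the "same downstream/upstream exon").  The overlap requirements keep
  AF/AL disjoint from A5/A3: a shared-boundary alternative whose variable
  exons overlap is a splice-site event, not a terminal-exon event.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core import ExonChain, TranscriptModel


@dataclass
class SplicingEvent:
    event_type: str
    locus_id: str
    chrom: str
    strand: str
    coordinates: tuple[int, ...]
    inclusion: set[str] = field(default_factory=set)
    exclusion: set[str] = field(default_factory=set)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _pair_events(t1, t2, strand: str) -> Iterable[tuple[str, tuple, str, str]]:
    """Yield (type, coords, inclusion_tid, exclusion_tid) for one ordered pair.

    ``t1``/``t2`` are (transcript_id, ExonChain).
    """
    id1, c1 = t1
    id2, c2 = t2
    e1, e2 = c1.exons, c2.exons
    i1, i2 = c1.introns, c2.introns
    set_i2 = set(i2)
    set_e2 = set(e2)

    # SE: internal exon of t1 skipped in t2 (flanking junctions joined)
    for k in range(1, len(e1) - 1):
        p = i1[k - 1][0]
        a, b = e1[k]
        q = i1[k][1]
        if (p, q) in set_i2:
            yield "SE", (p, a, b, q), id1, id2

    # RI: consecutive exon pair of t1 fused into one exon of t2
    for k in range(len(e1) - 1):
        s, d = e1[k]
        a, e = e1[k + 1]
        if (s, e) in set_e2:
            yield "RI", (s, d, a, e), id2, id1

    # MX: adjacent intron pairs sharing outer junctions, exclusive middle exons
    for k in range(len(i1) - 1):
        p, a1 = i1[k]
        b1, q = i1[k + 1]
        for m in range(len(i2) - 1):
            if i2[m][0] != p or i2[m + 1][1] != q:
                continue
            a2, b2 = i2[m][1], i2[m + 1][0]
            if not _overlap((a1, b1), (a2, b2)) and (a1, b1) != (a2, b2):
                lo, hi = sorted([(a1, b1), (a2, b2)])
                yield "MX", (p, *lo, *hi, q), id1, id2

    # A5/A3: introns sharing one boundary; flanking exons at the differing
    # boundary must overlap
    for k, (d1, a1) in enumerate(i1):
        left1, right1 = e1[k], e1[k + 1]
        for m, (d2, a2) in enumerate(i2):
            left2, right2 = e2[m], e2[m + 1]
            if a1 == a2 and d1 != d2 and _overlap(left1, left2):
                typ = "A5" if strand == "+" else "A3"
                lo, hi = sorted([d1, d2])
                yield typ, (lo, hi, a1), id1, id2
            if d1 == d2 and a1 != a2 and _overlap(right1, right2):
                typ = "A3" if strand == "+" else "A5"
                lo, hi = sorted([a1, a2])
                yield typ, (d1, lo, hi), id1, id2

    # AF/AL: distinct non-overlapping terminal exons with distinct inner
    # junctions splicing into overlapping partner exons
    if len(e1) > 1 and len(e2) > 1:
        f1, f2 = e1[0], e2[0]
        if f1 != f2 and not _overlap(f1, f2) and i1[0] != i2[0] and _overlap(e1[1], e2[1]):
            typ = "AF" if strand == "+" else "AL"
            lo, hi = sorted([(f1, i1[0]), (f2, i2[0])])
            yield typ, (*lo[0], *lo[1], *hi[0], *hi[1]), id1, id2
        l1, l2 = e1[-1], e2[-1]
        if l1 != l2 and not _overlap(l1, l2) and i1[-1] != i2[-1] and _overlap(e1[-2], e2[-2]):
            typ = "AL" if strand == "+" else "AF"
            lo, hi = sorted([(l1, i1[-1]), (l2, i2[-1])])
            yield typ, (*lo[0], *lo[1], *hi[0], *hi[1]), id1, id2


def enumerate_events(models: Sequence[TranscriptModel]) -> list[SplicingEvent]:
    """Enumerate deduplicated local events per locus.

    Single-transcript loci yield nothing; results are independent of input
    order (pairs are scanned in canonical transcript order and events are
    keyed on coordinates).
    """
    by_locus: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_locus.setdefault(m.locus_id or m.model_id, []).append(m)
    found: dict[tuple, SplicingEvent] = {}
    for locus_id in sorted(by_locus):
        group = sorted(by_locus[locus_id], key=lambda m: m.model_id)
        for x in range(len(group)):
            for y in range(len(group)):
                if x == y:
                    continue
                m1, m2 = group[x], group[y]
                if m1.chrom != m2.chrom or m1.strand != m2.strand:
                    continue
                for typ, coords, inc, exc in _pair_events(
                    (m1.model_id, m1.chain), (m2.model_id, m2.chain), m1.strand
                ):
                    key = (locus_id, typ, coords)
                    ev = found.get(key)
                    if ev is None:
                        ev = SplicingEvent(typ, locus_id, m1.chrom, m1.strand, coords)
                        found[key] = ev
                    ev.inclusion.add(inc)
                    ev.exclusion.add(exc)
    return sorted(
        found.values(), key=lambda e: (e.locus_id, e.event_type, e.coordinates)
    )


def events_table(events: Sequence[SplicingEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_type": e.event_type,
            "locus_id": e.locus_id,
            "chrom": e.chrom,
            "strand": e.strand,
            "coordinates": ":".join(map(str, e.coordinates)),
            "inclusion_transcripts": ",".join(sorted(e.inclusion)),
            "exclusion_transcripts": ",".join(sorted(e.exclusion)),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_type",
            "locus_id",
            "chrom",
            "strand",
            "coordinates",
            "inclusion_transcripts",
            "exclusion_transcripts",
        ],
    )


def event_counts(events: Sequence[SplicingEvent]) -> dict[str, int]:
    counts = {t: 0 for t in ("SE", "MX", "RI", "A5", "A3", "AF", "AL")}
    for e in events:
        counts[e.event_type] += 1
    return counts
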