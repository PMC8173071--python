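"""Brute-force reference implementations used only by the tests.

These deliberately use naive mechanisms (explicit base-position sets, all-
pairs scans, full EM over individual reads, exhaustive labeling enumeration)
so they stay independent of the package's optimised code paths.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np

from isoscribe.core import ExonChain, ReferenceTranscript, TranscriptModel


# ---------------------------------------------------------------------------
# class codes, via explicit genomic position sets
# ---------------------------------------------------------------------------

def _positions(exons) -> set[int]:
    out: set[int] = set()
    for s, e in exons:
        out.update(range(s, e))
    return out


def _intron_positions(chain: ExonChain) -> set[int]:
    out: set[int] = set()
    for s, e in chain.introns:
        out.update(range(s, e))
    return out


def _sub_list(sub, full) -> bool:
    sub, full = list(sub), list(full)
    if not sub:
        return True
    for i in range(len(full) - len(sub) + 1):
        if full[i : i + len(sub)] == sub:
            return True
    return False


def oracle_class_code(q: TranscriptModel, refs: list[ReferenceTranscript]) -> str:
    """Best class code by exhaustive evaluation of every code definition
    against every reference transcript, using base-position arithmetic."""
    qpos = _positions(q.chain.exons)
    qint = list(q.chain.introns)
    best = None  # (precedence, -shared, -overlap, ref_id, code)
    precedence = "=ckmnjoeiyxpsu"
    for r in refs:
        if r.chrom != q.chrom:
            continue
        rpos = _positions(r.chain.exons)
        rint = list(r.chain.introns)
        overlap = len(qpos & rpos)
        span_ov = q.chain.start < r.chain.end and r.chain.start < q.chain.end
        code = None
        if q.strand != r.strand:
            if overlap:
                code = "x"
            elif span_ov:
                code = "s"
        else:
            if overlap and qint == rint:
                code = "="
            elif overlap and qint and qint != rint and _sub_list(qint, rint) \
                    and q.chain.start >= r.chain.start and q.chain.end <= r.chain.end:
                code = "c"
            elif overlap and not qint and any(
                s <= q.chain.start and q.chain.end <= e for s, e in r.chain
            ):
                code = "c"
            elif overlap and rint and rint != qint and _sub_list(rint, qint) \
                    and r.chain.start >= q.chain.start and r.chain.end <= q.chain.end:
                code = "k"
            elif overlap and rint and q.chain.start < rint[0][0] \
                    and q.chain.end > rint[-1][1] and all(
                        _positions([iv]) <= qpos for iv in rint
                    ):
                code = "m"
            elif overlap and rint and q.chain.start < rint[0][0] \
                    and q.chain.end > rint[-1][1] and any(
                        _positions([iv]) <= qpos for iv in rint
                    ) and all(
                        _positions([iv]) <= qpos or iv in qint for iv in rint
                    ):
                code = "n"
            elif overlap and qint and rint and set(qint) & set(rint):
                code = "j"
            elif overlap and not qint and _e_code(q.chain, r.chain):
                code = "e"
            elif overlap:
                code = "o"
            elif qpos <= _intron_positions(r.chain):
                code = "i"
            elif rpos <= _intron_positions(q.chain):
                code = "y"
            elif q.strand == "+" and 0 <= q.chain.start - r.chain.end <= 2000:
                code = "p"
            elif q.strand == "-" and 0 <= r.chain.start - q.chain.end <= 2000:
                code = "p"
        if code is None:
            continue
        shared = len(set(qint) & set(rint))
        key = (precedence.index(code), -shared, -overlap, r.transcript_id)
        if best is None or key < best[0]:
            best = (key, code)
    return best[1] if best else "u"


def _e_code(qc: ExonChain, rc: ExonChain) -> bool:
    for k, (es, ee) in enumerate(rc):
        if qc.start < ee and es < qc.end:
            if k > 0 and es - qc.start >= 10:
                return True
            if k < len(rc) - 1 and qc.end - ee >= 10:
                return True
    return False


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------

def oracle_rank(m: TranscriptModel):
    return (-len(m.chain.introns), -m.support, -m.chain.span, m.chain.start)


def oracle_absorbable(a: TranscriptModel, b: TranscriptModel, tol) -> bool:
    """Naive restatement of the degradation-fragment predicate."""
    if a is b or (a.chrom, a.strand) != (b.chrom, b.strand):
        return False
    ia, ib = list(a.chain.introns), list(b.chain.introns)
    if len(ia) > len(ib):
        return False
    seg = ib[len(ib) - len(ia):] if a.strand == "+" else ib[: len(ia)]
    for (x0, x1), (y0, y1) in zip(ia, seg):
        if abs(x0 - y0) > tol.collapse_internal or abs(x1 - y1) > tol.collapse_internal:
            return False
    a3 = a.chain.end if a.strand == "+" else a.chain.start
    b3 = b.chain.end if b.strand == "+" else b.chain.start
    if abs(a3 - b3) > tol.collapse_3prime:
        return False
    k = len(ib) - len(ia)
    if a.strand == "+":
        return abs(a.chain.start - b.chain.exons[k][0]) <= tol.collapse_5prime
    return abs(a.chain.end - b.chain.exons[len(ia)][1]) <= tol.collapse_5prime


def oracle_collapse(models: list[TranscriptModel], tol) -> list[TranscriptModel]:
    """Exhaustive pairwise absorption to a fixed point, one pair at a time,
    always taking the fragment with fewest introns and its best survivor."""
    alive = list(models)
    while True:
        candidates = []
        for a in alive:
            for b in alive:
                if oracle_absorbable(a, b, tol) and oracle_rank(b) < oracle_rank(a):
                    candidates.append((len(a.chain.introns), oracle_rank(a), oracle_rank(b), a, b))
        if not candidates:
            return alive
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        _, _, _, a, b = candidates[0]
        b.support += a.support
        alive.remove(a)


# ---------------------------------------------------------------------------
# splicing events, by candidate generation + witness checking
# ---------------------------------------------------------------------------

def oracle_events(transcripts: list[tuple[str, str, ExonChain]]) -> set[tuple]:
    """(type, coords) event set for one locus, derived by generating every
    candidate coordinate tuple from the pooled exon/intron catalogue and
    checking that both forms are witnessed."""
    out: set[tuple] = set()
    items = [(tid, strand, ch) for tid, strand, ch in transcripts]
    for x, (id1, strand, c1) in enumerate(items):
        for y, (id2, _, c2) in enumerate(items):
            if x == y:
                continue
            e1, e2 = list(c1.exons), list(c2.exons)
            i1, i2 = list(c1.introns), list(c2.introns)
            for k in range(1, len(e1) - 1):
                p, q = i1[k - 1][0], i1[k][1]
                if (p, q) in i2:
                    out.add(("SE", (p, *e1[k], q)))
            for k in range(len(e1) - 1):
                s, d = e1[k]
                a, e = e1[k + 1]
                if (s, e) in e2:
                    out.add(("RI", (s, d, a, e)))
            for k in range(len(i1) - 1):
                for m in range(len(i2) - 1):
                    if i1[k][0] == i2[m][0] and i1[k + 1][1] == i2[m + 1][1]:
                        mid1 = (i1[k][1], i1[k + 1][0])
                        mid2 = (i2[m][1], i2[m + 1][0])
                        if mid1 != mid2 and (mid1[1] <= mid2[0] or mid2[1] <= mid1[0]):
                            lo, hi = sorted([mid1, mid2])
                            out.add(("MX", (i1[k][0], *lo, *hi, i1[k + 1][1])))
            for k, (d1, a1) in enumerate(i1):
                for m, (d2, a2) in enumerate(i2):
                    if a1 == a2 and d1 != d2:
                        ex1, ex2 = e1[k], e2[m]
                        if ex1[0] < ex2[1] and ex2[0] < ex1[1]:
                            typ = "A5" if strand == "+" else "A3"
                            out.add((typ, (min(d1, d2), max(d1, d2), a1)))
                    if d1 == d2 and a1 != a2:
                        ex1, ex2 = e1[k + 1], e2[m + 1]
                        if ex1[0] < ex2[1] and ex2[0] < ex1[1]:
                            typ = "A3" if strand == "+" else "A5"
                            out.add((typ, (d1, min(a1, a2), max(a1, a2))))
            if len(e1) > 1 and len(e2) > 1:
                f1, f2 = e1[0], e2[0]
                if f1 != f2 and (f1[1] <= f2[0] or f2[1] <= f1[0]) and i1[0] != i2[0] \
                        and e1[1][0] < e2[1][1] and e2[1][0] < e1[1][1]:
                    lo, hi = sorted([(tuple(f1), i1[0]), (tuple(f2), i2[0])])
                    out.add(("AF" if strand == "+" else "AL", (*lo[0], *lo[1], *hi[0], *hi[1])))
                l1, l2 = e1[-1], e2[-1]
                if l1 != l2 and (l1[1] <= l2[0] or l2[1] <= l1[0]) and i1[-1] != i2[-1] \
                        and e1[-2][0] < e2[-2][1] and e2[-2][0] < e1[-2][1]:
                    lo, hi = sorted([(tuple(l1), i1[-1]), (tuple(l2), i2[-1])])
                    out.add(("AL" if strand == "+" else "AF", (*lo[0], *lo[1], *hi[0], *hi[1])))
    return out


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def oracle_nearest(intervals, genes) -> list[int]:
    """All-pairs minimum with the bedtools distance convention."""
    out = []
    for iv in intervals:
        best = None
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            if g.start < iv.end and iv.start < g.end:
                d = 0
            elif g.start >= iv.end:
                d = g.start - iv.end + 1
            else:
                d = iv.start - g.end + 1
            best = d if best is None else min(best, d)
        out.append(-1 if best is None else best)
    return out


def oracle_exact_ranksum_p(x, y) -> float:
    """Two-sided exact p by enumerating every group labeling (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    order = sorted(pooled)
    ranks = {v: i + 1 for i, v in enumerate(order)}
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        r = sum(ranks[pooled[i]] for i in idx)
        return r - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for combo in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(combo) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def oracle_em(compat_sets: list[tuple[str, ...]], n_iter: int = 1000) -> dict[str, float]:
    """Plain per-read EM with a fixed large iteration count."""
    tids = sorted({t for s in compat_sets for t in s})
    theta = {t: 1.0 / len(tids) for t in tids}
    for _ in range(n_iter):
        counts = {t: 0.0 for t in tids}
        for s in compat_sets:
            ts = sorted(set(s))
            z = sum(theta[t] for t in ts)
            for t in ts:
                counts[t] += theta[t] / z if z > 0 else 1.0 / len(ts)
        total = sum(counts.values())
        theta = {t: c / total for t, c in counts.items()}
    return theta
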