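"""Reference-based classification of predicted transcripts.

Each model is compared against one or two reference annotations with
gffcompare-style one-letter class codes, then mapped to a novelty category:

* known_isoform — '=' against either annotation (exact intron-chain match;
  terminal ends free);
* novel_isoform — best evidence is same-strand structural overlap
  ('c', 'k', 'j', 'm', 'n' or 'o'), never '=';
* novel_locus — only intergenic/intronic/antisense codes ('i', 'u', 'y', 'x');
* artifact — only 'e', 's' or 'p' (pre-mRNA fragment, opposite-strand intron
  overlap, possible polymerase run-on).

The class-code definitions are re-implemented here with a fixed, documented
precedence; they follow the common semantics of the codes but make every
edge explicit so results are reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import ExonChain, ReferenceTranscript, TranscriptModel, three_prime

log = logging.getLogger(__name__)

#: precedence order: the highest-ranked applicable code wins
PRECEDENCE = ("=", "c", "k", "m", "n", "j", "o", "e", "i", "y", "x", "p", "s", "u")

NOVEL_ISOFORM_CODES = frozenset("ckjmno")
NOVEL_LOCUS_CODES = frozenset("iuyx")
ARTIFACT_CODES = frozenset("esp")

#: same-strand downstream window for the run-on code 'p' (bp)
P_WINDOW = 2000

#: minimum overhang into a reference intron for the pre-mRNA code 'e' (bp)
E_OVERHANG = 10


@dataclass(frozen=True)
class ClassCode:
    code: str
    matched_ref_transcript: str | None = None


class AnnotationIndex:
    """Interval-tree index of a reference annotation, by chromosome."""

    def __init__(self, transcripts: Iterable[ReferenceTranscript]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            tree[t.chain.start : t.chain.end] = t

    def near(self, chrom: str, start: int, end: int, pad: int = 0):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start - pad, end + pad)]


def _exon_overlap_bp(a: ExonChain, b: ExonChain) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _is_contiguous_subsequence(
    sub: Sequence[tuple[int, int]], full: Sequence[tuple[int, int]]
) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return n == 0
    return any(tuple(full[i : i + n]) == tuple(sub) for i in range(m - n + 1))


def _code_for_pair(q: TranscriptModel, r: ReferenceTranscript) -> str | None:
    """Class code of query ``q`` against the single reference ``r``."""
    qc, rc = q.chain, r.chain
    qi, ri = qc.introns, rc.introns
    span_overlap = qc.start < rc.end and rc.start < qc.end
    exon_bp = _exon_overlap_bp(qc, rc) if span_overlap else 0

    if q.strand != r.strand:
        if exon_bp > 0:
            return "x"
        if span_overlap:
            return "s"
        return None

    if exon_bp > 0:
        if qi == ri:
            return "="
        if qi and qi != ri and _is_contiguous_subsequence(qi, ri):
            if qc.start >= rc.start and qc.end <= rc.end:
                return "c"
        if not qi and any(s <= qc.start and qc.end <= e for s, e in rc):
            return "c"  # mono-exon query inside one reference exon
        if ri and ri != qi and _is_contiguous_subsequence(ri, qi):
            if rc.start >= qc.start and rc.end <= qc.end:
                return "k"
        if ri and qc.start < ri[0][0] and qc.end > ri[-1][1]:
            retained = [
                any(es <= s and e <= ee for es, ee in qc) for s, e in ri
            ]
            matched = [intron in qi for intron in ri]
            if all(retained):
                return "m"
            if all(rt or mt for rt, mt in zip(retained, matched)) and any(retained):
                return "n"
        if qi and ri and set(qi) & set(ri):
            return "j"
        if not qi:  # pre-mRNA fragment check before generic overlap
            for k, (es, ee) in enumerate(rc):
                if qc.start < ee and es < qc.end:
                    left_ok = k > 0 and es - qc.start >= E_OVERHANG
                    right_ok = k < len(rc) - 1 and qc.end - ee >= E_OVERHANG
                    if left_ok or right_ok:
                        return "e"
        return "o"

    if any(s <= qc.start and qc.end <= e for s, e in ri):
        return "i"
    if any(s <= rc.start and rc.end <= e for s, e in qi):
        return "y"
    # run-on: query starts within P_WINDOW downstream of the reference 3' end
    if q.strand == "+" and 0 <= qc.start - rc.end <= P_WINDOW:
        return "p"
    if q.strand == "-" and 0 <= rc.start - qc.end <= P_WINDOW:
        return "p"
    return None


def assign_class_code(model: TranscriptModel, index: AnnotationIndex) -> ClassCode:
    """Best class code of a model against one annotation.

    Among overlapping (or 2 kb-near) reference transcripts the winner has
    the highest-precedence code, ties broken by most shared intron
    boundaries, then longest exonic overlap.
    """
    best: tuple | None = None
    for r in index.near(model.chrom, model.chain.start, model.chain.end, pad=P_WINDOW):
        code = _code_for_pair(model, r)
        if code is None:
            continue
        shared = len(set(model.chain.introns) & set(r.chain.introns))
        key = (
            PRECEDENCE.index(code),
            -shared,
            -_exon_overlap_bp(model.chain, r.chain),
            r.transcript_id,
        )
        if best is None or key < best[0]:
            best = (key, code, r.transcript_id)
    if best is None:
        return ClassCode("u", None)
    return ClassCode(best[1], best[2])


def categorize(codes: Mapping[str, ClassCode]) -> str:
    """Map the per-annotation class codes to the final novelty category."""
    if not codes:
        raise ValueError("empty class-code map")
    letters = {c.code for c in codes.values()}
    if "=" in letters:
        return "known_isoform"
    if letters & NOVEL_ISOFORM_CODES:
        return "novel_isoform"
    if letters & NOVEL_LOCUS_CODES:
        return "novel_locus"
    return "artifact"


def classify_models(
    models: Sequence[TranscriptModel],
    annotations: Mapping[str, Sequence[ReferenceTranscript]],
) -> pd.DataFrame:
    """Classify every model against every annotation; one row per model."""
    indexes = {name: AnnotationIndex(ts) for name, ts in annotations.items()}
    rows = []
    for m in models:
        codes = {name: assign_class_code(m, idx) for name, idx in indexes.items()}
        row: dict = {"model_id": m.model_id, "category": categorize(codes)}
        for name, cc in codes.items():
            row[f"code_{name}"] = cc.code
            row[f"ref_{name}"] = cc.matched_ref_transcript or ""
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Single-exon retention filter
# ---------------------------------------------------------------------------

def filter_single_exon(
    models: Sequence[TranscriptModel],
    annotations: Mapping[str, Sequence[ReferenceTranscript]],
    min_support: int = 100,
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Retain single-exon models only with protein-coding exon overlap
    (same strand, either annotation) or strong read support.

    Multi-exon models pass unconditionally.  Returns (retained, removal log).
    """
    coding_exons: dict[tuple[str, str], IntervalTree] = {}
    for ts in annotations.values():
        for t in ts:
            if t.biotype != "protein_coding":
                continue
            tree = coding_exons.setdefault((t.chrom, t.strand), IntervalTree())
            for s, e in t.chain:
                tree[s:e] = True
    retained: list[TranscriptModel] = []
    removed = {"single_exon_no_coding_overlap": 0}
    for m in models:
        if not m.is_single_exon:
            retained.append(m)
            continue
        if m.support >= min_support:
            retained.append(m)
            continue
        tree = coding_exons.get((m.chrom, m.strand))
        if tree is not None and tree.overlap(m.chain.start, m.chain.end):
            retained.append(m)
        else:
            removed["single_exon_no_coding_overlap"] += 1
    log.info(
        "single-exon filter: retained %d/%d models", len(retained), len(models)
    )
    return retained, removed


# ---------------------------------------------------------------------------
# Sensitivity / precision metrics
# ---------------------------------------------------------------------------

def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _intersect_length(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    # both merged+sorted sweeps
    def merge(iv):
        out = []
        for s, e in sorted(iv):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    a, b = merge(a), merge(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _exon_catalog(transcripts) -> tuple[set, set, set]:
    """(all unique exons, 5'-free boundaries, 3'-free boundaries).

    A terminal exon is matched on its internal boundary only, so for every
    transcript the outer boundary of each terminal exon is recorded as free.
    Keys are (chrom, strand, start, end); free sets hold (chrom, strand,
    fixed_boundary) for exons whose other end may differ.
    """
    exons: set = set()
    start_free: set = set()  # genomic start is free; end must match
    end_free: set = set()
    for t in transcripts:
        ch = t.chain
        chrom, strand = t.chrom, t.strand
        for k, (s, e) in enumerate(ch):
            exons.add((chrom, strand, s, e))
            if len(ch) > 1:
                if k == 0:
                    start_free.add((chrom, strand, e))
                if k == len(ch) - 1:
                    end_free.add((chrom, strand, s))
    return exons, start_free, end_free


def _match_exons(ref_cat, pred_cat) -> int:
    """Number of reference exons with a matching predicted exon."""
    r_exons, _, _ = ref_cat
    p_exons, p_start_free, p_end_free = pred_cat
    p_exact = p_exons
    matched = 0
    for chrom, strand, s, e in r_exons:
        if (chrom, strand, s, e) in p_exact:
            matched += 1
        elif (chrom, strand, e) in p_start_free or (chrom, strand, s) in p_end_free:
            matched += 1
    return matched


def accuracy_metrics(
    predictions: Sequence[TranscriptModel],
    reference: Sequence[ReferenceTranscript],
) -> pd.DataFrame:
    """Sensitivity/precision of multi-exon predictions vs a reference.

    Levels: base (strand-aware exonic-base overlap), exon (exact coordinates,
    terminal exons matched on the internal boundary only), intron (exact),
    transcript (exact intron chain), locus (>=1 same-strand exon-overlapping
    prediction / reference).  Also reports missed/novel exon and intron
    counts.  Both sets are restricted to multi-exon entries, matching the
    usual reporting convention for spliced transcripts.
    """
    preds = [m for m in predictions if not m.is_single_exon]
    refs = [t for t in reference if len(t.chain) > 1]
    if not preds or not refs:
        raise ValueError("accuracy_metrics requires non-empty multi-exon sets")

    rows = []

    # --- base level
    by_key_ref: dict = {}
    by_key_pred: dict = {}
    for t in refs:
        by_key_ref.setdefault((t.chrom, t.strand), []).extend(t.chain)
    for m in preds:
        by_key_pred.setdefault((m.chrom, m.strand), []).extend(m.chain)
    ref_bases = sum(_merged_length(v) for v in by_key_ref.values())
    pred_bases = sum(_merged_length(v) for v in by_key_pred.values())
    inter = sum(
        _intersect_length(by_key_ref[k], by_key_pred[k])
        for k in by_key_ref.keys() & by_key_pred.keys()
    )
    rows.append(("base", 100 * inter / ref_bases, 100 * inter / pred_bases))

    # --- exon level
    ref_cat = _exon_catalog(refs)
    pred_cat = _exon_catalog(preds)
    ref_matched = _match_exons(ref_cat, pred_cat)
    pred_matched = _match_exons(pred_cat, ref_cat)
    n_ref_ex, n_pred_ex = len(ref_cat[0]), len(pred_cat[0])
    rows.append(
        ("exon", 100 * ref_matched / n_ref_ex, 100 * pred_matched / n_pred_ex)
    )

    # --- intron level
    ref_introns = {
        (t.chrom, t.strand, i) for t in refs for i in t.chain.introns
    }
    pred_introns = {
        (m.chrom, m.strand, i) for m in preds for i in m.chain.introns
    }
    shared = ref_introns & pred_introns
    rows.append(
        (
            "intron",
            100 * len(shared) / len(ref_introns),
            100 * len(shared) / len(pred_introns),
        )
    )

    # --- transcript level (exact intron chain)
    ref_chains = {(t.chrom, t.strand, t.chain.introns) for t in refs}
    pred_chains = {(m.chrom, m.strand, m.chain.introns) for m in preds}
    ref_hit = sum(
        1 for t in refs if (t.chrom, t.strand, t.chain.introns) in pred_chains
    )
    pred_hit = sum(
        1 for m in preds if (m.chrom, m.strand, m.chain.introns) in ref_chains
    )
    rows.append(
        ("transcript", 100 * ref_hit / len(refs), 100 * pred_hit / len(preds))
    )

    # --- locus level
    def overlaps_any(chain, chrom, strand, others) -> bool:
        return any(
            chrom == oc and strand == os_ and _exon_overlap_bp(chain, och) > 0
            for oc, os_, och in others
        )

    pred_view = [(m.chrom, m.strand, m.chain) for m in preds]
    ref_view = [(t.chrom, t.strand, t.chain) for t in refs]
    ref_loci: dict[str, list] = {}
    for t in refs:
        ref_loci.setdefault(t.gene_id, []).append(t)
    pred_loci: dict[str, list] = {}
    for m in preds:
        pred_loci.setdefault(m.locus_id or m.model_id, []).append(m)
    ref_loci_hit = sum(
        1
        for ts in ref_loci.values()
        if any(overlaps_any(t.chain, t.chrom, t.strand, pred_view) for t in ts)
    )
    pred_loci_hit = sum(
        1
        for ms in pred_loci.values()
        if any(overlaps_any(m.chain, m.chrom, m.strand, ref_view) for m in ms)
    )
    rows.append(
        (
            "locus",
            100 * ref_loci_hit / len(ref_loci),
            100 * pred_loci_hit / len(pred_loci),
        )
    )

    df = pd.DataFrame(rows, columns=["level", "sensitivity", "precision"])
    df.attrs["missed_exons"] = (n_ref_ex - ref_matched, n_ref_ex)
    df.attrs["novel_exons"] = (n_pred_ex - pred_matched, n_pred_ex)
    df.attrs["missed_introns"] = (
        len(ref_introns) - len(shared),
        len(ref_introns),
    )
    df.attrs["novel_introns"] = (
        len(pred_introns) - len(shared),
        len(pred_introns),
    )
    return df
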