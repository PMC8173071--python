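"""Read-to-transcript assignment and TPM estimation.

Full-length reads are assigned by structural compatibility: a read supports
a model when its intron chain is a boundary-compatible 3'-terminal
subsequence of the model's chain (5' truncation allowed — degraded reads
anchor at the more reliable 3' end).  Ambiguous reads are apportioned by an
expectation-maximisation estimator over their compatible sets, and
abundances are reported as TPM = proportion x 1e6 with no length term,
because each full-length read represents one molecule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlignedRead, ToleranceSet, TranscriptModel, is_terminal_suffix

log = logging.getLogger(__name__)


@dataclass
class CompatibilityMatrix:
    """Per-read compatible transcript sets, with sample ids."""

    read_models: dict[str, tuple[str, ...]]  # read_id -> model ids
    read_sample: dict[str, str]
    unassigned: int = 0

    def by_sample(self) -> dict[str, list[tuple[str, ...]]]:
        out: dict[str, list[tuple[str, ...]]] = {}
        for rid, models in self.read_models.items():
            out.setdefault(self.read_sample[rid], []).append(models)
        return out


def _read_compatible(
    read: AlignedRead, model: TranscriptModel, tol: ToleranceSet
) -> bool:
    if read.chrom != model.chrom or read.strand != model.strand:
        return False
    ri, mi = read.chain.introns, model.chain.introns
    if ri:
        if not is_terminal_suffix(ri, mi, read.strand, tol.cluster_internal):
            return False
        return (
            read.chain.start >= model.chain.start - tol.cluster_terminal
            and read.chain.end <= model.chain.end + tol.cluster_terminal
        )
    # single-exon read: must sit inside the model's 3'-terminal exon
    term = model.chain.exons[-1] if read.strand == "+" else model.chain.exons[0]
    return (
        read.chain.start >= term[0] - tol.cluster_terminal
        and read.chain.end <= term[1] + tol.cluster_terminal
    )


def build_compatibility(
    reads: list[AlignedRead],
    models: list[TranscriptModel],
    tol: ToleranceSet = ToleranceSet(),
) -> CompatibilityMatrix:
    """Compute each read's compatible model set (3'-anchored matching)."""
    by_group: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        by_group.setdefault((m.chrom, m.strand), []).append(m)
    read_models: dict[str, tuple[str, ...]] = {}
    read_sample: dict[str, str] = {}
    unassigned = 0
    for r in reads:
        compatible = tuple(
            m.model_id
            for m in by_group.get((r.chrom, r.strand), ())
            if _read_compatible(r, m, tol)
        )
        read_sample[r.read_id] = r.sample_id
        if compatible:
            read_models[r.read_id] = compatible
        else:
            unassigned += 1
    log.info(
        "compatibility: %d/%d reads assigned", len(read_models), len(reads)
    )
    return CompatibilityMatrix(read_models, read_sample, unassigned)


def em_abundance(
    compat_sets: list[tuple[str, ...]],
    max_iter: int = 100,
    rel_tol: float = 1e-6,
) -> dict[str, float]:
    """EM proportions for one sample's compatible sets.

    Reads with identical compatible sets are pooled into weighted equivalence
    classes; proportions are initialised uniform over transcripts with at
    least one compatible read and iterated to relative convergence.
    """
    if not compat_sets:
        log.warning("em_abundance: no assigned reads")
        return {}
    classes: dict[tuple[str, ...], int] = {}
    for s in compat_sets:
        key = tuple(sorted(set(s)))
        classes[key] = classes.get(key, 0) + 1
    tids = sorted({t for key in classes for t in key})
    idx = {t: i for i, t in enumerate(tids)}
    n_reads = sum(classes.values())
    class_members = [np.array([idx[t] for t in key]) for key in classes]
    class_counts = np.array(list(classes.values()), dtype=float)

    theta = np.full(len(tids), 1.0 / len(tids))
    for _ in range(max_iter):
        counts = np.zeros(len(tids))
        for members, c in zip(class_members, class_counts):
            w = theta[members]
            total = w.sum()
            if total <= 0:
                w = np.full(len(members), 1.0 / len(members))
                total = 1.0
            counts[members] += c * w / total
        new_theta = counts / n_reads
        delta = np.abs(new_theta - theta).max() / max(theta.max(), 1e-300)
        theta = new_theta
        if delta < rel_tol:
            break
    return {t: float(theta[i]) for t, i in idx.items()}


def em_log_likelihood(
    compat_sets: list[tuple[str, ...]], proportions: dict[str, float]
) -> float:
    """Log-likelihood of the full-length generative model (for diagnostics)."""
    ll = 0.0
    for s in compat_sets:
        p = sum(proportions.get(t, 0.0) for t in set(s))
        ll += np.log(max(p, 1e-300))
    return float(ll)


def to_tpm(proportions: dict[str, float]) -> dict[str, float]:
    """TPM = proportion x 1e6 (full-length counting, no length term)."""
    return {t: p * 1e6 for t, p in proportions.items()}


def quantify(
    reads: list[AlignedRead],
    models: list[TranscriptModel],
    sample_ids: list[str],
    tol: ToleranceSet = ToleranceSet(),
    max_iter: int = 100,
    rel_tol: float = 1e-6,
) -> "ExpressionMatrix":
    """Per-sample EM quantification of all models; returns counts and TPM."""
    compat = build_compatibility(reads, models, tol)
    model_ids = [m.model_id for m in models]
    counts = pd.DataFrame(0.0, index=model_ids, columns=sample_ids)
    tpm = pd.DataFrame(0.0, index=model_ids, columns=sample_ids)
    for sample, sets in compat.by_sample().items():
        if sample not in counts.columns:
            continue
        props = em_abundance(sets, max_iter=max_iter, rel_tol=rel_tol)
        n = len(sets)
        for t, p in props.items():
            counts.loc[t, sample] = p * n
            tpm.loc[t, sample] = p * 1e6
    return ExpressionMatrix(counts=counts, tpm=tpm, unassigned=compat.unassigned)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance (estimated counts and TPM)."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    unassigned: int = 0
    metadata: pd.DataFrame | None = None
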