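"""Positional statistics: end-overlap fractions, interval permutation null,
nearest-gene distances and the Mann-Whitney rank-sum test.

The intergenic-proximity test asks whether predicted intergenic transcripts
sit closer to annotated genes than expected: observed intervals are
re-placed uniformly at random on the genome (excluding annotated gene
space), nearest-gene distances are computed for both sets, and the two
distance samples are compared with a two-sided Mann-Whitney U test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomicInterval, ReferenceTranscript, TranscriptModel, five_prime, three_prime
from intervaltree import IntervalTree


# ---------------------------------------------------------------------------
# 5'/3' end overlap statistics
# ---------------------------------------------------------------------------

def end_overlap_stats(
    models: Sequence[TranscriptModel],
    reference_sets: Sequence[tuple[str, Sequence[tuple[str, str, int]]]],
    window: int = 100,
    near_kb: int = 2,
    matched_ref_ends: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-position concordance of predicted models with reference end sets.

    ``reference_sets`` holds named lists of (chrom, strand, position) 5'
    ends; a model's 5' end counts as overlapping when within ``window`` bp
    of any same-strand reference end.  When ``matched_ref_ends`` maps a
    model id to its matched reference (tss, tes), the fraction of models
    starting/ending within ``near_kb`` kb of the matched ends and the signed
    TSS offsets (positive = model downstream of reference) are reported.

    Returns (per-set summary, per-model matched-end table).
    """
    near = near_kb * 1000
    rows = []
    for name, ends in reference_sets:
        if not ends:
            rows.append({"set": name, "n_models": len(models), "fraction_tss_overlap": float("nan")})
            continue
        by_key: dict[tuple[str, str], list[int]] = {}
        for chrom, strand, pos in ends:
            by_key.setdefault((chrom, strand), []).append(pos)
        arrays = {k: np.sort(np.array(v)) for k, v in by_key.items()}
        n_hit = 0
        for m in models:
            arr = arrays.get((m.chrom, m.strand))
            if arr is None:
                continue
            j = np.searchsorted(arr, m.tss)
            cands = arr[max(0, j - 1) : j + 1]
            if cands.size and np.min(np.abs(cands - m.tss)) <= window:
                n_hit += 1
        rows.append(
            {
                "set": name,
                "n_models": len(models),
                "fraction_tss_overlap": n_hit / len(models) if models else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)

    matched_rows = []
    if matched_ref_ends:
        for m in models:
            if m.model_id not in matched_ref_ends:
                continue
            ref_tss, ref_tes = matched_ref_ends[m.model_id]
            sign = 1 if m.strand == "+" else -1
            matched_rows.append(
                {
                    "model_id": m.model_id,
                    "tss_offset": sign * (m.tss - ref_tss),
                    "tes_offset": sign * (m.tes - ref_tes),
                    "tss_within": abs(m.tss - ref_tss) <= near,
                    "tes_within": abs(m.tes - ref_tes) <= near,
                }
            )
    matched = pd.DataFrame(
        matched_rows,
        columns=["model_id", "tss_offset", "tes_offset", "tss_within", "tes_within"],
    )
    return summary, matched


# ---------------------------------------------------------------------------
# Interval shuffling (permutation null)
# ---------------------------------------------------------------------------

def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    excluded: Sequence[GenomicInterval] = (),
    seed: int | np.random.Generator = 0,
    same_chrom: bool = False,
    max_tries: int = 10000,
) -> list[GenomicInterval]:
    """Re-place each interval uniformly at random, preserving its length.

    Placements overlapping ``excluded`` regions are rejection-sampled away.
    By default intervals may move genome-wide (chromosome chosen with
    probability proportional to its length); ``same_chrom`` keeps each on
    its original chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trees: dict[str, IntervalTree] = {}
    for iv in excluded:
        trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end] = True
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    out = []
    for iv in intervals:
        size = len(iv)
        placed = None
        for _ in range(max_tries):
            if same_chrom:
                chrom = iv.chrom
            else:
                chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
            limit = genome[chrom] - size
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(start, start + size):
                continue
            placed = GenomicInterval(chrom, start, start + size, iv.strand)
            break
        if placed is None:
            raise RuntimeError(
                f"could not place interval {iv.chrom}:{iv.start}-{iv.end} "
                f"after {max_tries} tries"
            )
        out.append(placed)
    return out


# ---------------------------------------------------------------------------
# Nearest-gene distance
# ---------------------------------------------------------------------------

def nearest_gene_distance(
    intervals: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
) -> np.ndarray:
    """Distance (bp) from each interval to its nearest gene, strand-agnostic.

    Follows the bedtools ``closest -d`` convention: overlapping features are
    at distance 0 and book-ended features at distance 1.  Intervals on a
    chromosome with no gene get distance -1 (bedtools' "no hit" marker).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {g.chrom for g in genes}:
        gs = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
        starts[chrom] = np.array([s for s, _ in gs])
        ends[chrom] = np.array([e for _, e in gs])
    out = np.empty(len(intervals), dtype=np.int64)
    for k, iv in enumerate(intervals):
        if iv.chrom not in starts:
            out[k] = -1
            continue
        s_arr, e_arr = starts[iv.chrom], ends[iv.chrom]
        # overlap if any gene with start < iv.end and end > iv.start
        j = np.searchsorted(s_arr, iv.end)  # genes starting before iv.end
        if j > 0 and np.max(e_arr[:j]) > iv.start:
            out[k] = 0
            continue
        best = np.iinfo(np.int64).max
        if j < len(s_arr):  # nearest gene to the right
            best = min(best, int(s_arr[j] - iv.end) + 1)
        if j > 0:  # nearest gene end to the left
            best = min(best, int(iv.start - np.max(e_arr[:j])) + 1)
        out[k] = best
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    U: float
    n1: int
    n2: int
    p_value: float
    method: str


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Mann-Whitney U test with midranks.

    Exact enumeration over all C(n1+n2, n1) group labelings when
    n1 + n2 <= 12 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples need at least one observation")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2

    if np.all(pooled == pooled[0]):
        return RankSumResult(u1, n1, n2, 1.0, "degenerate")

    if n1 + n2 <= 12 and not has_ties:
        order = sps.rankdata(pooled)  # a permutation of 1..n, no ties
        n = n1 + n2
        stat_obs = abs(u1 - mu)
        hits = total = 0
        all_ranks = np.arange(1, n + 1)
        for combo in combinations(range(n), n1):
            r = all_ranks[list(combo)].sum()
            u = r - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= stat_obs - 1e-9:
                hits += 1
        return RankSumResult(u1, n1, n2, hits / total, "exact")

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return RankSumResult(u1, n1, n2, 1.0, "degenerate")
    # continuity correction toward the mean
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(sigma2)
    p = min(1.0, 2 * sps.norm.sf(abs(z)))
    return RankSumResult(u1, n1, n2, float(p), "normal_approx")


def intergenic_proximity_test(
    intergenic: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    seed: int = 0,
) -> dict:
    """The headline permutation test: observed vs shuffled nearest-gene
    distances, compared by rank sum (genome-wide shuffling, gene space
    excluded)."""
    shuffled = shuffle_intervals(
        intergenic, genome, excluded=genes, seed=seed, same_chrom=False
    )
    d_obs = nearest_gene_distance(intergenic, genes)
    d_null = nearest_gene_distance(shuffled, genes)
    keep_obs = d_obs[d_obs >= 0]
    keep_null = d_null[d_null >= 0]
    res = rank_sum_test(keep_obs, keep_null)
    return {
        "mean_observed_distance": float(keep_obs.mean()),
        "mean_shuffled_distance": float(keep_null.mean()),
        "U": res.U,
        "p_value": res.p_value,
        "method": res.method,
        "n_observed": len(keep_obs),
        "n_shuffled": len(keep_null),
    }


def model_ends(
    transcripts: Sequence[ReferenceTranscript] | Sequence[TranscriptModel],
) -> list[tuple[str, str, int]]:
    """(chrom, strand, 5' end) triples of a transcript set."""
    out = []
    for t in transcripts:
        out.append((t.chrom, t.strand, five_prime(t.chain, t.strand)))
    return out
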