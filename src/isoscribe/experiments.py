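"""Calibration and recovery experiments run under controlled conditions.

These are the study-condition checks the pipeline's claims rest on:
estimator accuracy of the EM quantifier, specificity-index recovery under
replicate noise, type-I calibration of the rank-sum test, and uniformity of
the interval shuffle.  Each is a plain function of a seed so the same
computation backs both the test suite and the acceptance script.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .core import GenomicInterval
from .quantify import em_abundance
from .specificity import tsi
from .structure import rank_sum_test, shuffle_intervals


def em_recovery_experiment(
    seed: int,
    proportions: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1),
    n_reads: int = 1000,
    n_samples: int = 8,
    ambiguity: float = 0.5,
) -> dict:
    """Mean relative error of EM-estimated vs designed proportions.

    Reads are drawn from the designed mixture; each read is compatible with
    its source transcript and, with probability ``ambiguity``, also with a
    suffix-sharing partner (transcripts are paired), mimicking 3'-anchored
    compatibility of degraded reads.  Estimates are averaged over replicate
    samples of ``n_reads`` reads before comparing to the design.
    """
    rng = np.random.default_rng(seed)
    tids = [f"T{i}" for i in range(len(proportions))]
    partner = {
        tids[i]: tids[i + 1 if i % 2 == 0 else i - 1] for i in range(len(tids))
    }
    estimates = np.zeros((n_samples, len(tids)))
    for s in range(n_samples):
        sources = rng.choice(len(tids), size=n_reads, p=np.asarray(proportions))
        sets = []
        for src in sources:
            t = tids[src]
            if rng.random() < ambiguity:
                sets.append((t, partner[t]))
            else:
                sets.append((t,))
        props = em_abundance(sets, max_iter=500, rel_tol=1e-9)
        estimates[s] = [props.get(t, 0.0) for t in tids]
    mean_est = estimates.mean(axis=0)
    rel_err = np.abs(mean_est - np.asarray(proportions)) / np.asarray(proportions)
    return {
        "mean_relative_error_pct": float(100 * rel_err.mean()),
        "max_relative_error_pct": float(100 * rel_err.max()),
        "n_reads_per_sample": n_reads,
        "n_samples": n_samples,
    }


def tsi_noise_experiment(
    seed: int,
    n_transcripts: int = 200,
    n_tissues: int = 5,
    n_replicates: int = 2,
    noise: float = 0.2,
) -> dict:
    """Designed single-tissue transcripts under multiplicative replicate
    noise with exact off-tissue zeros: TSI of the tissue means stays 1,
    hence always >= the 0.8 specificity threshold."""
    rng = np.random.default_rng(seed)
    n_pass = 0
    min_tsi = 1.0
    for _ in range(n_transcripts):
        home = int(rng.integers(n_tissues))
        reps = 50.0 * (1 + rng.uniform(-noise, noise, size=n_replicates))
        x = np.zeros(n_tissues)
        x[home] = reps.mean()
        value = tsi(x)
        min_tsi = min(min_tsi, value)
        if value >= 0.8:
            n_pass += 1
    return {
        "n_transcripts": n_transcripts,
        "recovery_pct": 100.0 * n_pass / n_transcripts,
        "min_tsi": min_tsi,
    }


def ranksum_type1_experiment(
    seed: int, n_sims: int = 2000, n: int = 20, alpha: float = 0.05
) -> dict:
    """Empirical type-I error of the two-sided rank-sum test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rank_sum_test(x, y).p_value < alpha:
            rejections += 1
    return {"n_sims": n_sims, "alpha": alpha, "type1_rate": rejections / n_sims}


def shuffle_uniformity_experiment(
    seed: int,
    n_intervals: int = 1000,
    genome: dict[str, int] | None = None,
) -> dict:
    """Chi-square goodness of fit of shuffled placements against
    length-proportional chromosome expectation."""
    genome = genome or {"chr1": 100_000, "chr2": 60_000, "chr3": 40_000}
    placed = shuffle_intervals(
        [GenomicInterval("chr1", 0, 100)] * n_intervals, genome, seed=seed
    )
    chroms = sorted(genome)
    counts = np.array([sum(1 for iv in placed if iv.chrom == c) for c in chroms])
    total_len = sum(genome.values())
    expected = np.array([n_intervals * genome[c] / total_len for c in chroms])
    chi2, p = sps.chisquare(counts, expected)
    return {
        "n_intervals": n_intervals,
        "chi2": float(chi2),
        "p_value": float(p),
        "counts": counts.tolist(),
        "expected": expected.tolist(),
    }
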