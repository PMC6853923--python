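"""Per-sample clonality, analytic rarefaction, and cohort clone census."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import Cohort, RepertoireSample

__all__ = ["RarefactionCurve", "rarefy", "clonality", "unique_clone_census"]


@dataclass
class RarefactionCurve:
    """Expected unique-clonotype counts at reduced sampling depths.

    ``expected_unique[i]`` is E[number of distinct clonotypes seen in a
    without-replacement subsample of ``depths[i]`` reads].
    """

    depths: np.ndarray
    expected_unique: np.ndarray
    total_reads: int
    total_unique: int


def default_depths(total_reads: int, n_points: int = 20) -> np.ndarray:
    """Log-spaced integer depths from 1 to the full read count."""
    grid = np.unique(
        np.round(np.logspace(0, np.log10(total_reads), n_points)).astype(int)
    )
    return np.clip(grid, 1, total_reads)


def rarefy(sample: RepertoireSample, depths=None) -> RarefactionCurve:
    """Hypergeometric rarefaction: exact E[S_m] without resampling.

    For clone counts ``n_i`` summing to N, the expected richness at depth m
    is ``sum_i (1 - C(N - n_i, m) / C(N, m))``; the binomial ratios are
    evaluated as differences of log-gamma terms for numerical stability.
    """
    counts = sample.counts.astype(np.int64)
    n_total = int(counts.sum())
    if n_total == 0:
        raise ValueError("cannot rarefy an empty sample")
    depths = default_depths(n_total) if depths is None else np.asarray(depths, dtype=np.int64)
    if (depths < 1).any() or (depths > n_total).any():
        raise ValueError(f"depths must lie in [1, {n_total}]")

    expected = np.empty(len(depths), dtype=float)
    for k, m in enumerate(depths):
        rem = n_total - counts  # reads left if clone i is excluded entirely
        feasible = rem >= m  # otherwise C(rem, m) = 0 and the clone is certain
        log_miss = np.full(len(counts), -np.inf)
        r = rem[feasible].astype(float)
        log_miss[feasible] = (
            gammaln(r + 1)
            - gammaln(r - m + 1)
            - (gammaln(n_total + 1) - gammaln(n_total - m + 1))
        )
        expected[k] = float(np.sum(1.0 - np.exp(log_miss)))
    return RarefactionCurve(depths, expected, n_total, int(len(counts)))


def clonality(sample: RepertoireSample) -> float:
    """1 - Pielou evenness: 0 for a perfectly even repertoire, 1 for monoclonal.

    Defined as ``1 - H / ln(S)`` with H the Shannon entropy of clone
    frequencies and S the clonotype count; a single-clone sample returns 1.0
    by convention.
    """
    freqs = sample.frequencies
    s = len(freqs)
    if s == 0:
        raise ValueError("clonality undefined for an empty sample")
    if s == 1:
        return 1.0
    h = -float(np.sum(freqs * np.log(freqs)))
    return 1.0 - h / np.log(s)


def unique_clone_census(cohort: Cohort) -> tuple[int, float]:
    """Cohort-wide clonotype tally keyed by CDR3 nucleotide sequence.

    Returns the number of distinct clonotypes across all samples and the
    fraction of them observed in two or more samples.
    """
    if not cohort:
        raise ValueError("empty cohort")
    seen: dict[str, int] = {}
    for sample in cohort.values():
        for nt in sample.clones["cdr3_nt"]:
            seen[nt] = seen.get(nt, 0) + 1
    total = len(seen)
    multi = sum(1 for n in seen.values() if n >= 2)
    return total, multi / total if total else 0.0
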