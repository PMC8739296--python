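"""Percent-rank dispersion summaries of per-cell lipid-body counts.

Per-cell LB counts are heavily tied, strongly right-skewed integers (most
cells show zero LBs in the focal plane, a few show up to ~20), so
dispersion is reported with empirical percentiles rather than standard
deviations.  The nearest-rank percentile convention is used throughout:
percentile P of n sorted values is the value at index ⌈P/100·n⌉ (1-based),
which makes ties visible — on heavily tied data many percentiles "fall
together" on the same count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np


def star_code(p: float) -> str:
    """Significance stars: *p < 0.05, **p < 0.01, ***p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PercentRankSummary:
    """Percent-rank location/dispersion summary of one group's counts."""

    sorted_counts: np.ndarray
    median: float
    mean: float
    box_25_75: Tuple[float, float]
    box_5_95: Tuple[float, float]
    n: int

    def percentile(self, p: float) -> float:
        """Nearest-rank empirical percentile; p in [0, 100]."""
        if not 0 <= p <= 100:
            raise ValueError("percentile must be in [0, 100]")
        if p == 0:
            return float(self.sorted_counts[0])
        rank = int(np.ceil(p / 100.0 * self.n))
        return float(self.sorted_counts[max(rank, 1) - 1])


def percent_rank(counts: Sequence[int]) -> PercentRankSummary:
    """Build the percent-rank summary of a group's per-cell LB counts."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    s = np.sort(arr.astype(float))
    n = int(s.size)

    def nearest_rank(p: float) -> float:
        if p == 0:
            return float(s[0])
        return float(s[max(int(np.ceil(p / 100.0 * n)), 1) - 1])

    return PercentRankSummary(
        sorted_counts=s,
        median=nearest_rank(50),
        mean=float(s.mean()),
        box_25_75=(nearest_rank(25), nearest_rank(75)),
        box_5_95=(nearest_rank(5), nearest_rank(95)),
        n=n,
    )


def count_histogram(counts: Sequence[int]) -> Dict[int, int]:
    """Exact integer histogram of LB counts, reporting empty bins up to the max."""
    arr = np.asarray(counts, dtype=int)
    if arr.size == 0:
        return {}
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    bins = np.bincount(arr)
    return {i: int(v) for i, v in enumerate(bins)}


def zero_fraction(counts: Sequence[int]) -> float:
    """Fraction of cells with zero LBs in the focal plane."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty input")
    return float(np.count_nonzero(arr == 0) / arr.size)
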