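"""Two-factor peak co-occupancy: Venn decomposition, overlap matching,
and rank correlation of matched peak intensities.

A transcription factor and an obligate dimerisation partner that binds
DNA only through it should occupy largely the same sites with correlated
binding strength. Given two peak sets scored against their own coverage
tracks, this module reports (i) the one-sided Venn overlap counts
(how many A peaks touch at least one B peak, and vice versa), (ii) a
deterministic one-to-one pairing of overlapping peaks by maximal shared
bases, and (iii) the Spearman correlation of the paired intensities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .coverage import CoverageTrack, peak_intensity
from .intervals import GenomicInterval, shared_bases

__all__ = [
    "Peak",
    "VennCounts",
    "score_peaks",
    "venn_decompose",
    "match_overlapping_peaks",
    "spearman_correlation",
    "format_pvalue",
]

#: Display floor for p-values below double precision, the convention used
#: when a test statistic is effectively off the scale.
PVALUE_DISPLAY_FLOOR = 2.2e-16


@dataclass(frozen=True)
class Peak:
    """A called peak, optionally scored with a tag-count intensity."""

    interval: GenomicInterval
    factor: str = ""
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class VennCounts:
    """One-sided overlap bookkeeping for two peak sets."""

    total_a: int
    total_b: int
    a_overlapping_b: int
    b_overlapping_a: int

    def __post_init__(self) -> None:
        if not (0 <= self.a_overlapping_b <= self.total_a):
            raise ValueError("a_overlapping_b out of range")
        if not (0 <= self.b_overlapping_a <= self.total_b):
            raise ValueError("b_overlapping_a out of range")

    @property
    def fraction_a(self) -> float:
        """Fraction of A peaks that overlap >=1 B peak."""
        return self.a_overlapping_b / self.total_a if self.total_a else 0.0

    @property
    def fraction_b(self) -> float:
        return self.b_overlapping_a / self.total_b if self.total_b else 0.0

    @property
    def percent_a(self) -> int:
        """fraction_a as the nearest integer percent, for display."""
        return round(self.fraction_a * 100)

    @property
    def percent_b(self) -> int:
        return round(self.fraction_b * 100)


def score_peaks(
    peaks: Sequence[GenomicInterval], cov: CoverageTrack, factor: str = ""
) -> list[Peak]:
    """Attach intensities (per-base tag sums) to raw peak intervals."""
    return [Peak(p, factor, peak_intensity(p, cov)) for p in peaks]


def _interval_of(p: Peak | GenomicInterval) -> GenomicInterval:
    return p.interval if isinstance(p, Peak) else p


def _overlap_index(intervals: Sequence[GenomicInterval]):
    """chrom -> (sorted starts, sorted ends, original indices) for sweep queries."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        idx = np.array([r[2] for r in rows], dtype=np.int64)
        # max end among the first k sorted intervals: lets a query prune by start
        max_end = np.maximum.accumulate(ends)
        out[chrom] = (starts, ends, idx, max_end)
    return out


def _overlappers(index, iv: GenomicInterval) -> list[int]:
    entry = index.get(iv.chrom)
    if entry is None:
        return []
    starts, ends, idx, _max_end = entry
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    hits = np.nonzero(ends[:hi] > iv.start)[0]
    return [int(idx[h]) for h in hits]


def venn_decompose(
    peaks_a: Sequence[Peak | GenomicInterval],
    peaks_b: Sequence[Peak | GenomicInterval],
) -> VennCounts:
    """Count, for each set, the peaks overlapping >=1 peak of the other set.

    Counts are peak-centric and one-sided: an A peak overlapping three B
    peaks counts once toward ``a_overlapping_b``. The two sides need not
    agree (peak widths differ), which is why both are reported.
    """
    ivs_a = [_interval_of(p) for p in peaks_a]
    ivs_b = [_interval_of(p) for p in peaks_b]
    index_a = _overlap_index(ivs_a)
    index_b = _overlap_index(ivs_b)
    a_hits = sum(1 for iv in ivs_a if _overlappers(index_b, iv))
    b_hits = sum(1 for iv in ivs_b if _overlappers(index_a, iv))
    return VennCounts(len(ivs_a), len(ivs_b), a_hits, b_hits)


def match_overlapping_peaks(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> list[tuple[Peak, Peak]]:
    """One-to-one pairing of overlapping peaks by maximal shared bases.

    Candidate (A, B) overlaps are ranked by shared bases (descending),
    breaking ties by the leftmost A interval then the leftmost B interval,
    and accepted greedily so that every peak is used at most once. The
    result is sorted by A coordinate and is deterministic for identical
    input.
    """
    ivs_b = [_interval_of(p) for p in peaks_b]
    index_b = _overlap_index(ivs_b)
    candidates: list[tuple[int, tuple, tuple, int, int]] = []
    for ai, pa in enumerate(peaks_a):
        iva = _interval_of(pa)
        for bi in _overlappers(index_b, iva):
            ivb = ivs_b[bi]
            sb = shared_bases(iva, ivb)
            candidates.append(
                (
                    -sb,
                    (iva.chrom, iva.start, iva.end),
                    (ivb.chrom, ivb.start, ivb.end),
                    ai,
                    bi,
                )
            )
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _negsb, _ka, _kb, ai, bi in candidates:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        pairs.append((ai, bi))
    pairs.sort(key=lambda ab: (_interval_of(peaks_a[ab[0]]).chrom,
                               _interval_of(peaks_a[ab[0]]).start,
                               _interval_of(peaks_a[ab[0]]).end))
    return [(peaks_a[ai], peaks_b[bi]) for ai, bi in pairs]


# ---------------------------------------------------------------------------
# Spearman correlation

EXACT_PERMUTATION_MAX_N = 10


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson product-moment correlation of average-tied ranks.
    For n > 10 the p-value uses the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho**2))`` with n - 2 degrees of
    freedom; for n <= 10 it is exact, by full enumeration of the n!
    permutations of one rank vector.

    Raises
    ------
    ValueError
        If the vectors differ in length, have n < 3, or either is constant
        (rho undefined).
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant vector")

    rx = _average_ranks(xa)
    ry = _average_ranks(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_pvalue(rx, ry, rho)
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _exact_permutation_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """P(|rho_perm| >= |rho_obs|) over all permutations of one rank vector.

    With the rank vectors fixed, rho is an affine function of the dot
    product rx . permuted(ry), so the permutation distribution is computed
    from dot products alone, in chunks to bound memory.
    """
    n = rx.size
    sx, sy = np.std(rx), np.std(ry)
    mx, my = np.mean(rx), np.mean(ry)
    total = math.factorial(n)
    target = abs(rho_obs) - 1e-12
    count = 0
    chunk = 40320  # 8! rows per matmul
    buf = np.empty((chunk, n), dtype=np.float64)
    filled = 0

    def flush(k: int) -> int:
        dots = buf[:k] @ rx
        rhos = (dots / n - mx * my) / (sx * sy)
        return int(np.sum(np.abs(rhos) >= target))

    for perm in itertools.permutations(ry):
        buf[filled] = perm
        filled += 1
        if filled == chunk:
            count += flush(filled)
            filled = 0
    if filled:
        count += flush(filled)
    return count / total


def format_pvalue(p: float, floor: float = PVALUE_DISPLAY_FLOOR) -> str:
    """Human-readable p-value with the conventional '< 2.2e-16' floor."""
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3g}"
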