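"""Per-base tag coverage as a step function, backed by bedGraph segments.

A :class:`CoverageTrack` maps every base of every chromosome to a
non-negative tag count; bases outside any declared segment have coverage
zero. Per-peak sums (the binding-strength statistic) are computed by
segment arithmetic — overlap length x segment value — which is exact and
avoids materialising per-base arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .intervals import GenomicInterval, _open_text

__all__ = ["CoverageTrack", "peak_intensity", "read_bedgraph", "write_bedgraph"]


@dataclass(frozen=True)
class _ChromCoverage:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray    # int64, ends[i] > starts[i], non-overlapping
    values: np.ndarray  # float64, >= 0


class CoverageTrack:
    """Step-function coverage over chromosomes.

    Parameters
    ----------
    segments
        Mapping chrom -> iterable of (start, end, value) in 0-based
        half-open coordinates. Segments must be non-overlapping; they are
        sorted on construction.
    """

    def __init__(
        self, segments: Mapping[str, Iterable[tuple[int, int, float]]]
    ) -> None:
        self._chroms: dict[str, _ChromCoverage] = {}
        for chrom, segs in segments.items():
            rows = sorted(segs)
            if not rows:
                continue
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted coverage segment")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping coverage segments")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage value")
            self._chroms[chrom] = _ChromCoverage(starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def value_at(self, chrom: str, pos: int) -> float:
        """Tag count at a single base (0 outside declared segments)."""
        cc = self._chroms.get(chrom)
        if cc is None:
            return 0.0
        i = int(np.searchsorted(cc.starts, pos, side="right")) - 1
        if i >= 0 and pos < cc.ends[i]:
            return float(cc.values[i])
        return 0.0

    def interval_sum(self, interval: GenomicInterval) -> float:
        """Sum of per-base tag counts over ``[start, end)``.

        Equals ``sum(value_at(chrom, p) for p in range(start, end))`` exactly,
        computed as sum over segments of (overlap length x value).
        """
        cc = self._chroms.get(interval.chrom)
        if cc is None:
            return 0.0
        lo = int(np.searchsorted(cc.ends, interval.start, side="right"))
        hi = int(np.searchsorted(cc.starts, interval.end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(cc.ends[lo:hi], interval.end) - np.maximum(
            cc.starts[lo:hi], interval.start
        )
        return float(np.sum(ov * cc.values[lo:hi]))

    def segments(self, chrom: str) -> list[tuple[int, int, float]]:
        cc = self._chroms.get(chrom)
        if cc is None:
            return []
        return [
            (int(s), int(e), float(v))
            for s, e, v in zip(cc.starts, cc.ends, cc.values)
        ]


def peak_intensity(peak: GenomicInterval, cov: CoverageTrack) -> float:
    """Peak intensity: the per-base tag counts summed across the peak."""
    return cov.interval_sum(peak)


def read_bedgraph(path: str | Path) -> CoverageTrack:
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[:4]
            segments.setdefault(chrom, []).append(
                (int(start), int(end), float(value))
            )
    return CoverageTrack(segments)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else repr(v)

    with _open_text(path, "wt") as fh:
        for chrom in track.chroms:
            for start, end, value in track.segments(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{fmt(value)}\n")
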