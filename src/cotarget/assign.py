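"""Strand-aware assignment of peaks to transcripts and genes.

Three zones around each transcript, in precedence order:

* **promoter** — TSS - W_prom to TSS + W_prom (default 5 kb each side),
  anchored at the strand-aware TSS;
* **gene_body** — the rest of the transcript span;
* **distal** — anywhere within W_dist (default 25 kb, strictly less than)
  of the nearest transcript edge.

A peak may hit several genes (each is reported); per gene only the best
assignment across its transcripts is kept (promoter > gene_body > distal,
then smallest distance). "Bound genes" are genes with at least one
assignment of any category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .intervals import (
    GenomicInterval,
    TranscriptModel,
    gap_distance,
    overlaps,
)

__all__ = [
    "AssignmentConfig",
    "PeakAssignment",
    "classify_peak_vs_transcript",
    "assign_peaks",
    "collapse_to_genes",
]

CATEGORY_ORDER = {"promoter": 0, "gene_body": 1, "distal": 2}


@dataclass(frozen=True)
class AssignmentConfig:
    """Window widths, in bp."""

    promoter_flank: int = 5000
    distal_limit: int = 25000

    def __post_init__(self) -> None:
        if self.promoter_flank <= 0:
            raise ValueError("promoter_flank must be > 0")
        if self.promoter_flank > self.distal_limit:
            raise ValueError("promoter_flank must be <= distal_limit")


@dataclass(frozen=True)
class PeakAssignment:
    peak: GenomicInterval
    gene_id: str
    transcript_id: str
    category: str  # promoter | gene_body | distal
    distance: int  # 0 for promoter/gene_body; gap to transcript edge for distal

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown category {self.category!r}")


def _promoter_window(tx: TranscriptModel, cfg: AssignmentConfig) -> GenomicInterval:
    # Symmetric in genomic bp around the strand-aware TSS; the strand decides
    # only where the TSS sits, since the window extends both ways equally.
    lo = max(0, tx.tss - cfg.promoter_flank)
    hi = tx.tss + cfg.promoter_flank
    return GenomicInterval(tx.interval.chrom, lo, hi)


def classify_peak_vs_transcript(
    peak: GenomicInterval, tx: TranscriptModel, cfg: AssignmentConfig | None = None
) -> tuple[str, int] | None:
    """Classify one peak against one transcript.

    Returns ``(category, distance)`` or None if the peak is farther than
    the distal limit (or on another chromosome). Distance is 0 for
    promoter and gene_body hits, and the gap to the nearest transcript
    edge for distal hits (strictly below ``distal_limit``).
    """
    cfg = cfg or AssignmentConfig()
    if peak.chrom != tx.interval.chrom:
        return None
    if overlaps(peak, _promoter_window(tx, cfg)):
        return ("promoter", 0)
    if overlaps(peak, tx.interval):
        return ("gene_body", 0)
    d = gap_distance(peak, tx.interval)
    if d < cfg.distal_limit:
        return ("distal", d)
    return None


def assign_peaks(
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    cfg: AssignmentConfig | None = None,
) -> tuple[list[PeakAssignment], set[str]]:
    """Assign every peak to every transcript whose windows it falls in.

    Returns all transcript-level assignments (a peak may hit several genes)
    and the bound-gene set. Candidate transcripts are found through an
    interval tree over transcript spans padded by the distal limit, so each
    peak query costs O(log n + k).
    """
    cfg = cfg or AssignmentConfig()
    if not transcripts:
        raise ValueError("annotation is empty")

    trees: dict[str, IntervalTree] = {}
    for i, tx in enumerate(transcripts):
        # Envelope covering every possible hit: promoter_flank <= distal_limit,
        # so padding the span by distal_limit covers promoter windows too.
        lo = max(0, tx.interval.start - cfg.distal_limit)
        hi = tx.interval.end + cfg.distal_limit
        trees.setdefault(tx.interval.chrom, IntervalTree()).addi(lo, hi, i)

    assignments: list[PeakAssignment] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(peak.start, peak.end))
        for i in hits:
            tx = transcripts[i]
            result = classify_peak_vs_transcript(peak, tx, cfg)
            if result is not None:
                category, distance = result
                assignments.append(
                    PeakAssignment(peak, tx.gene_id, tx.transcript_id, category, distance)
                )
    bound = {a.gene_id for a in assignments}
    return assignments, bound


def collapse_to_genes(
    assignments: Sequence[PeakAssignment],
) -> dict[str, PeakAssignment]:
    """Best assignment per gene: promoter > gene_body > distal, then nearest."""
    best: dict[str, PeakAssignment] = {}
    for a in assignments:
        cur = best.get(a.gene_id)
        if cur is None:
            best[a.gene_id] = a
            continue
        key = (CATEGORY_ORDER[a.category], a.distance, a.peak.chrom, a.peak.start)
        cur_key = (CATEGORY_ORDER[cur.category], cur.distance, cur.peak.chrom, cur.peak.start)
        if key < cur_key:
            best[a.gene_id] = a
    return best
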