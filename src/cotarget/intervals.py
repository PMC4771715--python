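"""Genomic coordinate conventions, interval algebra, and format I/O.

All internal coordinates are 0-based half-open ([start, end)), the BED
convention. Readers convert on the way in (GFF3 is 1-based inclusive),
writers convert on the way out; nothing else in the package touches a
coordinate convention. All readers and writers are gzip-transparent: a
path ending in ``.gz`` is opened through :mod:`gzip`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "IncomparableIntervals",
    "overlaps",
    "gap_distance",
    "shared_bases",
    "read_peaks",
    "write_peaks",
    "read_annotation",
    "write_annotation_gff3",
]


class IncomparableIntervals(ValueError):
    """Raised when an operation needs both intervals on one chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span: ``start`` inclusive, ``end`` exclusive, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded transcript; the TSS is the strand-dependent 5' end.

    For a ``+`` transcript the TSS is ``interval.start``; for a ``-``
    transcript it is ``interval.end - 1`` (the last base of the half-open
    span).
    """

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def shared_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases common to both intervals (0 if disjoint or trans-chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two same-chromosome intervals; 0 if they touch or overlap.

    Raises
    ------
    IncomparableIntervals
        If the intervals sit on different chromosomes.
    """
    if a.chrom != b.chrom:
        raise IncomparableIntervals(
            f"cannot measure distance between {a.chrom} and {b.chrom}"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# BED peaks


def read_peaks(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file of peak calls.

    Columns beyond the first three (name, score, ...) are ignored here;
    intensities are assigned by scoring against a coverage track, not read
    from BED scores. Order is preserved.
    """
    peaks: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(iv)
    return peaks


def write_peaks(peaks: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# Transcript annotation: GFF3 and BED12

_GFF3_TX_TYPES = {"transcript", "mRNA"}


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: str | Path) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start1, end1, _score, strand, _frame, attrs = fields
            if ftype not in _GFF3_TX_TYPES:
                skipped += 1
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: transcript without strand")
            attributes = _parse_gff3_attributes(attrs)
            tx_id = attributes.get("ID") or attributes.get("transcript_id")
            gene_id = attributes.get("gene_id") or attributes.get("Parent") or tx_id
            if tx_id is None:
                raise ValueError(f"{path}:{lineno}: transcript without ID")
            # GFF3 is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1))
            models.append(TranscriptModel(gene_id, tx_id, iv, strand))
    if skipped:
        logger.info("read_annotation: skipped %d non-transcript GFF3 records", skipped)
    _check_unique_transcripts(models, path)
    return models


def _read_bed12(path: str | Path) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED12 needs >=6 columns (strand)")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: transcript without strand")
            gene_id = fields[12] if len(fields) > 12 else name
            iv = GenomicInterval(chrom, int(start), int(end))
            models.append(TranscriptModel(gene_id, name, iv, strand))
    _check_unique_transcripts(models, path)
    return models


def _check_unique_transcripts(models: list[TranscriptModel], path: str | Path) -> None:
    seen: set[str] = set()
    for m in models:
        if m.transcript_id in seen:
            raise ValueError(f"{path}: duplicate transcript_id {m.transcript_id!r}")
        seen.add(m.transcript_id)


def read_annotation(path: str | Path, format: str | None = None) -> list[TranscriptModel]:
    """Read a transcript annotation from GFF3 or BED12.

    ``format`` is ``"gff3"`` or ``"bed12"``; if None it is sniffed from the
    file extension (``.gff``, ``.gff3`` vs ``.bed``).
    """
    if format is None:
        name = str(path)
        if name.endswith(".gz"):
            name = name[: -len(".gz")]
        format = "gff3" if name.endswith((".gff", ".gff3")) else "bed12"
    format = format.lower()
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotation_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GFF3 (converting back to 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.transcript_id};gene_id={m.gene_id}"
            fh.write(
                f"{m.interval.chrom}\ttx\ttranscript\t{m.interval.start + 1}\t"
                f"{m.interval.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
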