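"""Seeded synthetic-data generators with planted ground truth.

Emulates the statistical structure of a two-factor ChIP-seq + knockdown
RNA-seq study so every pipeline stage is testable without sequencing
data: two peak sets with a chosen one-sided overlap fraction and
rank-correlated intensities, coverage tracks whose per-peak sums equal
the drawn intensities exactly, a non-overlapping two-strand annotation
with unambiguous assignment windows, and three-replicate RPKM matrices
for control plus two knockdown hairpins with planted dependent genes.

All randomness flows from ``SimConfig.seed``; no global state. Each
generator draws from its own child stream of the seed, so the outputs
are byte-reproducible and insensitive to call order.

Layout guarantees (what makes planted truth exact):

* transcripts are spaced more than 2 x (promoter_flank + distal_limit)
  apart, so no peak can fall in the windows of two genes;
* gene-associated peaks are placed inside the intended window of the
  intended gene, with distal peaks on the transcript's 3' side so they
  cannot graze the promoter window;
* the remaining peaks sit in a desert farther than the distal limit from
  every transcript, in slots wide enough that a peak and its partner
  never touch a neighbouring slot.

Hence re-deriving bound genes from the emitted files with
:func:`cotarget.assign.assign_peaks` reproduces the planted bound list
exactly, and the realized Venn fraction equals the planted one.

Rank correlation of paired intensities is induced with a Gaussian
copula: normal scores drawn with Pearson correlation r = 2 sin(pi*rho/6)
— the closed-form bivariate-normal relation between Pearson r and
Spearman rho — then pushed through log-normal margins (Spearman is
invariant under the monotone transform).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assign import AssignmentConfig
from .cooccupancy import Peak, spearman_correlation
from .coverage import CoverageTrack
from .de import ExpressionMatrix
from .intervals import GenomicInterval, TranscriptModel, write_annotation_gff3, write_peaks
from . import coverage as _coverage

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "generate_annotation",
    "generate_cooccupied_peaks",
    "generate_knockdown_expression",
    "generate_bundle",
]

CHROM = "chrS"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults emulate the study being modelled: ~61% one-sided peak
    overlap, Spearman 0.84 between paired intensities, three replicates
    per condition, 3-fold planted knockdown effects with 20% replicate
    CV, at a desk scale of 1000 peaks x 500 genes.
    """

    seed: int = 0
    n_genes: int = 500
    chrom_length: int = 100_000_000
    n_peaks_a: int = 1000
    n_peaks_b_extra: int = 300      # B-only peaks (the partner factor binds more sites)
    target_overlap_fraction: float = 0.61
    target_intensity_rho: float = 0.84
    n_bound_genes: int = 250
    n_planted_activated: int = 30
    n_planted_repressed: int = 30
    n_dependent_unbound: int = 20   # dependent genes without a peak (indirect)
    effect_fold: float = 3.0
    replicate_cv: float = 0.2
    n_replicates: int = 3
    base_rpkm_median: float = 30.0  # log-normal centre of control expression
    base_rpkm_sigma_log2: float = 1.2
    peak_width_range: tuple[int, int] = (200, 400)
    intensity_log_mean: float = math.log(3000.0)
    intensity_log_sigma: float = 0.8
    windows: AssignmentConfig = field(default_factory=AssignmentConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.target_overlap_fraction <= 1:
            raise ValueError("target_overlap_fraction must be in [0, 1]")
        if not -1 <= self.target_intensity_rho <= 1:
            raise ValueError("target_intensity_rho must be in [-1, 1]")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must be > 1")
        if min(self.n_genes, self.n_peaks_a, self.n_peaks_b_extra,
               self.n_bound_genes, self.n_planted_activated,
               self.n_planted_repressed, self.n_dependent_unbound) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_bound_genes > self.n_genes:
            raise ValueError("n_bound_genes exceeds n_genes")
        if self.n_planted_activated + self.n_planted_repressed > self.n_bound_genes:
            raise ValueError("planted direct targets exceed bound genes")
        if self.n_dependent_unbound > self.n_genes - self.n_bound_genes:
            raise ValueError("n_dependent_unbound exceeds unbound genes")
        if self.n_bound_genes > self.n_peaks_a:
            raise ValueError("need at least one A peak per bound gene")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class PlantedTruth:
    """Ground-truth ledger written alongside every synthetic bundle."""

    bound_genes: dict[str, str]          # gene -> planted peak category
    dependent_genes: dict[str, str]      # gene -> 'up' | 'down'
    direct_targets: dict[str, str]       # gene -> 'activated' | 'repressed'
    realized_overlap_fraction: float
    realized_intensity_rho: float

    def __post_init__(self) -> None:
        stray = set(self.direct_targets) - (
            set(self.bound_genes) & set(self.dependent_genes)
        )
        if stray:
            raise ValueError(f"direct targets outside bound ∩ dependent: {sorted(stray)}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Annotation

_TX_LEN_RANGE = (12_000, 20_000)


def generate_annotation(cfg: SimConfig) -> list[TranscriptModel]:
    """Non-overlapping single-transcript genes on alternating strands.

    Inter-transcript gaps exceed 2 x (promoter_flank + distal_limit), so
    assignment windows of neighbouring genes can never both reach one
    peak.
    """
    rng = cfg.rng(1)
    gap = 2 * (cfg.windows.promoter_flank + cfg.windows.distal_limit) + 10_000
    margin = cfg.windows.distal_limit + 10_000
    needed = margin + cfg.n_genes * (_TX_LEN_RANGE[1] + gap) + margin
    if cfg.chrom_length < needed:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes; "
            f"need at least {needed}"
        )
    models: list[TranscriptModel] = []
    pos = margin
    for i in range(cfg.n_genes):
        length = int(rng.integers(_TX_LEN_RANGE[0], _TX_LEN_RANGE[1] + 1))
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval(CHROM, pos, pos + length)
        models.append(TranscriptModel(f"g{i:04d}", f"t{i:04d}", iv, strand))
        pos += length + gap
    return models


# ---------------------------------------------------------------------------
# Peaks + coverage

def _gaussian_copula_lognormal(
    rng: np.random.Generator, n: int, rho_s: float, mu: float, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """n intensity pairs with Spearman ~ rho_s and log-normal margins."""
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    a = np.maximum(1, np.rint(np.exp(mu + sigma * z[:, 0]))).astype(np.int64)
    b = np.maximum(1, np.rint(np.exp(mu + sigma * z[:, 1]))).astype(np.int64)
    return a, b


def _lognormal_intensities(
    rng: np.random.Generator, n: int, mu: float, sigma: float
) -> np.ndarray:
    return np.maximum(1, np.rint(rng.lognormal(mu, sigma, size=n))).astype(np.int64)


def _place_in_window(rng: np.random.Generator, lo: int, hi: int, width: int) -> GenomicInterval:
    """A width-bp interval uniformly inside [lo, hi)."""
    start = int(rng.integers(lo, hi - width + 1))
    return GenomicInterval(CHROM, start, start + width)


def _plant_gene_peak(
    rng: np.random.Generator, tx: TranscriptModel, category: str, cfg: SimConfig
) -> GenomicInterval:
    w = int(rng.integers(*cfg.peak_width_range))
    wp = cfg.windows.promoter_flank
    if category == "promoter":
        return _place_in_window(rng, tx.tss - wp, tx.tss + wp, w)
    if category == "gene_body":
        # inside the span, clear of the promoter window
        if tx.strand == "+":
            lo, hi = tx.tss + wp, tx.interval.end
        else:
            lo, hi = tx.interval.start, tx.tss - wp
        return _place_in_window(rng, lo, hi, w)
    # distal: 3' side of the span, so the peak cannot graze the promoter window
    d = int(rng.integers(1000, cfg.windows.distal_limit - 1000 - w))
    if tx.strand == "+":
        start = tx.interval.end + d
    else:
        start = tx.interval.start - d - w
    return GenomicInterval(CHROM, start, start + w)


def _partner_peak(rng: np.random.Generator, a: GenomicInterval, width: int) -> GenomicInterval:
    """A width-bp interval sharing >= 50 bp with ``a``."""
    min_shared = min(50, len(a), width)
    shift = int(rng.integers(-(width - min_shared), len(a) - min_shared + 1))
    start = a.start + shift
    return GenomicInterval(a.chrom, start, start + width)


def _coverage_from_peaks(
    peaks: Sequence[GenomicInterval], intensities: Sequence[int]
) -> CoverageTrack:
    """Rectangular pileups whose per-peak sums equal the intensities exactly.

    Each peak of length L and intensity I becomes a plateau of height
    I // L with the remainder I % L stacked one tag higher over the first
    I % L bases.
    """
    segs: dict[str, list[tuple[int, int, float]]] = {}
    for peak, inten in zip(peaks, intensities):
        L = len(peak)
        h, rem = divmod(int(inten), L)
        rows = segs.setdefault(peak.chrom, [])
        if rem:
            rows.append((peak.start, peak.start + rem, float(h + 1)))
        if h and rem < L:
            rows.append((peak.start + rem, peak.end, float(h)))
    return CoverageTrack(segs)


_CATEGORY_CHOICES = np.array(["promoter", "gene_body", "distal"])
_CATEGORY_PROBS = np.array([0.5, 0.3, 0.2])


def generate_cooccupied_peaks(
    cfg: SimConfig, annotation: Sequence[TranscriptModel]
) -> tuple[list[Peak], list[Peak], CoverageTrack, CoverageTrack, PlantedTruth]:
    """Two scored peak sets + coverage tracks + the planted-truth ledger.

    Exactly ``round(n_peaks_a * target_overlap_fraction)`` A peaks receive
    an overlapping B partner; paired intensities come from the Gaussian
    copula at the target Spearman. One A peak is planted per bound gene;
    all other peaks live in an intergenic desert beyond the distal limit.
    """
    rng = cfg.rng(2)
    if cfg.n_bound_genes > len(annotation):
        raise ValueError("n_bound_genes exceeds annotation size")
    n_pairs = int(round(cfg.n_peaks_a * cfg.target_overlap_fraction))
    if n_pairs > cfg.n_peaks_a:
        raise ValueError("target overlap fraction infeasible for n_peaks_a")

    bound_idx = rng.choice(len(annotation), size=cfg.n_bound_genes, replace=False)
    bound_idx.sort()
    categories = rng.choice(_CATEGORY_CHOICES, size=cfg.n_bound_genes, p=_CATEGORY_PROBS)

    peaks_a: list[GenomicInterval] = []
    bound_genes: dict[str, str] = {}
    for gi, cat in zip(bound_idx, categories):
        tx = annotation[int(gi)]
        peaks_a.append(_plant_gene_peak(rng, tx, str(cat), cfg))
        bound_genes[tx.gene_id] = str(cat)

    # desert slots: beyond the distal limit from every transcript
    n_desert_a = cfg.n_peaks_a - cfg.n_bound_genes
    n_desert = n_desert_a + cfg.n_peaks_b_extra
    slot_pitch = 3000
    desert_start = (
        (annotation[-1].interval.end if annotation else 0)
        + cfg.windows.distal_limit + 10_000
    )
    desert_end = desert_start + n_desert * slot_pitch
    if desert_end > cfg.chrom_length:
        raise ValueError(
            f"chrom_length too small for desert peaks; need >= {desert_end}"
        )
    # offsets keep a slot's peak AND its partner (which may stick out by up
    # to one peak width) strictly inside the slot, so no two slots can touch
    slots = desert_start + slot_pitch * rng.permutation(n_desert)
    pad = cfg.peak_width_range[1] + 100

    def desert_peak(s: int) -> GenomicInterval:
        w = int(rng.integers(*cfg.peak_width_range))
        off = int(rng.integers(pad, slot_pitch - w - pad))
        return GenomicInterval(CHROM, int(s) + off, int(s) + off + w)

    for s in slots[:n_desert_a]:
        peaks_a.append(desert_peak(int(s)))

    # choose which A peaks get a B partner
    paired_idx = rng.choice(cfg.n_peaks_a, size=n_pairs, replace=False)
    int_a_pair, int_b_pair = _gaussian_copula_lognormal(
        rng, n_pairs, cfg.target_intensity_rho,
        cfg.intensity_log_mean, cfg.intensity_log_sigma,
    )
    intensities_a = _lognormal_intensities(
        rng, cfg.n_peaks_a, cfg.intensity_log_mean, cfg.intensity_log_sigma
    )
    intensities_a[paired_idx] = int_a_pair

    peaks_b: list[GenomicInterval] = []
    intensities_b: list[int] = []
    for j, ai in enumerate(paired_idx):
        w = int(rng.integers(*cfg.peak_width_range))
        peaks_b.append(_partner_peak(rng, peaks_a[int(ai)], w))
        intensities_b.append(int(int_b_pair[j]))
    int_b_only = _lognormal_intensities(
        rng, cfg.n_peaks_b_extra, cfg.intensity_log_mean, cfg.intensity_log_sigma
    )
    for j, s in enumerate(slots[n_desert_a:]):
        peaks_b.append(desert_peak(int(s)))
        intensities_b.append(int(int_b_only[j]))

    # sort each set by coordinate, keeping intensity alignment
    order_a = sorted(range(len(peaks_a)), key=lambda i: (peaks_a[i].start, peaks_a[i].end))
    order_b = sorted(range(len(peaks_b)), key=lambda i: (peaks_b[i].start, peaks_b[i].end))
    peaks_a = [peaks_a[i] for i in order_a]
    ints_a = [int(intensities_a[i]) for i in order_a]
    peaks_b = [peaks_b[i] for i in order_b]
    ints_b = [int(intensities_b[i]) for i in order_b]

    cov_a = _coverage_from_peaks(peaks_a, ints_a)
    cov_b = _coverage_from_peaks(peaks_b, ints_b)
    scored_a = [Peak(p, "A", float(i)) for p, i in zip(peaks_a, ints_a)]
    scored_b = [Peak(p, "B", float(i)) for p, i in zip(peaks_b, ints_b)]

    realized_fraction = n_pairs / cfg.n_peaks_a if cfg.n_peaks_a else 0.0
    if n_pairs >= 3:
        rho, _ = spearman_correlation(int_a_pair.tolist(), int_b_pair.tolist())
    else:
        rho = float("nan")
    truth = PlantedTruth(
        bound_genes=bound_genes,
        dependent_genes={},
        direct_targets={},
        realized_overlap_fraction=realized_fraction,
        realized_intensity_rho=rho,
    )
    return scored_a, scored_b, cov_a, cov_b, truth


# ---------------------------------------------------------------------------
# Expression

def plant_dependent_genes(cfg: SimConfig, annotation: Sequence[TranscriptModel],
                          truth: PlantedTruth) -> PlantedTruth:
    """Choose planted direct targets (from bound genes) and indirect
    dependents (from unbound genes), filling in the truth ledger."""
    rng = cfg.rng(3)
    genes = [tx.gene_id for tx in annotation]
    bound = sorted(truth.bound_genes)
    unbound = sorted(set(genes) - set(bound))
    n_direct = cfg.n_planted_activated + cfg.n_planted_repressed
    direct = rng.choice(len(bound), size=n_direct, replace=False)
    direct_genes = [bound[i] for i in sorted(direct)]
    activated = direct_genes[: cfg.n_planted_activated]
    repressed = direct_genes[cfg.n_planted_activated:]
    indirect_idx = rng.choice(len(unbound), size=cfg.n_dependent_unbound, replace=False)
    indirect = [unbound[i] for i in sorted(indirect_idx)]

    dependent: dict[str, str] = {}
    # knockdown of an activator lowers its targets; of a repressor raises them
    for g in activated:
        dependent[g] = "down"
    for g in repressed:
        dependent[g] = "up"
    for j, g in enumerate(indirect):
        dependent[g] = "down" if j % 2 == 0 else "up"
    targets = {g: "activated" for g in activated}
    targets.update({g: "repressed" for g in repressed})
    return PlantedTruth(
        bound_genes=truth.bound_genes,
        dependent_genes=dependent,
        direct_targets=targets,
        realized_overlap_fraction=truth.realized_overlap_fraction,
        realized_intensity_rho=truth.realized_intensity_rho,
    )


def generate_knockdown_expression(
    cfg: SimConfig, annotation: Sequence[TranscriptModel], planted: PlantedTruth
) -> ExpressionMatrix:
    """Three-condition RPKM matrix with the planted effects.

    Control means are log-normal; both knockdown conditions scale each
    planted dependent gene by ``effect_fold`` (down for 'down', up for
    'up'); replicates add multiplicative log-normal noise of the stated
    CV (mean-1 noise, so condition means are unbiased).
    """
    rng = cfg.rng(4)
    genes = [tx.gene_id for tx in annotation]
    stray = set(planted.dependent_genes) - set(genes)
    if stray:
        raise ValueError(f"planted genes outside the annotation: {sorted(stray)}")

    n = len(genes)
    base = 2.0 ** rng.normal(
        math.log2(cfg.base_rpkm_median), cfg.base_rpkm_sigma_log2, n
    )
    scale = np.ones(n)
    for i, g in enumerate(genes):
        direction = planted.dependent_genes.get(g)
        if direction == "down":
            scale[i] = 1.0 / cfg.effect_fold
        elif direction == "up":
            scale[i] = cfg.effect_fold

    sigma_ln = math.sqrt(math.log(1.0 + cfg.replicate_cv**2))

    def noisy(mean: np.ndarray) -> np.ndarray:
        noise = np.exp(
            rng.normal(0.0, sigma_ln, (n, cfg.n_replicates)) - sigma_ln**2 / 2.0
        )
        return mean[:, None] * noise

    columns: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    blocks = [("control", base), ("kdA", base * scale), ("kdB", base * scale)]
    for cond, mean in blocks:
        block = noisy(mean)
        for r in range(cfg.n_replicates):
            name = f"{cond}_{r + 1}"
            columns[name] = block[:, r]
            conditions[name] = cond
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(values, conditions)


# ---------------------------------------------------------------------------
# Bundle

def generate_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture bundle; returns the file map.

    Files: annotation.gff3, peaks_a.bed, peaks_b.bed, coverage_a.bedgraph,
    coverage_b.bedgraph, expression.tsv, design.yaml, planted_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(cfg)
    peaks_a, peaks_b, cov_a, cov_b, truth = generate_cooccupied_peaks(cfg, annotation)
    truth = plant_dependent_genes(cfg, annotation, truth)
    expr = generate_knockdown_expression(cfg, annotation, truth)

    paths = {
        "annotation": outdir / "annotation.gff3",
        "peaks_a": outdir / "peaks_a.bed",
        "peaks_b": outdir / "peaks_b.bed",
        "coverage_a": outdir / "coverage_a.bedgraph",
        "coverage_b": outdir / "coverage_b.bedgraph",
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.yaml",
        "planted_truth": outdir / "planted_truth.json",
    }
    write_annotation_gff3(annotation, paths["annotation"])
    write_peaks([p.interval for p in peaks_a], paths["peaks_a"])
    write_peaks([p.interval for p in peaks_b], paths["peaks_b"])
    _coverage.write_bedgraph(cov_a, paths["coverage_a"])
    _coverage.write_bedgraph(cov_b, paths["coverage_b"])
    expr.write_tsv(paths["expression"], paths["design"])
    truth.to_json(paths["planted_truth"])
    return paths
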