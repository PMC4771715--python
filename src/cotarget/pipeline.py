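"""End-to-end orchestration: files in, target calls and a summary out.

Stage order: read inputs -> score peaks -> Venn decomposition ->
match overlapping peaks + Spearman -> assign factor-A peaks to genes ->
concordant-knockdown dependent genes -> direct targets -> optional
gene-set enrichment. Every stage error aborts with the stage name and
cause; outputs are plain TSV/JSON so a run is diffable and seedless
re-runs on identical inputs are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assign import AssignmentConfig, assign_peaks, collapse_to_genes
from .cooccupancy import (
    format_pvalue,
    match_overlapping_peaks,
    score_peaks,
    spearman_correlation,
    venn_decompose,
)
from .coverage import read_bedgraph
from .de import DEConfig, ExpressionMatrix, concordant_dependent_genes
from .intervals import read_annotation, read_peaks
from .targets import call_direct_targets, enrich_gene_sets, read_gmt, target_class_counts

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    peaks_a: str
    peaks_b: str
    coverage_a: str
    coverage_b: str
    annotation: str
    expression: str
    design: str
    outdir: str
    gene_sets: str | None = None          # optional GMT
    promoter_only: bool = False           # count only promoter peaks as "bound"
    windows: AssignmentConfig = field(default_factory=AssignmentConfig)
    de: DEConfig = field(default_factory=DEConfig)

    REQUIRED = (
        "peaks_a", "peaks_b", "coverage_a", "coverage_b",
        "annotation", "expression", "design", "outdir",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        missing = [k for k in cls.REQUIRED if k not in raw]
        if missing:
            raise ValueError(f"config missing required fields: {missing}")
        windows = AssignmentConfig(**raw.pop("windows", {}))
        de = DEConfig(**raw.pop("de", {}))
        return cls(windows=windows, de=de, **raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write the artifact bundle; returns the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    read = _stage("read_inputs")(_read_inputs)
    peaks_a, peaks_b, cov_a, cov_b, annotation, expr, gene_sets = read(cfg)

    scored_a = _stage("score_peaks")(score_peaks)(peaks_a, cov_a, "A")
    scored_b = _stage("score_peaks")(score_peaks)(peaks_b, cov_b, "B")
    _write_scored(scored_a, scored_b, outdir / "scored_peaks.tsv")

    venn = _stage("venn")(venn_decompose)(scored_a, scored_b)
    pairs = _stage("match")(match_overlapping_peaks)(scored_a, scored_b)
    if len(pairs) >= 3:
        rho, p = _stage("spearman")(spearman_correlation)(
            [a.intensity for a, _ in pairs], [b.intensity for _, b in pairs]
        )
    else:
        rho, p = float("nan"), float("nan")
    logger.info("matched %d pairs, Spearman rho=%.3f p=%s", len(pairs), rho,
                format_pvalue(p) if p == p else "n/a")
    _write_pairs(pairs, outdir / "matched_pairs.tsv")

    assignments, bound = _stage("assign")(assign_peaks)(
        [p.interval for p in scored_a], annotation, cfg.windows
    )
    best = collapse_to_genes(assignments)
    if cfg.promoter_only:
        bound = {g for g, a in best.items() if a.category == "promoter"}
    _write_assignments(assignments, outdir / "assignments.tsv")

    calls = _stage("de")(concordant_dependent_genes)(expr, cfg.de)
    _write_calls(calls, outdir / "dependency_calls.tsv")

    targets = _stage("targets")(call_direct_targets)(
        calls, bound, {g: a.category for g, a in best.items()}
    )
    counts = target_class_counts(targets)
    _write_targets(targets, outdir / "target_calls.tsv")

    enrichments = []
    if gene_sets:
        universe = sorted({tx.gene_id for tx in annotation})
        direct = [t.gene_id for t in targets if t.target_class != "none"]
        enrichments = _stage("enrich")(enrich_gene_sets)(direct, gene_sets, universe)
        _write_enrichments(enrichments, outdir / "enrichment.tsv")

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "parameters": {
            "promoter_flank": cfg.windows.promoter_flank,
            "distal_limit": cfg.windows.distal_limit,
            "fc_threshold": cfg.de.fc_threshold,
            "alpha": cfg.de.alpha,
            "pseudocount": cfg.de.pseudocount,
            "promoter_only": cfg.promoter_only,
        },
        "peaks": {
            "total_a": venn.total_a,
            "total_b": venn.total_b,
            "a_overlapping_b": venn.a_overlapping_b,
            "b_overlapping_a": venn.b_overlapping_a,
            "fraction_a": venn.fraction_a,
            "percent_a_display": venn.percent_a,
        },
        "intensity_correlation": {
            "n_pairs": len(pairs),
            "spearman_rho": rho,
            "p_value": p,
            "p_display": format_pvalue(p) if p == p else None,
        },
        "genes": {
            "annotated": len({tx.gene_id for tx in annotation}),
            "bound": len(bound),
            "dependent": sum(1 for c in calls if c.dependent),
            "direct_targets": counts["direct"],
            "activated": counts["activated"],
            "repressed": counts["repressed"],
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _read_inputs(cfg: PipelineConfig):
    peaks_a = read_peaks(cfg.peaks_a)
    peaks_b = read_peaks(cfg.peaks_b)
    cov_a = read_bedgraph(cfg.coverage_a)
    cov_b = read_bedgraph(cfg.coverage_b)
    annotation = read_annotation(cfg.annotation)
    expr = ExpressionMatrix.read_tsv(cfg.expression, cfg.design)
    gene_sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else None
    return peaks_a, peaks_b, cov_a, cov_b, annotation, expr, gene_sets


def _write_scored(scored_a, scored_b, path: Path) -> None:
    rows = [
        (p.factor, p.interval.chrom, p.interval.start, p.interval.end, p.intensity)
        for p in (*scored_a, *scored_b)
    ]
    pd.DataFrame(rows, columns=["factor", "chrom", "start", "end", "intensity"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def _write_pairs(pairs, path: Path) -> None:
    rows = [
        (
            a.interval.chrom, a.interval.start, a.interval.end, a.intensity,
            b.interval.chrom, b.interval.start, b.interval.end, b.intensity,
        )
        for a, b in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "chrom_a", "start_a", "end_a", "intensity_a",
            "chrom_b", "start_b", "end_b", "intensity_b",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_assignments(assignments, path: Path) -> None:
    rows = [
        (a.peak.chrom, a.peak.start, a.peak.end, a.gene_id, a.transcript_id,
         a.category, a.distance)
        for a in assignments
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene_id", "transcript_id", "category", "distance"],
    ).to_csv(path, sep="\t", index=False)


def _write_calls(calls, path: Path) -> None:
    rows = [
        (c.gene_id, c.log2fc_a, c.log2fc_b, c.p_a, c.p_b,
         c.direction or "", c.dependent)
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "log2fc_a", "log2fc_b", "p_a", "p_b", "direction", "dependent"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_targets(targets, path: Path) -> None:
    rows = [
        (t.gene_id, t.dependent_direction or "", t.bound,
         t.best_peak_category or "", t.target_class)
        for t in targets
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "direction", "bound", "best_peak_category", "target_class"],
    ).to_csv(path, sep="\t", index=False)


def _write_enrichments(enrichments, path: Path) -> None:
    rows = [
        (r.geneset, r.overlap, r.geneset_size, r.target_size, r.universe_size,
         r.p_value, q, ",".join(r.members))
        for r, q in enrichments
    ]
    pd.DataFrame(
        rows,
        columns=["geneset", "overlap", "geneset_size", "target_size",
                 "universe_size", "p_value", "q_value", "members"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
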