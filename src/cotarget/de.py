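"""Factor-dependent genes from control vs two-hairpin knockdown RPKM.

Off-target effects are the classic failure mode of shRNA screens; the
guard used here is concordance: a gene counts as factor-dependent only if
BOTH independent hairpins move it past the fold-change and p-value gates
in the SAME direction. The per-hairpin test is a two-sided Welch t on
log2(RPKM + pseudocount) across replicates (the statistic is pluggable);
no multiple-testing correction is applied — the thresholds are raw
per-gene gates, which is a deliberate, and logged, caveat.

Fold changes are computed on pseudocounted linear condition means,
log2((mean_kd + eps) / (mean_ctrl + eps)), and the threshold is applied on
the linear scale (|FC| > tau means FC > tau or FC < 1/tau).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEConfig",
    "DependencyCall",
    "ExpressionMatrix",
    "log2_fold_change",
    "replicate_test",
    "concordant_dependent_genes",
]

CONTROL = "control"


@dataclass(frozen=True)
class DEConfig:
    """Gates for the dependent-gene call."""

    fc_threshold: float = 1.5   # linear fold change, > 1
    alpha: float = 0.05         # per-hairpin p gate
    pseudocount: float = 1.0    # RPKM added before ratios/logs

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class DependencyCall:
    gene_id: str
    log2fc_a: float
    log2fc_b: float
    p_a: float
    p_b: float
    direction: str | None  # 'up' | 'down' | None
    dependent: bool


class ExpressionMatrix:
    """Gene x sample RPKM table with condition/replicate labels.

    ``values`` is a DataFrame indexed by gene_id with one column per
    sample; ``conditions`` maps each sample column to its condition label
    (``control`` plus the knockdown condition names).
    """

    def __init__(self, values: pd.DataFrame, conditions: dict[str, str]) -> None:
        missing = [c for c in values.columns if c not in conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if (values.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        self.values = values.astype(float)
        self.conditions = dict(conditions)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.values.columns:
            cond = self.conditions[c]
            if cond not in seen:
                seen.append(cond)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [c for c in self.values.columns if self.conditions[c] == condition]

    def submatrix(self, condition: str) -> pd.DataFrame:
        cols = self.samples_for(condition)
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        return self.values[cols]

    def collapse_transcripts(self, tx_to_gene: dict[str, str]) -> "ExpressionMatrix":
        """Sum transcript-level rows into gene-level rows."""
        mapped = self.values.rename(index=tx_to_gene)
        collapsed = mapped.groupby(level=0).sum()
        return ExpressionMatrix(collapsed, self.conditions)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_tsv(
        cls, expr_path: str | Path, design_path: str | Path
    ) -> "ExpressionMatrix":
        """Read an RPKM TSV (first column gene_id) plus a YAML design sidecar.

        The sidecar maps condition -> list of sample column names, e.g.::

            control: [ctrl_1, ctrl_2, ctrl_3]
            kdA: [shA_1, shA_2, shA_3]
            kdB: [shB_1, shB_2, shB_3]
        """
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        with open(design_path) as fh:
            design = yaml.safe_load(fh)
        conditions = {
            sample: cond for cond, samples in design.items() for sample in samples
        }
        return cls(values, conditions)

    def write_tsv(self, expr_path: str | Path, design_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t", float_format="%.6g")
        design: dict[str, list[str]] = {}
        for sample in self.values.columns:
            design.setdefault(self.conditions[sample], []).append(sample)
        with open(design_path, "w") as fh:
            yaml.safe_dump(design, fh, sort_keys=True)


def log2_fold_change(mean_kd: float, mean_ctrl: float, pseudocount: float = 1.0) -> float:
    """Signed log2 ratio of pseudocounted condition means."""
    if mean_kd < 0 or mean_ctrl < 0:
        raise ValueError("RPKM means must be >= 0")
    return float(np.log2((mean_kd + pseudocount) / (mean_ctrl + pseudocount)))


def replicate_test(
    ctrl_reps: Sequence[float],
    kd_reps: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """Two-sided Welch t on log2(RPKM + pseudocount); p in (0, 1].

    Degenerate case: zero variance in both groups with equal means gives
    p = 1 (no evidence of change, rather than NaN).
    """
    c = np.log2(np.asarray(ctrl_reps, dtype=float) + pseudocount)
    k = np.log2(np.asarray(kd_reps, dtype=float) + pseudocount)
    if c.size < 2 or k.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.var(c) == 0 and np.var(k) == 0:
        return 1.0 if c.mean() == k.mean() else 0.0
    p = float(stats.ttest_ind(c, k, equal_var=False).pvalue)
    return min(max(p, np.nextafter(0, 1)), 1.0)


def concordant_dependent_genes(
    expr: ExpressionMatrix,
    cfg: DEConfig | None = None,
    test: Callable[[Sequence[float], Sequence[float], float], float] = replicate_test,
) -> list[DependencyCall]:
    """Call dependent genes from control + two knockdown conditions.

    A gene is dependent iff for BOTH knockdowns |FC| exceeds the linear
    threshold, p is below alpha, and the two log2 fold changes share a
    sign; the shared sign is the direction ('up' = higher upon knockdown).
    Every gene is returned with its statistics.
    """
    cfg = cfg or DEConfig()
    conds = expr.condition_names()
    if CONTROL not in conds:
        raise ValueError("missing 'control' condition")
    kd_conds = [c for c in conds if c != CONTROL]
    if len(kd_conds) != 2:
        raise ValueError(f"need exactly two knockdown conditions, got {kd_conds}")

    logger.warning(
        "dependent-gene gates use raw per-hairpin p < %g with no multiple-testing "
        "correction; concordance across hairpins is the only guard",
        cfg.alpha,
    )

    ctrl = expr.submatrix(CONTROL)
    kd_a = expr.submatrix(kd_conds[0])
    kd_b = expr.submatrix(kd_conds[1])
    log2_tau = float(np.log2(cfg.fc_threshold))

    calls: list[DependencyCall] = []
    for gene in expr.genes:
        c = ctrl.loc[gene].to_numpy()
        a = kd_a.loc[gene].to_numpy()
        b = kd_b.loc[gene].to_numpy()
        fc_a = log2_fold_change(a.mean(), c.mean(), cfg.pseudocount)
        fc_b = log2_fold_change(b.mean(), c.mean(), cfg.pseudocount)
        p_a = test(c, a, cfg.pseudocount)
        p_b = test(c, b, cfg.pseudocount)
        passes = (
            abs(fc_a) > log2_tau
            and abs(fc_b) > log2_tau
            and p_a < cfg.alpha
            and p_b < cfg.alpha
            and np.sign(fc_a) == np.sign(fc_b)
            and fc_a != 0
        )
        direction = ("up" if fc_a > 0 else "down") if passes else None
        calls.append(DependencyCall(gene, fc_a, fc_b, p_a, p_b, direction, passes))
    return calls
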