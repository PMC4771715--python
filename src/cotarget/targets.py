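"""Direct-target calling and gene-set enrichment.

A *direct target* is a gene that is both factor-dependent (concordant
two-hairpin knockdown change) and factor-bound (>= 1 peak within the
assignment windows). Direction disambiguates the regulatory sign:
knockdown of an activator LOWERS its targets, so dependent-down + bound
=> activated; dependent-up + bound => repressed.

Enrichment of the resulting target list in user-supplied gene sets uses
the upper-tail hypergeometric test (one-sided overrepresentation),
with Benjamini-Hochberg q-values added alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .de import DependencyCall

__all__ = [
    "TargetCall",
    "EnrichmentResult",
    "call_direct_targets",
    "target_class_counts",
    "hypergeometric_enrichment",
    "enrich_gene_sets",
    "bh_adjust",
    "read_gmt",
]


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    dependent_direction: str | None  # 'up' | 'down' | None
    bound: bool
    best_peak_category: str | None   # promoter | gene_body | distal | None
    target_class: str                # 'activated' | 'repressed' | 'none'


@dataclass(frozen=True)
class EnrichmentResult:
    geneset: str
    overlap: int          # k
    geneset_size: int     # K (within the universe)
    target_size: int      # n (within the universe)
    universe_size: int    # N
    p_value: float
    members: tuple[str, ...] = ()


def call_direct_targets(
    dependency_calls: Sequence[DependencyCall],
    bound_genes: set[str],
    best_categories: Mapping[str, str] | None = None,
) -> list[TargetCall]:
    """Intersect dependency calls with the bound-gene set.

    Returns one TargetCall per dependency call. ``best_categories``
    optionally supplies the best peak category per bound gene for the
    report.
    """
    best_categories = best_categories or {}
    out: list[TargetCall] = []
    for call in dependency_calls:
        bound = call.gene_id in bound_genes
        if call.dependent and bound:
            # knockdown-down means the factor was activating the gene
            cls = "activated" if call.direction == "down" else "repressed"
        else:
            cls = "none"
        out.append(
            TargetCall(
                call.gene_id,
                call.direction,
                bound,
                best_categories.get(call.gene_id),
                cls,
            )
        )
    return out


def target_class_counts(targets: Sequence[TargetCall]) -> dict[str, int]:
    """Counts of activated / repressed / total direct targets."""
    activated = sum(1 for t in targets if t.target_class == "activated")
    repressed = sum(1 for t in targets if t.target_class == "repressed")
    return {"activated": activated, "repressed": repressed, "direct": activated + repressed}


def hypergeometric_enrichment(
    targets: Iterable[str],
    geneset: Iterable[str],
    universe: Iterable[str],
    name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment p-value, P[X >= k].

    With N universe genes of which K are in the set, and n target genes
    drawn, the overlap k is tested for overrepresentation. Computed via
    the log-space survival function, so tiny p-values do not underflow to
    meaningless zeros.

    Raises
    ------
    ValueError
        If the universe is empty, or either list strays outside it.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    gs = set(geneset)
    tg = set(targets)
    stray = sorted(gs - uni)
    if stray:
        raise ValueError(f"geneset members outside the universe: {stray}")
    stray_t = sorted(tg - uni)
    if stray_t:
        raise ValueError(f"target genes outside the universe: {stray_t}")

    N, K, n = len(uni), len(gs), len(tg)
    k = len(gs & tg)
    if k == 0:
        p = 1.0
    else:
        logp = stats.hypergeom.logsf(k - 1, N, K, n)
        p = float(np.exp(logp))
    return EnrichmentResult(name, k, K, n, N, min(max(p, 0.0), 1.0),
                            tuple(sorted(gs & tg)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_gene_sets(
    targets: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[tuple[EnrichmentResult, float]]:
    """Hypergeometric enrichment over a gene-set collection, with BH q-values.

    Gene-set members outside the universe are dropped before testing (a
    set restricted to the measured universe is the standard treatment for
    collections built on a larger genome). Results are sorted by p.
    """
    uni = set(universe)
    results = [
        hypergeometric_enrichment(targets, set(members) & uni, uni, name=name)
        for name, members in gene_sets.items()
    ]
    qs = bh_adjust([r.p_value for r in results]) if results else np.array([])
    ranked = sorted(zip(results, qs.tolist()), key=lambda rq: (rq[0].p_value, rq[0].geneset))
    return ranked


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs name, description, members")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
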