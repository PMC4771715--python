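# cotarget

Integration of ChIP-seq binding data with knockdown RNA-seq to call the
**direct transcriptional targets** of a transcription-factor pair — the
analysis used to show that a DNA-binding factor (e.g. RUNX2) and its
dimerisation partner (CBFB) co-occupy the genome and directly drive a
downstream survival gene such as *MYC* in p53-defective cancer cells.

The package is a library first (import `cotarget`), with narrative
scripts under `examples/` and a thin `cotarget` CLI for shell use.

## What it computes

Given peak calls (BED), per-base tag coverage (bedGraph), a transcript
annotation (GFF3/BED12), and an RPKM matrix for control + two independent
shRNA knockdowns:

1. **Peak intensity** — for a peak $P = [s, e)$ over tag coverage $c$,
   the binding-strength statistic $I(P) = \sum_{p=s}^{e-1} c(p)$,
   computed exactly by segment arithmetic.
2. **Co-occupancy** — one-sided Venn counts (A peaks overlapping ≥1 B
   peak, and vice versa) plus a deterministic one-to-one matching of
   overlapping peaks by maximal shared bases, and the Spearman rank
   correlation $\rho$ of the matched intensities (exact permutation
   p-value for $n \le 10$, t approximation above).
3. **Peak→gene assignment** — strand-aware windows: *promoter* = TSS
   ± 5 kb, *gene body* = rest of the transcript, *distal* = within 25 kb
   of a transcript edge (strictly less than); precedence promoter >
   gene_body > distal. Genes with ≥1 assigned peak are **bound**.
4. **Dependent genes** — per hairpin, fold change on pseudocounted means
   $\log_2\frac{\bar{x}_{kd}+\varepsilon}{\bar{x}_{ctrl}+\varepsilon}$
   and a two-sided Welch t on $\log_2(\mathrm{RPKM}+\varepsilon)$; a gene
   is dependent iff **both** hairpins pass $|FC| > 1.5$, $p < 0.05$ and
   agree in direction (the concordance guard against off-target effects).
5. **Direct targets** — dependent ∩ bound; knockdown-down + bound ⇒
   *activated*, knockdown-up + bound ⇒ *repressed*. Target lists are
   tested for gene-set enrichment with the upper-tail hypergeometric
   $P[X \ge k]$, $X \sim \mathrm{Hypergeom}(N, K, n)$, with BH q-values.
6. **Bench calculators** — ChIP-qPCR percent of input
   ($100 \cdot f \cdot E^{Ct_{input} - Ct_{IP}}$, dilution-adjusted ΔCt)
   and cumulative cell numbers (counts scaled by the running product of
   split ratios).

A seeded synthetic-data generator (`cotarget.simulate`) emulates the
study's structure — ~61% one-sided peak overlap, Spearman ≈ 0.84 between
paired intensities, three replicates, planted 3-fold knockdown effects —
and writes a planted-truth ledger so the whole pipeline is testable
end-to-end without sequencing data.

## Worked example

```sh
python examples/05_full_pipeline.py
```

generates the default synthetic bundle (1000 factor-A peaks, 500 genes,
60 planted direct targets, seed 1) and runs every stage. It prints:

```
{
 "total_a": 1000,
 "total_b": 910,
 "a_overlapping_b": 610,
 "b_overlapping_a": 610,
 "fraction_a": 0.61,
 "percent_a_display": 61
}
{
 "annotated": 500,
 "bound": 250,
 "dependent": 79,
 "direct_targets": 60,
 "activated": 30,
 "repressed": 30
}
Spearman rho of 610 matched intensity pairs: 0.826 (generator target 0.84)
planted direct targets: 60; pipeline called 60
```

Reading: 610 of the 1000 A peaks overlap a B peak (displayed 61%), the
matched intensities are strongly rank-correlated (0.826 measured against
the 0.84 generator target), 250 genes carry at least one A peak within
the assignment windows, 79 genes pass the two-hairpin concordance filter,
and their intersection recovers all 60 planted direct targets, split into
the planted 30 activated + 30 repressed.

The other examples (`01`–`04`) each exercise one capability on inputs
small enough to verify by eye. The same stages are available from the
shell: `cotarget simulate|run|score-peaks|venn|assign|de|targets|enrich`.

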