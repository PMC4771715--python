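# Methods

## Problem and model

A transcription factor with a genome-wide binding map (ChIP-seq) and a
knockdown expression readout (RNA-seq) supports two independent claims
about any gene: the factor *binds near it*, and the gene's expression
*depends on the factor*. Neither alone identifies direct regulation —
most binding is non-functional, and most expression changes are
downstream ripples. The integration implemented here takes the
intersection: a **direct target** is a gene that is both bound and
dependent, with the regulatory sign read off the knockdown direction
(knockdown lowers the targets of an activator, raises the targets of a
repressor).

All genomic coordinates are 0-based half-open internally; readers convert
GFF3's 1-based inclusive convention on input and writers convert back.
Overlap means ≥1 shared base; no minimum-fraction rule is imposed.

## Stages and parameters

### Peak intensity

Coverage is a per-base step function (bedGraph segments). A peak's
intensity is the sum of per-base tag counts across the peak, computed as
Σ(segment overlap length × segment value). This equals the per-base loop
exactly; the loop is retained in the test suite as the oracle.

### Co-occupancy

Venn counts are peak-centric and one-sided: an A peak overlapping any
number of B peaks counts once toward `a_overlapping_b`. The two sides
are reported separately since they need not agree. The display percent
is the fraction rounded to the nearest integer.

For the intensity correlation, overlapping peaks are paired one-to-one.
The contract "each A peak takes its maximal-overlap B peak" can conflict
with one-to-one-ness when two A peaks prefer the same B; candidates are
therefore accepted greedily by descending shared bases, breaking ties by
leftmost A then leftmost B, each peak used at most once. The pairing is
deterministic for identical input.

Spearman ρ is the product-moment correlation of average-tied ranks. The
two-sided p-value is exact for n ≤ 10 (full enumeration of the n!
permutations of one rank vector — ρ is affine in the rank dot product,
so the enumeration reduces to chunked matrix products) and uses the
t approximation t = ρ·√((n−2)/(1−ρ²)) with n−2 df above. p-values below
2.2e−16 are displayed with the conventional "< 2.2e-16" floor; the
numeric value is preserved.

### Peak→gene windows

Defaults: promoter flank 5000 bp, distal limit 25 000 bp. The promoter
window is symmetric in genomic bp around the strand-aware TSS (for a −
transcript, upstream means larger coordinates). Distal distance is the
gap to the nearest transcript edge, not the TSS midpoint, and the limit
is strict (< 25 000), so a gap of exactly 25 kb does not bind; an
abutting peak (gap 0 without overlap) is distal at distance 0. Precedence
per (peak, transcript) is promoter > gene body > distal; categories are
mutually exclusive and exhaustive within the limit. A peak may be
assigned to multiple genes (all are reported); per gene the best
assignment across transcripts is kept (category precedence, then smallest
distance). Candidate transcripts are found through an interval tree over
spans padded by the distal limit (O(log n + k) per query); correctness is
tested against an all-pairs classifier.

### Dependent genes

Per hairpin: fold change log2((mean_kd + ε)/(mean_ctrl + ε)) with
pseudocount ε = 1 RPKM, thresholded on the linear scale at 1.5; a
two-sided Welch t on log2(RPKM + ε) across replicates, α = 0.05. A gene
is dependent iff both hairpins pass both gates in the same direction.
The statistic is a parameter of `concordant_dependent_genes`, so a
count-based or rank test can be swapped in. **No multiple-testing
correction is applied** — the gates are raw per-gene thresholds and the
concordance requirement is the only guard; the pipeline logs this caveat
prominently. Zero variance in both groups with equal means yields p = 1;
fewer than two replicates per group is an error. Transcript-level input
can be collapsed to gene level by summing RPKM before testing, since the
integration is gene-level.

### Direct targets and enrichment

Direct = dependent ∩ bound; by default "bound" accepts any window
category, with a promoter-only mode as a flag. Enrichment of the target
list in a GMT collection uses the upper-tail hypergeometric P[X ≥ k]
computed through the log-space survival function; the universe defaults
to all annotated genes (configurable), gene-set members outside the
universe are dropped before testing, and Benjamini–Hochberg q-values are
reported alongside the raw p-values.

### Bench calculators

Percent of input adjusts the input Ct to 100% (subtract log_E(1/f)
cycles for input fraction f), then applies ΔCt with amplification
efficiency E = 2.0 (a parameter): 100·E^(adjusted input Ct − IP Ct) =
100·f·E^(Ct_input − Ct_IP). Cumulative cell numbers interpret repeated
1:r splitting as a running product: C_0 = count_0, C_i = count_i ·
Π_{j<i} r_j — the only reading under which a steadily growing, repeatedly
split culture produces a growing cumulative curve. With all r = 1 the
raw counts are returned unchanged.

## Synthetic data: what it emulates and what it does not

The generator (`cotarget.simulate`) reproduces the *statistical* shape of
the study inputs, not their sequence content:

* **Co-occupancy**: exactly round(n_A · fraction) A peaks receive an
  overlapping B partner (default fraction 0.61), so the realized Venn
  fraction is deterministic rather than binomially scattered. Paired
  intensities come from a Gaussian copula — normal scores with Pearson
  r = 2·sin(π·ρ_s/6), the closed-form bivariate-normal relation to
  Spearman ρ_s (used instead of an empirical calibration constant because
  it is exact) — pushed through log-normal margins (default ρ_s 0.84).
* **Coverage**: each peak becomes a rectangular pileup of height I//L
  with the remainder stacked one tag higher over the first I mod L bases,
  so the scored intensity equals the drawn intensity *exactly* and
  intensity tests are equality tests.
* **Annotation**: non-overlapping single-transcript genes on alternating
  strands, spaced more than 2×(promoter flank + distal limit) apart, so
  no peak can reach two genes' windows. One peak is planted per bound
  gene (category drawn 0.5/0.3/0.2 promoter/gene-body/distal, distal on
  the 3′ side so it cannot graze the promoter window); all other peaks
  sit in a desert beyond the distal limit. Re-deriving bound genes from
  the emitted files therefore reproduces the planted list exactly.
* **Expression**: control RPKM is log-normal (median 30, σ = 1.2 in log2
  units — a realistic dynamic range under which a 3-fold effect with
  ε = 1 pseudocounting stays above the 1.5-fold gate); both hairpins
  scale planted genes by effect_fold (default 3) in the planted
  direction; replicates add multiplicative log-normal noise at CV 20%
  (mean-1, so condition means are unbiased); n = 3 per condition.

Default scale — 1000 A peaks, 500 genes, 250 bound, 60 planted direct
targets plus 20 indirect dependents — runs the full pipeline in about a
second and was chosen as the smallest size at which the co-occupancy
fraction and correlation are estimated tightly (±0.03 / ±0.05 bands at
n = 610 pairs).

Not emulated: read-level data (FASTQ), fragment-size effects, background
noise peaks and ChIP artefacts, overlapping or multi-isoform gene models,
correlated replicate structure, count-level mean–variance relationships,
and library-size effects. Passing the planted-truth tests therefore
demonstrates the correctness of the bookkeeping and the power of the
concordance filter under idealised noise — not robustness to the
messiness of real libraries.

## Numerical and design notes

* Welch p-values are clamped into (0, 1]; Spearman ρ is clipped to
  [−1, 1] against rounding drift.
* `match_overlapping_peaks` and all generators are deterministic;
  generator streams derive from `(seed, salt)` pairs per stage, so adding
  a stage never perturbs another's draws.
* The one-to-one matching tie-break (leftmost partner) and the strict
  distal boundary are conventions; both are surfaced in the docstrings
  and exercised by tests.
* Intensities are rounded to integer tag counts (minimum 1), which can
  introduce rank ties at the low end; Spearman handles ties by average
  ranks.
* Degenerate inputs: empty peak files flow through to zero bound genes
  and zero targets; an empty annotation, a missing condition, a constant
  vector, or an inverted interval raise informative errors naming the
  offending stage, line or field.

## Limitations

* The per-hairpin test is replicate-level on RPKM, not a count model; no
  dispersion shrinkage, no batch correction, no isoform resolution.
* Raw p-value gates (no FDR) mirror a common practice but inflate the
  dependent set on large gene universes; the concordance filter only
  partially compensates.
* Gene-set enrichment ignores ontology topology (no DAG propagation) and
  treats sets as flat member lists.
* The assignment scheme has no notion of enhancer–promoter looping;
  "distal within 25 kb" is a proximity heuristic.
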