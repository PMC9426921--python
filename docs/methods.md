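# Methods

## The problem

A DNase-seq or ATAC-seq experiment yields a set of accessible genomic
regions ("peaks"), which reflect where regulatory proteins act in that
cell state. Motif- or abundance-based tools ask *which transcription
factor's binding sites are most over-represented in these regions?* — a
question that favours pervasive, promiscuous binders. This package asks a
different question: *which TF's conserved binding sites concentrate inside
the regulatory territory of functionally coherent gene sets that are
themselves enriched in the peaks?* A TF that dominates a cell state should
bind near many genes of the ontology terms that characterise that state,
not merely bind often.

## Single-run model

Inputs: a query peak set (BED, optional SCORE column), one BED track of
predicted conserved binding sites per TF (each track truncated to its
`per_tf_cap` = 5,000 best-scoring sites), gene models (TSV of gene id,
chromosome, strand, TSS), gene–term annotations plus is_a edges of an
ontology, chromosome sizes, and an optional assembly-gap BED.

**Regulatory domains.** Each gene receives a basal domain around its
canonical TSS — 5 kb upstream and 1 kb downstream by default, strand-aware
— extended in both directions up to 1 Mb but stopping at the nearest
neighbouring gene's basal domain, clipped to the chromosome. These
defaults are the standard basal-plus-extension values and are
configurable. A gene always keeps its own basal domain even when a
neighbour's basal domain overlaps it. Annotations are propagated upward
over is_a edges before any counting; the 2–500 gene filter on terms is
applied to post-propagation counts.

**Term selection.** Query elements are kept whole if they overlap ≥ 1 bp
of any TF's predicted site (element selection, not trimming). Each
candidate term π is scored two ways:

- region binomial: P(X ≥ hits), X ~ Bin(|query elements|, p_π), where
  p_π is the fraction of non-gap bases covered by the merged regulatory
  domains of the term's genes, and `hits` counts query elements
  overlapping that merged domain;
- gene hypergeometric: of the n annotated genes whose domain the query
  touches, how many are the term's, out of K term genes in the universe N
  of genes with ≥ 1 annotation.

Terms are ranked by ascending binomial p, ties by ascending
hypergeometric p, then term id, and the top K = 100 are kept
(π₁, …, π_K). The ordering is K-independent, so a smaller K selects a
prefix. The binomial leads the key because it is the region-level
statistic the selection is about; the hypergeometric guards against
enrichment driven by a single gene's long domain and is reported.

**TF-by-term matrices.** With n_i = #\{TFBS_i ∩ QUERY\},
k_ij = #\{(TFBS_i ∩ QUERY) ∩ RegDom_j\}, N = #\{∪_k TFBS_k ∩ QUERY\} and
K_j the same count for the union track, each (TF, term) pair gets

- a hypergeometric tail P(X ≥ k_ij) with parameters (n_i, K_j, N) —
  "is this TF's share of in-query sites inside the term's domain larger
  than the all-TF background share?" — and
- a binomial tail P(X ≥ k_ij), X ~ Bin(n_i, p_π) — "are this TF's
  in-query sites inside the domain beyond what uniform placement gives?"

All counts are element-level; exact-coordinate duplicate sites collapse in
the union track (and within a track at load). A TF with no sites in the
query gets p = 1 everywhere and simply ranks at the bottom, keeping the TF
count constant across terms.

**Adaptive leap threshold.** For each term and each test column the top 10
p-values p₁ ≤ … ≤ p₁₀ are inspected; d_k = −log(p_k / p_{k+1}); the
threshold is p_m at m = argmax_k d_k (smallest index on ties, the more
stringent choice); every TF with p ≤ p_m is kept — including ties beyond
rank 10. A term with a lone finite p-value keeps that TF: a leap is
undefined there, and failing the term would silently drop signal. A TF is
*significant* for a term when it passes both columns' thresholds. P-values
are carried as natural-log values end to end, so the leap statistic never
collapses on underflow; linear-scale outputs are floored at the smallest
positive subnormal float.

**Score.** Within each term TFs are ranked by ascending hypergeometric p,
ties by binomial p, then name (the threshold machinery is built around the
hypergeometric column, so it also defines Rank; this is a deliberate,
isolated choice). Then

    partial(i, j) = Significant(i, j) / (j · Rank(i, j))
    score(i)      = Σ_j partial(i, j)

Final ordering is by descending score, exact ties alphabetical. Per TF the
report lists the driving terms by descending partial score and whether
each term also annotates the TF's own gene ("closed loop"; `unavailable`
when the TF has no gene mapping).

## Conditional p-values

The null holds each term's TF ordering uniform and independent. For one
focal TF, term j contributes 1/(j·r) when the focal TF lands on a
significant position r, else 0, so the null score distribution is the
K-fold convolution of small discrete distributions. It is built by dynamic
programming over (cumulative score, configuration count) tuples with
scores as exact rationals (`fractions.Fraction`), merged on equality;
level j's counts always sum to N_tf^j (asserted). The i-th ranked TF's
p-value is conditional: the i−1 higher-scoring TFs are removed from every
term's rank list, remaining ranks are compacted preserving order,
significance flags are retained (not re-derived), the focal TF's score is
recomputed under compacted ranks, and the null is rebuilt on N_tf−(i−1)
TFs. For i = 1 nothing is removed, so the conditional p-value *is* the
marginal one, bit-exactly.

### Numerical choices in the tail computation

The pipeline needs only P(score ≥ x), not the whole distribution, and two
exact prunings keep that cheap: states at or above x are absorbed into one
bucket (summands are non-negative, the bucket is closed), and states that
cannot reach x even by adding every later term's maximum summand fall into
a dead bucket. Both preserve exact rational arithmetic and the result is
identical to reading the full distribution's tail.

When a term's p-value column is all ties (typical for sparse differential
queries: many TFs with p = 1), the tie rule marks every TF significant and
the exact DP's live states can still grow combinatorially — distinct sums
of unit fractions essentially never collide. If live states exceed 20,000
the computation restarts on a discretised grid: summands are floored onto
~200,000 bins spanning [0, x), so a configuration counted into the ≥ x
bucket truly scores ≥ x and the reported tail underestimates by at most
the probability mass in [x − K·grid, x). The switch is logged. Fixture
single-mode runs stay on the exact path; the full-distribution API
(`null_score_distribution`) always uses exact rationals (with a 2×10⁶
state cap and 12-digit rounding fallback that small instances never hit).

## Baseline and differential modes

The abundance-only comparator ranks TFs by binomial fold
(m_i/M_i)/c — sites-in-query over genome coverage of the query — with the
binomial tail p reported; no functional annotation is used. Genome length
is the sum of chromosome lengths (configurable to non-gap).

Differential mode derives A∖B by base-level subtraction (the same
semantics as `bedtools subtract`; a whole-feature mode is a flag) and runs
the single-mode pipeline on each direction. A set-combination form
(∩ group1) ∖ (∪ group2) supports multi-replicate contrasts. An empty
direction produces an empty report with a logged reason rather than an
error.

## Synthetic study conditions

The generator writes complete input bundles: by default one 1 Mb
chromosome, 60 genes (alternating strands, jittered even spacing), a
two-level ontology of 9 leaf terms (5 contiguous genes each) under 3
roots, 20 TFs × 300 sites of 10 bp, and 400 scored peaks of 300 bp. A
terminal 5 kb assembly gap exercises the non-gap bookkeeping; placements
avoid chromosome edges by one site length so clipping corner cases are
exercised only by dedicated micro-fixtures.

Planted structure: 40% of peaks fall inside the planted leaf term's merged
regulatory domain, making that term the top selection. The planted TF
places 60% of its sites in the query and, of those, a fraction
`concentration` (default 0.8) inside (query ∩ planted-term domain). The
decoy TF has twice the sites (600) and puts 85% of them in the query,
uniformly with respect to term domains — it therefore leads the
abundance-only baseline while contributing no stratified signal. The
remaining 18 TFs are uniform background. The unstated magnitudes (in-query
fractions, decoy multiplier, peak-in-domain fraction) were fixed once at
values typical of a strong cell-type-specific factor versus a pervasive
binder: they put the planted and decoy TFs at comparable raw in-query
abundance (180 vs 510 of 1,000–1,600 in-query union sites) so that only
the term-stratified concentration separates them.

The differential generator shares all reference files between two queries:
a common core of peaks plus direction-specific peaks placed in each side's
own planted term domain (terms chosen under different ontology roots, so
the two signals do not meet at a shared ancestor), with each direction's
planted TF concentrated in its own unique regions and the decoy seeking
both queries.

What the generator does *not* emulate: read-depth noise, peak-caller
artefacts, irregular gene density, deep ontologies, correlated TF
families, and genome-scale coordinates. Passing tests therefore
demonstrate the statistical machinery — selection, masking, scoring,
exact nulls, subtraction — under controlled conditions, not performance on
real chromatin data.

## Problem sizes and tolerances

Exact-statistics oracles run on randomised grids with populations ≤ 25
(rational-arithmetic summation, agreement to ~12 significant digits); the
DP is checked against enumeration over all N_tf^K configurations for
N_tf ≤ 5, K ≤ 4 (200 random instances, exact equality). Recovery and
contrast claims use 40 generator seeds per condition at concentrations
{0, 0.4, 0.8}; robustness uses subsample fractions {0.7, 0.8, 0.9, 1.0}
(ties at the cutoff score broken at random per seed, kept count rounded
half-up), midpoint-preserving trims {200, 500, 1000, none} and
K ∈ {50, 100, 150}, varied one axis at a time. These sizes keep a full
verification run in minutes on one core while leaving each statistical
check at its designed resolution.

## Known limitations

- Rank within a term is defined on the hypergeometric column; the score
  formula itself does not dictate this, and the choice is isolated in
  `rank_within_terms` so alternatives (binomial, combined) can be swapped.
- Significance flags are retained, not re-derived, after conditioning
  removals; re-running the leap threshold on the reduced TF set is a
  defensible alternative reading and would change conditional p-values
  below rank 1.
- The all-ties rule keeps entire uninformative terms significant, which
  adds small noise scores to every TF in sparse queries; downstream this
  is harmless for the ranking (the noise is shared) but it is why the
  discretised tail fallback exists.
- Chromosome names are compared as exact strings; `chr1` vs `1` raises
  immediately rather than guessing an aliasing.
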