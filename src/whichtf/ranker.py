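"""TF ranking core: TF-by-term enrichment matrices, adaptive significance
masking, rank-based partial scores, and exact conditional p-values.

The score of a TF is the sum over selected terms pi_j of
``Significant(TF, pi_j) / (j * Rank(TF, pi_j))`` — a nonparametric,
rank-based statistic. Its null distribution, under the model that any
ordering of TFs within each term is equally likely, is computed exactly by
dynamic programming over (cumulative score, configuration count) tuples
held as rational numbers, so the identity "conditional p of the top-ranked
TF == its marginal p" holds bit-exactly.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .enrichstats import adaptive_threshold, binomial_logtail, hypergeometric_logtail
from .intervals import GenomicIntervalSet, select_overlapping_elements
from .refdata import AnnotationTable, ReferenceData, TFBSLibrary
from .termselect import TermSelection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentMatrix",
    "SignificanceMask",
    "ScoreDistribution",
    "TFRankingRow",
    "TFRanking",
    "compute_tf_term_matrix",
    "rank_within_terms",
    "significance_mask",
    "partial_scores",
    "null_score_distribution",
    "null_score_tail",
    "conditional_pvalues",
    "top_contributing_terms",
    "closed_loop_check",
    "rank_tfs",
]


@dataclass
class EnrichmentMatrix:
    """Per-(TF, term) counts and p-values (natural-log scale).

    Rows follow `tf_names`, columns `term_ids`. `n_i[i]` is the number of
    TF i's sites overlapping the query, `k_ij[i, j]` how many of those also
    overlap term j's merged regulatory domain; `N_elem` / `K_j` are the same
    counts for the deduplicated union of all TF tracks.
    """

    tf_names: list[str]
    term_ids: list[str]
    n_i: np.ndarray  # (n_tf,)
    k_ij: np.ndarray  # (n_tf, K)
    N_elem: int
    K_j: np.ndarray  # (K,)
    hyper_logp: np.ndarray  # (n_tf, K)
    binom_logp: np.ndarray  # (n_tf, K)

    @property
    def n_tf(self) -> int:
        return len(self.tf_names)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)


@dataclass
class SignificanceMask:
    """Significant(TF_i, pi_j): passed BOTH adaptive thresholds for the term."""

    mask: np.ndarray  # bool (n_tf, K)


def compute_tf_term_matrix(
    query: GenomicIntervalSet,
    tfbs_lib: TFBSLibrary,
    selection: TermSelection,
    refs: ReferenceData,
) -> EnrichmentMatrix:
    """Count binding sites in the query and in each term's domain; test both.

    A TF with no sites in the query gets p = 1 for every term (it simply
    carries no evidence), keeping the TF count constant across terms.
    """
    if len(selection) == 0:
        raise ValueError("empty term selection")
    tf_names = tfbs_lib.tf_names
    term_ids = selection.term_ids
    annot = refs.annotations

    union_in_query = select_overlapping_elements(tfbs_lib.union_track(), query)
    N_elem = len(union_in_query)
    per_tf_in_query = {
        tf: select_overlapping_elements(tfbs_lib.tracks[tf], query)
        for tf in tf_names
    }

    n_tf, K = len(tf_names), len(term_ids)
    n_i = np.array([len(per_tf_in_query[tf]) for tf in tf_names], dtype=np.int64)
    k_ij = np.zeros((n_tf, K), dtype=np.int64)
    K_j = np.zeros(K, dtype=np.int64)
    hyper_logp = np.zeros((n_tf, K))
    binom_logp = np.zeros((n_tf, K))

    for j, term in enumerate(term_ids):
        dom = annot.term_domain(term)
        K_j[j] = len(select_overlapping_elements(union_in_query, dom))
        p_pi = annot.term_base_probability(term)
        for i, tf in enumerate(tf_names):
            if n_i[i] == 0:
                continue  # logp already 0 -> p = 1
            k = len(select_overlapping_elements(per_tf_in_query[tf], dom))
            k_ij[i, j] = k
            hyper_logp[i, j] = hypergeometric_logtail(
                k, int(n_i[i]), int(K_j[j]), N_elem
            )
            binom_logp[i, j] = binomial_logtail(k, int(n_i[i]), p_pi)

    return EnrichmentMatrix(
        tf_names=tf_names,
        term_ids=term_ids,
        n_i=n_i,
        k_ij=k_ij,
        N_elem=N_elem,
        K_j=K_j,
        hyper_logp=hyper_logp,
        binom_logp=binom_logp,
    )


def rank_within_terms(matrix: EnrichmentMatrix) -> np.ndarray:
    """1-based rank of each TF within each term.

    Sort key per term: ascending hypergeometric p, ties by ascending
    binomial p, then TF name; ranks are a permutation of 1..n_tf.
    """
    n_tf, K = matrix.n_tf, matrix.n_terms
    ranks = np.zeros((n_tf, K), dtype=np.int64)
    for j in range(K):
        order = sorted(
            range(n_tf),
            key=lambda i: (
                matrix.hyper_logp[i, j],
                matrix.binom_logp[i, j],
                matrix.tf_names[i],
            ),
        )
        for r, i in enumerate(order, start=1):
            ranks[i, j] = r
    return ranks


def significance_mask(
    matrix: EnrichmentMatrix, top_m: int = 10
) -> SignificanceMask:
    """AND of the per-term adaptive-leap thresholds on both test columns."""
    n_tf, K = matrix.n_tf, matrix.n_terms
    mask = np.zeros((n_tf, K), dtype=bool)
    name_to_idx = {nm: i for i, nm in enumerate(matrix.tf_names)}
    for j in range(K):
        hyp = adaptive_threshold(
            {nm: matrix.hyper_logp[i, j] for i, nm in enumerate(matrix.tf_names)},
            top_m=top_m,
            log=True,
        )
        bino = adaptive_threshold(
            {nm: matrix.binom_logp[i, j] for i, nm in enumerate(matrix.tf_names)},
            top_m=top_m,
            log=True,
        )
        for nm in hyp.kept & bino.kept:
            mask[name_to_idx[nm], j] = True
    return SignificanceMask(mask=mask)


def partial_scores(
    mask: SignificanceMask, ranks: np.ndarray
) -> tuple[list[dict[int, Fraction]], list[Fraction]]:
    """Partial scores 1/(j*Rank) where significant, and their per-TF sums.

    Returns (per-TF {term index (0-based) -> partial}, per-TF total score),
    both in exact rational arithmetic.
    """
    n_tf, K = ranks.shape
    partials: list[dict[int, Fraction]] = []
    scores: list[Fraction] = []
    for i in range(n_tf):
        row: dict[int, Fraction] = {}
        for j in range(K):
            if mask.mask[i, j]:
                row[j] = Fraction(1, (j + 1) * int(ranks[i, j]))
        partials.append(row)
        scores.append(sum(row.values(), Fraction(0)))
    return partials, scores


@dataclass
class ScoreDistribution:
    """Exact null of the score as per-level (score, configuration count) sets.

    `levels[j]` maps cumulative score after the first j terms to its
    configuration count; `levels[0]` is {0: 1}. Configuration conservation
    (counts at level j summing to n_tf**j) is checked at construction.
    """

    n_tf: int
    summands: list[list[Fraction]]  # nonzero summands per term (level order)
    levels: list[dict[Fraction, int]]
    rounded: bool = False  # True if the state-cap fallback engaged

    @property
    def final(self) -> dict[Fraction, int]:
        return self.levels[-1]

    def tail_probability(self, x: Fraction) -> Fraction:
        """P(score >= x) under the uniform-ordering null."""
        total = self.n_tf ** (len(self.levels) - 1)
        hits = sum(c for s, c in self.final.items() if s >= x)
        return Fraction(hits, total)


def null_score_distribution(
    per_term_significant_positions: Sequence[Sequence[int]],
    N_tf: int,
    *,
    max_states: int = 2_000_000,
    round_ndigits: int = 12,
) -> ScoreDistribution:
    """Exact score null via DP over (cumulative score, configuration count).

    Term j (1-based level) contributes a summand 1/(j*r) for each
    significant rank position r, and 0 with multiplicity N_tf minus the
    number of significant positions. Scores are exact rationals merged on
    equality; if the number of distinct states exceeds `max_states` the DP
    falls back to rounding scores at `round_ndigits` decimal digits (logged).
    """
    if N_tf < 1:
        raise ValueError("N_tf must be >= 1")
    summands: list[list[Fraction]] = []
    for j, positions in enumerate(per_term_significant_positions, start=1):
        pos = sorted(set(int(r) for r in positions))
        if pos and (pos[0] < 1 or pos[-1] > N_tf):
            raise ValueError(f"term {j}: positions must lie in 1..{N_tf}")
        if len(pos) > N_tf:
            raise ValueError(f"term {j}: more significant positions than TFs")
        summands.append([Fraction(1, j * r) for r in pos])

    scale = Fraction(10) ** round_ndigits
    rounded = False
    levels: list[dict[Fraction, int]] = [{Fraction(0): 1}]
    cur: dict[Fraction, int] = {Fraction(0): 1}
    for terms in summands:
        n_zero = N_tf - len(terms)
        nxt: dict[Fraction, int] = {}
        for s, c in cur.items():
            if n_zero:
                nxt[s] = nxt.get(s, 0) + c * n_zero
            for t in terms:
                s2 = s + t
                nxt[s2] = nxt.get(s2, 0) + c
        if len(nxt) > max_states:
            rounded = True
            logger.warning(
                "score DP exceeded %d states; rounding scores to %d digits",
                max_states,
                round_ndigits,
            )
            merged: dict[Fraction, int] = {}
            for s, c in nxt.items():
                sr = Fraction(round(s * scale)) / scale
                merged[sr] = merged.get(sr, 0) + c
            nxt = merged
        cur = nxt
        levels.append(cur)

    for j, lvl in enumerate(levels):
        assert sum(lvl.values()) == N_tf**j, "configuration conservation violated"
    return ScoreDistribution(
        n_tf=N_tf, summands=summands, levels=levels, rounded=rounded
    )


def null_score_tail(
    per_term_significant_positions: Sequence[Sequence[int]],
    N_tf: int,
    x: Fraction,
    *,
    max_states: int = 20_000,
) -> Fraction:
    """P(score >= x) without materialising the full distribution.

    Summands are non-negative, so every configuration at or above `x` stays
    there: such states collapse into one absorbing bucket. Symmetrically, a
    state that cannot reach `x` even by adding the maximum remaining summand
    of every later term collapses into a dead bucket. Only states inside the
    shrinking live window stay explicit, in exact rational arithmetic;
    the result is identical to
    ``null_score_distribution(...).tail_probability(x)``.

    If the live window still holds more than `max_states` states the DP
    restarts on a discretised score grid (see
    :func:`_null_score_tail_discretised`); the switch is logged.
    """
    if N_tf < 1:
        raise ValueError("N_tf must be >= 1")
    if x <= 0:
        return Fraction(1)
    K = len(per_term_significant_positions)
    summands: list[list[Fraction]] = []
    for j, positions in enumerate(per_term_significant_positions, start=1):
        pos = sorted(set(int(r) for r in positions))
        if pos and (pos[0] < 1 or pos[-1] > N_tf):
            raise ValueError(f"term {j}: positions must lie in 1..{N_tf}")
        summands.append([Fraction(1, j * r) for r in pos])
    # max_remaining[j]: largest total still addable after the first j terms
    max_remaining = [Fraction(0)] * (len(summands) + 1)
    for j in range(len(summands) - 1, -1, -1):
        biggest = max(summands[j], default=Fraction(0))
        max_remaining[j] = max_remaining[j + 1] + biggest

    below: dict[Fraction, int] = {Fraction(0): 1}
    ge = 0
    dead = 0
    for j, terms in enumerate(summands, start=1):
        n_zero = N_tf - len(terms)
        ge *= N_tf
        dead *= N_tf
        floor = x - max_remaining[j]
        nxt: dict[Fraction, int] = {}
        for s, c in below.items():
            if n_zero:
                if s < floor:
                    dead += c * n_zero
                else:
                    nxt[s] = nxt.get(s, 0) + c * n_zero
            for t in terms:
                s2 = s + t
                if s2 >= x:
                    ge += c
                elif s2 < floor:
                    dead += c
                else:
                    nxt[s2] = nxt.get(s2, 0) + c
        below = nxt
        assert ge + dead + sum(below.values()) == N_tf**j
        if len(below) > max_states:
            logger.warning(
                "exact tail DP exceeded %d live states at level %d; "
                "switching to discretised DP",
                max_states,
                j,
            )
            return _null_score_tail_discretised(summands, N_tf, x)
    return Fraction(ge, N_tf**K)


def _null_score_tail_discretised(
    summands: Sequence[Sequence[Fraction]],
    N_tf: int,
    x: Fraction,
    n_bins_target: int = 200_000,
) -> Fraction:
    """Approximate P(score >= x) on a fixed score grid (safety valve).

    Summands are floored onto multiples of `grid`, so the discretised sum
    of a configuration never exceeds its exact sum: a configuration counted
    into the absorbing >= x bucket truly scores >= x, and the tail is
    underestimated by at most the mass in [x - K*grid, x). The DP runs as a
    dense float64 vector of configuration counts per bin; counts lose
    relative precision ~1e-16, negligible for a reported p-value.
    """
    import numpy as _np

    grid = max(1e-12, float(x) / n_bins_target)
    n_bins = max(1, int(math.ceil(float(x) / grid)))  # live bins 0..n_bins-1
    counts = _np.zeros(n_bins)
    counts[0] = 1.0
    ge = 0.0
    for terms in summands:
        n_zero = N_tf - len(terms)
        new = counts * n_zero
        ge *= N_tf
        for t in terms:
            shift = int(float(t) / grid)  # floor
            if shift >= n_bins:
                ge += counts.sum()
            elif shift == 0:
                new += counts
            else:
                new[shift:] += counts[:-shift]
                ge += counts[-shift:].sum()
        counts = new
    total = float(N_tf) ** len(summands)
    p = ge / total
    return Fraction(min(max(p, 0.0), 1.0))


def conditional_pvalues(
    order: Sequence[int],
    mask: SignificanceMask,
    ranks: np.ndarray,
    N_tf: int,
) -> list[Fraction]:
    """Conditional p-value for each TF, in score order (best first).

    For the i-th TF, the i-1 higher-scoring TFs are deleted from every
    term's rank list; the remaining ranks are compacted preserving order,
    significance flags are retained, the focal TF's observed score is
    recomputed under the compacted ranks, and the exact null on
    N_tf - (i-1) TFs gives P(score >= observed). For i = 1 this is exactly
    the marginal p-value.
    """
    n_tf, K = ranks.shape
    out: list[Fraction] = []
    for i0, focal in enumerate(order):
        removed = list(order[:i0])
        removed_ranks_per_term = [
            sorted(int(ranks[r, j]) for r in removed) for j in range(K)
        ]
        remaining = [t for t in range(n_tf) if t not in set(removed)]
        positions: list[list[int]] = []
        observed = Fraction(0)
        for j in range(K):
            rr = removed_ranks_per_term[j]
            pos_j = []
            for t in remaining:
                if mask.mask[t, j]:
                    new_rank = int(ranks[t, j]) - bisect_left(rr, int(ranks[t, j]))
                    pos_j.append(new_rank)
                    if t == focal:
                        observed += Fraction(1, (j + 1) * new_rank)
            positions.append(sorted(pos_j))
        if observed == 0:
            out.append(Fraction(1))
        else:
            out.append(null_score_tail(positions, N_tf - i0, observed))
    return out


def top_contributing_terms(
    tf_index: int,
    partials: list[dict[int, Fraction]],
    term_ids: Sequence[str],
    n_top: Optional[int] = None,
) -> list[tuple[str, Fraction]]:
    """Terms with positive partial score, best first (ties: earlier term)."""
    items = sorted(
        partials[tf_index].items(), key=lambda kv: (-kv[1], kv[0])
    )
    if n_top is not None:
        items = items[:n_top]
    return [(term_ids[j], p) for j, p in items]


def closed_loop_check(
    tf: str,
    term: str,
    annot: AnnotationTable,
    tf_gene_map: dict[str, str],
) -> Optional[bool]:
    """Does the driving term annotate the TF's own gene?

    Returns True/False, or None ("unavailable") when the TF has no mapped
    gene — a missing mapping is not evidence of absence.
    """
    gene = tf_gene_map.get(tf)
    if gene is None:
        return None
    return annot.is_annotated(gene, term)


@dataclass
class TFRankingRow:
    rank: int
    tf: str
    score: Fraction
    cond_p: Fraction
    top_terms: list[tuple[str, Fraction]]
    closed_loop: list[Optional[bool]]

    @property
    def score_float(self) -> float:
        return float(self.score)

    @property
    def neglog10_cond_p(self) -> float:
        if self.cond_p <= 0:
            return math.inf
        return math.log10(self.cond_p.denominator) - math.log10(
            self.cond_p.numerator
        )


@dataclass
class TFRanking:
    rows: list[TFRankingRow]
    matrix: EnrichmentMatrix
    mask: SignificanceMask
    ranks: np.ndarray
    selection: TermSelection

    @property
    def tf_order(self) -> list[str]:
        return [r.tf for r in self.rows]

    def row_for(self, tf: str) -> TFRankingRow:
        for r in self.rows:
            if r.tf == tf:
                return r
        raise KeyError(tf)


def rank_tfs(
    query: GenomicIntervalSet,
    tfbs_lib: TFBSLibrary,
    selection: TermSelection,
    refs: ReferenceData,
    top_m: int = 10,
    n_top_terms: int = 5,
) -> TFRanking:
    """Full ranking stage: matrix -> mask -> ranks -> scores -> conditional p.

    Final ordering is by descending score; exact ties break lexicographically
    by TF name.
    """
    matrix = compute_tf_term_matrix(query, tfbs_lib, selection, refs)
    ranks = rank_within_terms(matrix)
    mask = significance_mask(matrix, top_m=top_m)
    partials, scores = partial_scores(mask, ranks)
    logger.info(
        "ranking %d TFs over %d terms; %d significant cells",
        matrix.n_tf,
        matrix.n_terms,
        int(mask.mask.sum()),
    )
    order = sorted(
        range(matrix.n_tf),
        key=lambda i: (-scores[i], matrix.tf_names[i]),
    )
    cond = conditional_pvalues(order, mask, ranks, matrix.n_tf)
    rows = []
    for pos, (i, p) in enumerate(zip(order, cond), start=1):
        terms = top_contributing_terms(i, partials, matrix.term_ids, n_top_terms)
        loops = [
            closed_loop_check(
                matrix.tf_names[i], t, refs.annotations, tfbs_lib.tf_gene_map
            )
            for t, _ in terms
        ]
        rows.append(
            TFRankingRow(
                rank=pos,
                tf=matrix.tf_names[i],
                score=scores[i],
                cond_p=p,
                top_terms=terms,
                closed_loop=loops,
            )
        )
    return TFRanking(
        rows=rows, matrix=matrix, mask=mask, ranks=ranks, selection=selection
    )
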