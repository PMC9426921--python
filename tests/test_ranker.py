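"""Ranking core: rank matrices, masking, partial scores, and the exact
score-null dynamic programming against brute-force enumeration."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from whichtf.enrichstats import adaptive_threshold
from whichtf.ranker import (
    EnrichmentMatrix,
    SignificanceMask,
    closed_loop_check,
    conditional_pvalues,
    null_score_distribution,
    null_score_tail,
    partial_scores,
    rank_within_terms,
    significance_mask,
    top_contributing_terms,
)


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

def enumerate_null(positions_per_term, N_tf):
    """Score of every one of the N_tf**K configurations, by brute force."""
    K = len(positions_per_term)
    scores = []
    for config in product(range(1, N_tf + 1), repeat=K):
        s = Fraction(0)
        for j, r in enumerate(config, start=1):
            if r in positions_per_term[j - 1]:
                s += Fraction(1, j * r)
        scores.append(s)
    return scores


def enumerate_tail(positions_per_term, N_tf, x):
    scores = enumerate_null(positions_per_term, N_tf)
    return Fraction(sum(1 for s in scores if s >= x), len(scores))


def random_instance(rng, max_tf=5, max_k=4):
    N_tf = int(rng.integers(1, max_tf + 1))
    K = int(rng.integers(1, max_k + 1))
    positions = []
    for _ in range(K):
        n_sig = int(rng.integers(0, N_tf + 1))
        positions.append(
            sorted(rng.choice(range(1, N_tf + 1), size=n_sig, replace=False).tolist())
        )
    return N_tf, positions


def matrix_from_p(tf_names, term_ids, hyper_p, binom_p):
    """Build an EnrichmentMatrix carrying given linear p-values."""
    h = np.log(np.asarray(hyper_p, dtype=float))
    b = np.log(np.asarray(binom_p, dtype=float))
    n_tf, K = h.shape
    return EnrichmentMatrix(
        tf_names=list(tf_names),
        term_ids=list(term_ids),
        n_i=np.ones(n_tf, dtype=np.int64),
        k_ij=np.zeros((n_tf, K), dtype=np.int64),
        N_elem=n_tf,
        K_j=np.ones(K, dtype=np.int64),
        hyper_logp=h,
        binom_logp=b,
    )


class TestRankWithinTerms:
    def test_sort_order_and_tie_rule(self):
        m = matrix_from_p(
            ["B", "A", "C"],
            ["t1"],
            hyper_p=[[0.5], [0.5], [0.01]],
            binom_p=[[0.2], [0.2], [0.9]],
        )
        ranks = rank_within_terms(m)
        # C leads; A and B tie on both p-values -> alphabetical
        assert ranks[:, 0].tolist() == [3, 2, 1]

    def test_permutation_invariance(self, rng):
        names = [f"TF{i}" for i in range(6)]
        hp = rng.uniform(0.001, 1, size=(6, 3))
        bp = rng.uniform(0.001, 1, size=(6, 3))
        m = matrix_from_p(names, ["a", "b", "c"], hp, bp)
        base = {
            (names[i], j): int(rank_within_terms(m)[i, j])
            for i in range(6)
            for j in range(3)
        }
        perm = rng.permutation(6)
        m2 = matrix_from_p(
            [names[i] for i in perm], ["a", "b", "c"], hp[perm], bp[perm]
        )
        permuted = {
            (names[perm[i]], j): int(rank_within_terms(m2)[i, j])
            for i in range(6)
            for j in range(3)
        }
        assert base == permuted


class TestSignificanceMask:
    def test_and_semantics(self):
        # TF A leads hyper in t1 but trails binomial there -> not significant
        m = matrix_from_p(
            ["A", "B", "C"],
            ["t1"],
            hyper_p=[[1e-10], [0.5], [0.6]],
            binom_p=[[0.9], [1e-9], [0.8]],
        )
        mask = significance_mask(m).mask
        assert not mask.any()

    def test_joint_leaders_significant(self):
        m = matrix_from_p(
            ["A", "B", "C", "D"],
            ["t1"],
            hyper_p=[[1e-10], [1e-9], [0.5], [0.6]],
            binom_p=[[1e-8], [1e-7], [0.7], [0.9]],
        )
        mask = significance_mask(m).mask
        assert mask[:, 0].tolist() == [True, True, False, False]

    def test_all_equal_p_all_significant(self):
        m = matrix_from_p(
            ["A", "B", "C"],
            ["t1"],
            hyper_p=[[0.3]] * 3,
            binom_p=[[0.4]] * 3,
        )
        assert significance_mask(m).mask.all()


class TestPartialScores:
    def test_formula_values(self):
        mask = SignificanceMask(np.array([[True, True], [False, True]]))
        ranks = np.array([[1, 3], [2, 1]])
        partials, scores = partial_scores(mask, ranks)
        assert partials[0] == {0: Fraction(1, 1), 1: Fraction(1, 6)}
        assert scores[0] == Fraction(7, 6)
        assert partials[1] == {1: Fraction(1, 2)}

    def test_insignificant_tf_scores_zero(self):
        mask = SignificanceMask(np.zeros((2, 3), dtype=bool))
        ranks = np.tile(np.array([[1], [2]]), (1, 3))
        _, scores = partial_scores(mask, ranks)
        assert scores == [Fraction(0), Fraction(0)]

    def test_clearing_flag_never_increases_score(self, rng):
        mask = rng.random((4, 3)) < 0.5
        ranks = np.array([rng.permutation(4) + 1 for _ in range(3)]).T
        _, base = partial_scores(SignificanceMask(mask.copy()), ranks)
        on = np.argwhere(mask)
        if len(on):
            i, j = on[0]
            mask[i, j] = False
            _, cleared = partial_scores(SignificanceMask(mask), ranks)
            assert cleared[i] < base[i]


class TestNullScoreDistribution:
    def test_worked_example_three_tfs(self):
        dist = null_score_distribution([[1], [1, 2]], 3)
        want = {
            Fraction(3, 2): 1,
            Fraction(5, 4): 1,
            Fraction(1): 1,
            Fraction(1, 2): 2,
            Fraction(1, 4): 2,
            Fraction(0): 2,
        }
        assert dist.final == want
        assert dist.tail_probability(Fraction(5, 4)) == Fraction(2, 9)

    def test_no_significant_positions(self):
        dist = null_score_distribution([[], [], []], 4)
        assert dist.final == {Fraction(0): 64}
        assert dist.tail_probability(Fraction(0)) == 1

    def test_matches_enumeration(self, rng):
        for _ in range(25):
            N_tf, positions = random_instance(rng)
            dist = null_score_distribution(positions, N_tf)
            scores = enumerate_null(positions, N_tf)
            want = {}
            for s in scores:
                want[s] = want.get(s, 0) + 1
            assert dist.final == want

    def test_configuration_conservation_every_level(self, rng):
        N_tf, positions = random_instance(rng)
        dist = null_score_distribution(positions, N_tf)
        for j, level in enumerate(dist.levels):
            assert sum(level.values()) == N_tf**j

    def test_tail_function_agrees_with_distribution(self, rng):
        for _ in range(25):
            N_tf, positions = random_instance(rng)
            dist = null_score_distribution(positions, N_tf)
            for x in sorted(dist.final)[:: max(1, len(dist.final) // 5)]:
                assert null_score_tail(positions, N_tf, x) == dist.tail_probability(x)

    def test_invalid_positions(self):
        with pytest.raises(ValueError):
            null_score_distribution([[5]], 3)


class TestConditionalPvalues:
    def oracle(self, order, mask, ranks, N_tf):
        """Sequential removal + compaction + enumeration, independently."""
        n_tf, K = ranks.shape
        out = []
        for i0, focal in enumerate(order):
            removed = set(order[:i0])
            positions = []
            observed = Fraction(0)
            for j in range(K):
                rr = sorted(int(ranks[t, j]) for t in removed)
                pos = []
                for t in range(n_tf):
                    if t in removed or not mask[t, j]:
                        continue
                    new_rank = int(ranks[t, j]) - sum(
                        1 for r in rr if r < ranks[t, j]
                    )
                    pos.append(new_rank)
                    if t == focal:
                        observed += Fraction(1, (j + 1) * new_rank)
                positions.append(sorted(pos))
            if observed == 0:
                out.append(Fraction(1))
            else:
                out.append(enumerate_tail(positions, N_tf - i0, observed))
        return out

    def random_mask_ranks(self, rng, n_tf, K):
        mask = rng.random((n_tf, K)) < 0.4
        ranks = np.array([rng.permutation(n_tf) + 1 for _ in range(K)]).T
        return mask, ranks

    def test_matches_sequential_enumeration(self, rng):
        for _ in range(20):
            n_tf = int(rng.integers(2, 5))
            K = int(rng.integers(1, 4))
            mask, ranks = self.random_mask_ranks(rng, n_tf, K)
            _, scores = partial_scores(SignificanceMask(mask), ranks)
            order = sorted(range(n_tf), key=lambda i: (-scores[i], i))
            got = conditional_pvalues(order, SignificanceMask(mask), ranks, n_tf)
            want = self.oracle(order, mask, ranks, n_tf)
            assert got == want

    def test_zero_score_gives_p_one(self):
        mask = np.zeros((3, 2), dtype=bool)
        ranks = np.array([[1, 2], [2, 1], [3, 3]])
        got = conditional_pvalues([0, 1, 2], SignificanceMask(mask), ranks, 3)
        assert got == [Fraction(1)] * 3

    def test_top_conditional_equals_marginal(self, rng):
        n_tf, K = 4, 3
        mask, ranks = self.random_mask_ranks(rng, n_tf, K)
        _, scores = partial_scores(SignificanceMask(mask), ranks)
        order = sorted(range(n_tf), key=lambda i: (-scores[i], i))
        got = conditional_pvalues(order, SignificanceMask(mask), ranks, n_tf)
        focal = order[0]
        positions = [
            sorted(int(ranks[t, j]) for t in range(n_tf) if mask[t, j])
            for j in range(K)
        ]
        marginal = (
            null_score_tail(positions, n_tf, scores[focal])
            if scores[focal] > 0
            else Fraction(1)
        )
        assert got[0] == marginal


class TestReportHelpers:
    def test_top_contributing_terms_order(self):
        partials = [{1: Fraction(1, 2), 0: Fraction(1, 3)}]
        got = top_contributing_terms(0, partials, ["early", "late"])
        assert got == [("late", Fraction(1, 2)), ("early", Fraction(1, 3))]

    def test_top_contributing_empty_for_zero_score(self):
        assert top_contributing_terms(0, [{}], ["t"]) == []

    def test_closed_loop_contract(self):
        from whichtf.refdata import OntologyGraph, propagate_annotations

        annot = propagate_annotations([("g1", "t")], OntologyGraph([], terms=["t"]))
        assert closed_loop_check("TF1", "t", annot, {"TF1": "g1"}) is True
        assert closed_loop_check("TF1", "u", annot, {"TF1": "g1"}) is False
        assert closed_loop_check("TF2", "t", annot, {"TF1": "g1"}) is None
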