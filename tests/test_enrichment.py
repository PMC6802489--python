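"""Hypergeometric enrichment, BH adjustment, and kappa term grouping."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from herbnet.enrichment import (
    bh_adjust,
    cohen_kappa_binary,
    enrich,
    hypergeom_pvalue,
    kappa_group_terms,
)
from herbnet.errors import DomainError, InputError
from herbnet.io import AnnotationSet


def upper_tail_exact(k, K, n, N):
    """Exact P(X >= k) by combinatorial enumeration (independent oracle)."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return float(acc)


class TestHypergeomPvalue:
    def test_zero_overlap_is_exactly_one(self):
        assert hypergeom_pvalue(0, 4, 5, 10) == 1.0

    def test_hand_enumerated_values(self):
        # drawing 5 of 10 with 4 marked: P(all 4 marked) = C(6,1)/C(10,5) = 6/252
        assert hypergeom_pvalue(4, 4, 5, 10) == pytest.approx(6 / 252, abs=1e-12)
        # C(3,3)*C(3,0)/C(6,3) = 1/20
        assert hypergeom_pvalue(3, 3, 3, 6) == pytest.approx(0.05, abs=1e-12)

    @pytest.mark.parametrize(
        "k,K,n,N", [(5, 4, 5, 10), (3, 4, 2, 10), (1, 11, 5, 10), (1, 4, 11, 10)]
    )
    def test_inconsistent_counts_rejected(self, k, K, n, N):
        with pytest.raises(DomainError):
            hypergeom_pvalue(k, K, n, N)

    def test_matches_enumeration_on_a_sample_grid(self):
        for N in (5, 8, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                            upper_tail_exact(k, K, n, N), abs=1e-12
                        )

    def test_p_decreases_as_overlap_grows(self):
        ps = [hypergeom_pvalue(k, 10, 20, 100) for k in range(0, 11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_stable_at_large_scale(self):
        # moderate tail stays a genuine probability; far tail underflows cleanly
        assert 0.0 < hypergeom_pvalue(60, 500, 5000, 50000) < 0.1
        assert 0.0 <= hypergeom_pvalue(400, 500, 5000, 50000) < 1e-100


def step_up_reference(ps):
    """Textbook BH step-up recomputation (independent oracle)."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, ps[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.04, 1.0]) == pytest.approx([0.08, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])

    def test_matches_reference_step_up_on_random_vectors(self, rng):
        for _ in range(200):
            ps = rng.uniform(0, 1, rng.integers(1, 30)).tolist()
            assert bh_adjust(ps) == pytest.approx(step_up_reference(ps), abs=1e-12)

    def test_adjusted_never_below_raw_and_capped_at_one(self, rng):
        ps = rng.uniform(0, 1, 50).tolist()
        adj = bh_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert max(adj) <= 1.0


def _annotations(terms, universe=None):
    built = {tid: (tid, frozenset(members)) for tid, members in terms.items()}
    uni = frozenset(universe) if universe is not None else frozenset(
        itertools.chain.from_iterable(m for _, m in built.values())
    )
    return AnnotationSet(terms=built, universe=uni)


class TestEnrich:
    def test_fully_recovered_term_ranks_first(self):
        universe = {f"g{i}" for i in range(60)}
        ann = _annotations(
            {"hit": {"g0", "g1", "g2", "g3"}, "other": {f"g{i}" for i in range(20, 40)}},
            universe,
        )
        results = enrich({"g0", "g1", "g2", "g3"}, ann)
        assert results[0].term_id == "hit"
        assert results[0].k == results[0].K == 4
        assert results[0].retained

    def test_disjoint_query_warns_and_returns_empty(self):
        ann = _annotations({"t": {"g1", "g2"}})
        with pytest.warns(UserWarning):
            assert enrich({"zz"}, ann) == []

    def test_query_restricted_to_universe(self):
        ann = _annotations({"t": {"g1", "g2", "g3"}}, universe={f"g{i}" for i in range(10)})
        [res] = enrich({"g1", "g2", "outsider"}, ann)
        assert res.n == 2  # outsider dropped from the query size
        assert res.k == 2

    def test_empty_annotation_set_is_an_input_error(self):
        with pytest.raises(InputError):
            enrich({"g1"}, AnnotationSet(terms={}, universe=frozenset({"g1"})))

    def test_results_sorted_by_p_then_term(self):
        universe = {f"g{i}" for i in range(100)}
        ann = _annotations(
            {"a": {"g0", "g1", "g2"}, "b": {"g0", "g1", "g50"}, "c": {"g0", "g99"}},
            universe,
        )
        results = enrich({"g0", "g1", "g2"}, ann)
        ps = [r.p_raw for r in results]
        assert ps == sorted(ps)

    def test_planted_term_recovered_in_most_replicates(self, rng):
        # planted study shape: term of 20, query of 25 overlapping in 15,
        # universe of 500; power at alpha=0.05 should exceed 0.95
        universe = [f"g{i}" for i in range(500)]
        hits = 0
        reps = 200
        for _ in range(reps):
            term = rng.choice(universe, 20, replace=False).tolist()
            overlap = rng.choice(term, 15, replace=False).tolist()
            outside = [g for g in universe if g not in term]
            query = overlap + rng.choice(outside, 10, replace=False).tolist()
            ann = _annotations({"planted": set(term)}, universe)
            results = enrich(set(query), ann, alpha=0.05)
            if results and results[0].retained:
                hits += 1
        assert hits / reps >= 0.95

    def test_null_type_one_rate_matches_attainable_level(self, rng):
        # discrete test: compare the observed rejection rate to the exact
        # attainable level of the 0.05 threshold for this (K, n, N)
        N, K, n = 400, 40, 50
        universe = [f"g{i}" for i in range(N)]
        term = set(universe[:K])
        alpha_eff = 0.0
        for k in range(K + 1):
            p = hypergeom_pvalue(k, K, n, N) if k <= min(K, n) else 0.0
            if k >= 1 and p <= 0.05:
                alpha_eff = p
                break
        reps = 400
        rejections = 0
        for _ in range(reps):
            query = set(rng.choice(universe, n, replace=False).tolist())
            ann = _annotations({"t": term}, universe)
            results = enrich(query, ann, alpha=0.05)
            if results and results[0].retained:
                rejections += 1
        observed = rejections / reps
        se = np.sqrt(alpha_eff * (1 - alpha_eff) / reps)
        assert abs(observed - alpha_eff) <= 3 * se + 1e-9


class TestKappaGrouping:
    def test_kappa_against_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        domain = [f"g{i}" for i in range(20)]
        for _ in range(50):
            a = {g for g in domain if rng.random() < 0.4}
            b = {g for g in domain if rng.random() < 0.4}
            va = [int(g in a) for g in domain]
            vb = [int(g in b) for g in domain]
            if len(set(va)) < 2 and len(set(vb)) < 2:
                continue  # sklearn's kappa is degenerate there; handled separately
            expected = cohen_kappa_score(va, vb)
            if np.isnan(expected):
                continue
            assert cohen_kappa_binary(a, b, domain) == pytest.approx(expected, abs=1e-12)

    def test_identical_hit_sets_form_one_group(self):
        from herbnet.enrichment import EnrichmentResult

        shared = frozenset({"g1", "g2", "g3"})
        results = [
            EnrichmentResult("a", "a", 3, 5, 3, 50, 0.01, 0.02, shared, True),
            EnrichmentResult("b", "b", 3, 5, 3, 50, 0.02, 0.02, shared, True),
        ]
        groups = kappa_group_terms(results, kappa_min=0.4)
        assert len(groups) == 1
        assert groups[0]["leading_term"] == "a"

    def test_disjoint_hit_sets_stay_separate(self):
        from herbnet.enrichment import EnrichmentResult

        results = [
            EnrichmentResult("a", "a", 3, 6, 3, 50, 0.01, 0.02,
                             frozenset({"g1", "g2", "g3"}), True),
            EnrichmentResult("b", "b", 3, 6, 3, 50, 0.02, 0.02,
                             frozenset({"g4", "g5", "g6"}), True),
        ]
        assert len(kappa_group_terms(results, kappa_min=0.2)) == 2

    def test_three_term_pattern_matches_brute_force_matrix(self):
        from herbnet.enrichment import EnrichmentResult

        sets = {
            "a": frozenset({"g1", "g2", "g3", "g4"}),
            "b": frozenset({"g1", "g2", "g3", "g5"}),
            "c": frozenset({"g7", "g8"}),
        }
        results = [
            EnrichmentResult(t, t, len(s), 8, len(s), 50, 0.01 * (i + 1), 0.05, s, True)
            for i, (t, s) in enumerate(sorted(sets.items()))
        ]
        domain = sorted(frozenset().union(*sets.values()))
        kappa = {
            (t1, t2): cohen_kappa_binary(sets[t1], sets[t2], domain)
            for t1 in sets for t2 in sets if t1 < t2
        }
        # brute-force expectation: a-b agree strongly, c is apart
        assert kappa[("a", "b")] >= 0.4
        assert kappa[("a", "c")] < 0.4 and kappa[("b", "c")] < 0.4
        groups = kappa_group_terms(results, kappa_min=0.4)
        membership = {frozenset(g["terms"]) for g in groups}
        assert membership == {frozenset({"a", "b"}), frozenset({"c"})}
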