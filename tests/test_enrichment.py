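"""Contingency tables and the three over-representation tests."""

import math
import warnings
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from overrep.enrichment import (ContingencyTable, build_table, chisq_test,
                                fisher_exact_test, hypergeom_test,
                                run_enrichment)
from overrep.geneset_io import Background, Category, GeneSet, GeneSetCollection


def brute_force_upper_tail(N, n, K, k):
    """Independent oracle: exact rational hypergeometric tail sum."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


class TestBuildTable:
    def test_counts_drop_ids_outside_background(self):
        bg = Background(genes=frozenset(f"g{i}" for i in range(1, 11)))
        s = GeneSet("S", "d", frozenset({"g2", "g3"}))
        table, overlap = build_table({"g1", "g2", "gX"}, s, bg)
        assert (table.N, table.n, table.K, table.k) == (10, 2, 2, 1)
        assert overlap == {"g2"}

    def test_query_equals_set_equals_background(self):
        bg = Background(genes=frozenset({"a", "b", "c"}))
        s = GeneSet("S", "d", bg.genes)
        table, _ = build_table(bg.genes, s, bg)
        assert (table.N, table.n, table.K, table.k) == (3, 3, 3, 3)

    def test_empty_query_background_intersection_raises(self):
        bg = Background(genes=frozenset({"a"}))
        s = GeneSet("S", "d", frozenset({"a"}))
        with pytest.raises(ValueError, match="background"):
            build_table({"zz"}, s, bg)

    def test_k_matches_three_way_intersection_on_fixture(self, planted_run):
        collection, background, query, _ = planted_run
        for s in collection:
            table, overlap = build_table(query, s, background)
            expected = set(query) & s.members & background.genes
            assert table.k == len(expected) and overlap == expected

    @pytest.mark.parametrize("N,n,K,k", [(5, 6, 2, 1), (5, 2, 6, 1),
                                         (10, 2, 2, 3), (10, 5, 5, -1)])
    def test_invalid_tables_rejected(self, N, n, K, k):
        with pytest.raises(ValueError):
            ContingencyTable(N=N, n=n, K=K, k=k)


class TestHypergeom:
    def test_k_zero_covers_whole_support(self):
        assert hypergeom_test(ContingencyTable(N=50, n=10, K=5, k=0)) == 1.0

    def test_perfect_overlap_is_one_over_binomial(self):
        p = hypergeom_test(ContingencyTable(N=10, n=5, K=5, k=5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    @pytest.mark.parametrize("N,n,K", [(20, 7, 9), (30, 15, 10), (12, 4, 4)])
    def test_matches_exact_rational_oracle(self, N, n, K):
        for k in range(max(0, n + K - N), min(n, K) + 1):
            p = hypergeom_test(ContingencyTable(N=N, n=n, K=K, k=k))
            assert p == pytest.approx(brute_force_upper_tail(N, n, K, k), abs=1e-12)

    @given(st.integers(2, 60).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(1, N), st.integers(1, N))))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_k(self, margins):
        N, n, K = margins
        lo, hi = max(0, n + K - N), min(n, K)
        ps = [hypergeom_test(ContingencyTable(N=N, n=n, K=K, k=k))
              for k in range(lo, hi + 1)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)


class TestFisher:
    @pytest.mark.parametrize("N,n,K,k", [(30, 10, 12, 7), (100, 20, 30, 3),
                                         (8, 4, 4, 2)])
    def test_greater_equals_hypergeometric_tail(self, N, n, K, k):
        t = ContingencyTable(N=N, n=n, K=K, k=k)
        assert fisher_exact_test(t, "greater") == hypergeom_test(t)

    def test_balanced_table_two_sided_is_one(self):
        assert fisher_exact_test(ContingencyTable(N=4, n=2, K=2, k=1),
                                 "two_sided") == pytest.approx(1.0)

    @pytest.mark.parametrize("N,n,K", [(12, 5, 6), (20, 9, 7)])
    def test_two_sided_matches_point_probability_enumeration(self, N, n, K):
        for k in range(max(0, n + K - N), min(n, K) + 1):
            obs_pmf = stats.hypergeom.pmf(k, N, K, n)
            expected = sum(
                stats.hypergeom.pmf(i, N, K, n)
                for i in range(max(0, n + K - N), min(n, K) + 1)
                if stats.hypergeom.pmf(i, N, K, n) <= obs_pmf * (1 + 1e-9)
            )
            got = fisher_exact_test(ContingencyTable(N=N, n=n, K=K, k=k), "two_sided")
            assert got == pytest.approx(expected, rel=1e-9)


class TestChisq:
    def test_observed_equals_expected_gives_p_one(self):
        # margins 10/10 over 20, overlap exactly at expectation (k=5)
        t = ContingencyTable(N=20, n=10, K=10, k=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert chisq_test(t, yates=False) == pytest.approx(1.0)

    def test_statistic_matches_hand_formula(self):
        t = ContingencyTable(N=200, n=50, K=40, k=20)
        obs = t.as_2x2().astype(float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        assert chisq_test(t, yates=False) == pytest.approx(
            float(stats.chi2.sf(stat, 1)), rel=1e-12)

    @pytest.mark.parametrize("k", [13, 14])
    def test_one_sided_tail_consistent_with_exact_test(self, k):
        # moderate-tail regime where the large-sample approximation is valid
        t = ContingencyTable(N=1000, n=100, K=100, k=k)
        p_half = chisq_test(t, yates=True) / 2
        assert p_half == pytest.approx(hypergeom_test(t), rel=0.10)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_test(ContingencyTable(N=10, n=0, K=5, k=0))

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected cell"):
            chisq_test(ContingencyTable(N=20, n=4, K=4, k=2))


class TestRunEnrichment:
    def test_query_equal_to_set_attains_minimal_p(self):
        genes = frozenset(f"g{i}" for i in range(100))
        target = frozenset(f"g{i}" for i in range(10))
        coll = GeneSetCollection(sets=[GeneSet("T", "d", target)])
        bg = Background(genes=genes)
        results, _ = run_enrichment(sorted(target), coll, bg)
        (r,) = results
        assert r.table.k == r.table.n == 10
        # k = n is the lower-tail-most table for these margins
        for k in range(10):
            assert r.p_raw < hypergeom_test(ContingencyTable(N=100, n=10, K=10, k=k))

    def test_category_filter_restricts_results(self, planted_run):
        collection, background, query, _ = planted_run
        results, _ = run_enrichment(query, collection, background,
                                    categories=[Category.GO])
        assert results and all(r.category == Category.GO for r in results)

    def test_planted_set_has_smallest_raw_p(self, planted_run):
        collection, background, query, truth = planted_run
        results, _ = run_enrichment(query, collection, background)
        best = min(results, key=lambda r: r.p_raw)
        assert best.set_name in truth["planted_sets"]

    def test_results_ordered_by_category_then_name(self, planted_run):
        collection, background, query, _ = planted_run
        results, _ = run_enrichment(query, collection, background)
        order = {c: i for i, c in enumerate(Category)}
        keys = [(order[r.category], r.set_name) for r in results]
        assert keys == sorted(keys)

    def test_zero_overlap_sets_kept_with_p_one(self):
        bg = Background(genes=frozenset(f"g{i}" for i in range(20)))
        coll = GeneSetCollection(sets=[GeneSet("NO", "d", frozenset({"g18", "g19"}))])
        results, _ = run_enrichment(["g0", "g1"], coll, bg)
        assert results[0].table.k == 0 and results[0].p_raw == 1.0

    def test_audit_tracks_redundancy_and_drops(self):
        bg = Background(genes=frozenset({"a", "b"}))
        coll = GeneSetCollection(sets=[GeneSet("S", "d", frozenset({"a", "b"}))])
        _, audit = run_enrichment(["a", "a", "b", "zz"], coll, bg)
        assert audit.raw_count == 4
        assert audit.nonredundant == ["a", "b", "zz"]
        assert audit.dropped_not_in_background == ["zz"]
        assert audit.redundancy == 1 and audit.in_background_count == 2

    def test_hypergeom_and_fisher_default_agree(self, planted_run):
        collection, background, query, _ = planted_run
        r_f, _ = run_enrichment(query, collection, background, test="fisher")
        r_h, _ = run_enrichment(query, collection, background, test="hypergeom")
        assert [r.p_raw for r in r_f] == pytest.approx(
            [r.p_raw for r in r_h], abs=1e-300)
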