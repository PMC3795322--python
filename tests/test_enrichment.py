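"""Hypergeometric enrichment and FDR correction."""

import math
from io import StringIO

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gocoherence.enrichment import (
    EnrichmentConfig,
    bh_correct,
    by_correct,
    enrich_family,
    fisher_enrichment,
    hypergeom_tail,
    write_enrichment_table,
)
from gocoherence.metrics import term_stats


def tail_sum_oracle(k, n, K, N):
    """Exhaustive hypergeometric upper tail: sum of point masses."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        for i in range(k, min(n, K) + 1)
    )


class TestHypergeomTail:
    def test_hand_computed_tail(self):
        # C(4,3)C(46,2) + C(4,4)C(46,1) over C(50,5)
        expected = (4 * math.comb(46, 2) + 46) / math.comb(50, 5)
        assert expected == 4186 / 2118760
        assert hypergeom_tail(3, 5, 4, 50) == pytest.approx(expected)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 5, 4, 50) == 1.0

    def test_ubiquitous_term_is_one(self):
        assert hypergeom_tail(10, 10, 40, 40) == pytest.approx(1.0)

    def test_family_exclusive_term_closed_form(self):
        # K = n = k: the smallest achievable p is 1 / C(N, n)
        n = k = K = 4
        N = 20
        assert hypergeom_tail(k, n, K, N) == pytest.approx(1 / math.comb(N, n))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_tail_sum(self, data):
        N = data.draw(st.integers(1, 60))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert hypergeom_tail(k, n, K, N) == pytest.approx(
            tail_sum_oracle(k, n, K, N), rel=1e-9, abs=1e-12
        )

    def test_inconsistent_table_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(3, 5, 2, 50)


class TestByCorrection:
    def test_single_test_unchanged(self):
        assert by_correct([0.03]) == [pytest.approx(0.03)]

    def test_hand_evaluated_step_up(self):
        # m=3, c(3)=11/6: raw (0.01, 0.02, 0.9) -> (0.055, 0.055, 1.0)
        adj = by_correct([0.01, 0.02, 0.9])
        assert adj == pytest.approx([0.055, 0.055, 1.0])

    def test_all_ones_stay_one(self):
        assert by_correct([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_correct([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_adjusted_at_least_raw_and_rank_monotone(self, pvals):
        adj = by_correct(pvals)
        for raw, a in zip(pvals, adj):
            assert a >= raw - 1e-12
            assert a <= 1.0 + 1e-12
        ranked = sorted(zip(pvals, adj))
        for (p1, a1), (p2, a2) in zip(ranked, ranked[1:]):
            assert a1 <= a2 + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_bh_never_exceeds_by(self, pvals):
        for bh, by in zip(bh_correct(pvals), by_correct(pvals)):
            assert bh <= by + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.permutations(list(range(6))),
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=6, max_size=6,
        ),
    )
    def test_permutation_invariance(self, perm, pvals):
        adj = by_correct(pvals)
        adj_perm = by_correct([pvals[i] for i in perm])
        for j, i in enumerate(perm):
            assert adj_perm[j] == pytest.approx(adj[i])


class TestEnrichFamily:
    def test_ubiquitous_term_not_significant(self, pl4):
        graph, corpus, family = pl4
        results = {r.term: r for r in enrich_family(family, corpus, graph)}
        # the catalytic-activity analogue is everywhere in the background
        assert not results["GO:0003824"].significant
        assert results["GO:0003824"].p_adj == pytest.approx(1.0, abs=0.2)
        # single-occurrence term lacks support too
        assert not results["GO:0005509"].significant
        # family-concentrated terms are significant
        for term in ("GO:0030246", "GO:0016837", "GO:0016829", "GO:0004180"):
            assert results[term].significant, term

    def test_results_sorted_by_adjusted_p_then_ic(self, pl4):
        graph, corpus, family = pl4
        results = enrich_family(family, corpus, graph)
        keys = [(r.p_adj, -r.ic_norm) for r in results]
        assert keys == sorted(keys)

    def test_fisher_counts_consistent(self, pl22):
        graph, corpus, family = pl22
        k, n, K, N, p = fisher_enrichment(family, corpus, "GO:0047487")
        assert (k, n) == (22, 29)
        assert K == 22  # family-exclusive in this corpus
        assert N == corpus.protein_count
        assert p == pytest.approx(tail_sum_oracle(22, 29, 22, N))

    def test_alpha_boundary_uses_strict_inequality(self, pl3):
        graph, corpus, family = pl3
        first = enrich_family(family, corpus, graph)
        # pick a term with a representable nonzero adjusted p
        target = next(r for r in first if 0 < r.p_adj < 1)
        at_boundary = enrich_family(
            family, corpus, graph, EnrichmentConfig(alpha=target.p_adj)
        )
        boundary_result = next(r for r in at_boundary if r.term == target.term)
        assert not boundary_result.significant

    def test_alpha_one_like_makes_everything_significant(self, pl8):
        graph, corpus, family = pl8
        res = enrich_family(
            family, corpus, graph, EnrichmentConfig(alpha=0.999999)
        )
        assert len(res) == 9  # the nine directly-used terms
        assert all(r.significant for r in res if r.p_adj < 0.999999)

    def test_pl8_table_has_nine_rows_in_order(self, pl8):
        graph, corpus, family = pl8
        res = enrich_family(family, corpus, graph)
        buf = StringIO()
        write_enrichment_table(res, buf, graph)
        lines = buf.getvalue().strip().splitlines()
        assert len(lines) == 10  # header + 9 terms
        assert lines[0].split("\t") == ["GO_term", "p_corr", "IC_norm", "Annotations"]
        padj = [float(ln.split("\t")[1]) for ln in lines[1:]]
        assert padj == sorted(padj)
        # the five leaf descendants are all enriched
        sig = {r.term for r in res if r.significant}
        assert {
            "GO:0030340", "GO:0034000", "GO:0030341", "GO:0034001", "GO:0085030",
        } <= sig
        # the off-lineage metal-binding analogue is not
        assert "GO:0046872" not in sig
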