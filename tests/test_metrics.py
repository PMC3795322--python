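"""Information content, GOscore and GOoccurrence."""

from io import StringIO

import pytest

from gocoherence.corpus import Annotation, AnnotationCorpus, Family, propagate
from gocoherence.fixtures import random_dag_corpus
from gocoherence.metrics import (
    EmptyCorpusError,
    EmptyScopeError,
    go_occurrence,
    go_score,
    restricted_go_occurrence,
    term_stats,
    write_coherence_table,
)

MF = "molecular_function"


def ann(protein, term, direct=True):
    return Annotation(
        protein=protein, term=term, evidence=("IDA",), aspect=MF, direct=direct
    )


class TestTermStats:
    def test_ubiquitous_term_zero_ic(self, pl22):
        graph, corpus, _ = pl22
        stats = term_stats(corpus, graph)
        root = "GO:0003674"
        assert stats[root].corpus_freq == 1.0
        assert stats[root].ic == 0.0
        assert stats[root].ic_norm == 0.0

    def test_quarter_frequency_is_two_bits(self):
        corpus = AnnotationCorpus(
            [ann(f"P{i}", "X:root") for i in range(4)] + [ann("P0", "X:rare")]
        )
        stats = term_stats(corpus, normalize=False)
        assert stats["X:rare"].corpus_freq == 0.25
        assert stats["X:rare"].ic == pytest.approx(2.0)

    def test_rarest_of_eight_is_three_bits_norm_one(self):
        corpus = AnnotationCorpus(
            [ann(f"P{i}", "X:root") for i in range(8)] + [ann("P0", "X:rare")]
        )
        stats = term_stats(corpus)
        assert stats["X:rare"].ic == pytest.approx(3.0)
        assert stats["X:rare"].ic_norm == pytest.approx(1.0)

    def test_empty_corpus_is_error(self):
        with pytest.raises(EmptyCorpusError):
            term_stats(AnnotationCorpus())

    @pytest.mark.parametrize("seed", range(20))
    def test_ic_antitone_along_edges_after_propagation(self, seed):
        graph, corpus = random_dag_corpus(n_terms=25, n_proteins=30, seed=seed)
        prop = propagate(corpus, graph)
        stats = term_stats(prop, graph, normalize=False)
        for t in stats:
            for parent, rel in graph.terms[t].parents:
                if rel == "is_a" and parent in stats:
                    assert stats[t].ic >= stats[parent].ic - 1e-12


class TestGoOccurrence:
    def test_pl22_value(self, pl22):
        graph, corpus, family = pl22
        occ = go_occurrence(family, corpus, graph).go_occurrence
        assert occ == pytest.approx((1 + 22 / 29) / 2)
        assert round(occ, 3) == 0.879

    def test_perfectly_coherent_family(self, pl5):
        graph, corpus, family = pl5
        assert go_occurrence(family, corpus, graph).go_occurrence == 1.0

    def test_mean_of_scoped_frequencies(self, fig1_graph):
        corpus = propagate(
            AnnotationCorpus(
                [ann("P1", "GO:0030247"), ann("P2", "GO:0030246")]
            ),
            fig1_graph,
        )
        fam = Family(name="f", proteins=frozenset({"P1", "P2"}))
        # scope {polysaccharide binding (1/2), carbohydrate binding (2/2)}
        assert go_occurrence(fam, corpus, fig1_graph).go_occurrence == 0.75

    def test_invariant_under_family_duplication(self, fig1_graph):
        # cloning every protein with its full annotation set leaves every
        # scoped frequency, hence the occurrence score, unchanged
        base = [ann("P1", "GO:0030247"), ann("P2", "GO:0030246")]
        clones = [ann("Q1", "GO:0030247"), ann("Q2", "GO:0030246")]
        c1 = propagate(AnnotationCorpus(base), fig1_graph)
        fam1 = Family(name="f", proteins=frozenset({"P1", "P2"}))
        c2 = propagate(AnnotationCorpus(base + clones), fig1_graph)
        fam2 = Family(name="f", proteins=frozenset({"P1", "P2", "Q1", "Q2"}))
        occ1 = go_occurrence(fam1, c1, fig1_graph).go_occurrence
        occ2 = go_occurrence(fam2, c2, fig1_graph).go_occurrence
        assert occ1 == occ2 == pytest.approx(0.75)

    def test_empty_scope_is_error(self, fig1_graph):
        corpus = propagate(
            AnnotationCorpus([ann("P1", "GO:0003674")]), fig1_graph
        )
        fam = Family(name="rooty", proteins=frozenset({"P1"}))
        with pytest.raises(EmptyScopeError):
            go_occurrence(fam, corpus, fig1_graph)


class TestGoScore:
    def test_max_of_products_not_product_of_maxima(self):
        freqs = {"A": 1.0, "B": 0.8}
        ics = {"A": 0.64, "B": 0.9}
        best = max(freqs[t] * ics[t] for t in freqs)
        assert best == pytest.approx(0.72)
        assert max(freqs.values()) * max(ics.values()) != best

    def test_mono_specific_family_score_is_single_term_ic(self, pl5):
        graph, corpus, family = pl5
        report = go_score(family, corpus, graph)
        stats = term_stats(corpus, graph)
        assert report.argmax_term == "GO:0030570"
        assert report.go_score == pytest.approx(stats["GO:0030570"].ic_norm)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        graph, corpus = random_dag_corpus(
            n_terms=20, n_proteins=15, seed=seed
        )
        prop = propagate(corpus, graph)
        fam = Family(name="all", proteins=prop.proteins)
        stats = term_stats(prop, graph)
        report = go_score(fam, prop, graph, stats=stats)
        scope = prop.family_direct_terms(fam, MF, graph)
        freqs = prop.family_frequencies(fam)
        oracle = max(
            freqs[t].freq * stats[t].ic_norm for t in scope if t in freqs
        )
        assert report.go_score == pytest.approx(oracle)

    def test_score_bounded_by_max_ic_norm(self, pl4):
        graph, corpus, family = pl4
        report = go_score(family, corpus, graph)
        stats = term_stats(corpus, graph)
        assert 0 <= report.go_score <= max(
            stats[t].ic_norm for t in report.scope
        )


class TestRestrictedOccurrence:
    def test_restriction_removes_off_focus_terms_and_raises_score(self, pl3):
        graph, corpus, family = pl3
        full = go_occurrence(family, corpus, graph)
        restricted = restricted_go_occurrence(
            family, "GO:0016829", corpus, graph
        )
        assert restricted.scope < full.scope
        assert restricted.scope == {"GO:0030570", "GO:0047490"}
        assert restricted.go_occurrence > full.go_occurrence
        assert restricted.go_occurrence == pytest.approx((1 + 12 / 228) / 2)

    def test_focus_at_root_changes_nothing(self, pl3):
        graph, corpus, family = pl3
        full = go_occurrence(family, corpus, graph)
        at_root = restricted_go_occurrence(
            family, "GO:0003674", corpus, graph
        )
        assert at_root.go_occurrence == pytest.approx(full.go_occurrence)
        assert at_root.scope == full.scope

    def test_all_terms_already_in_lineage_unchanged(self, pl22):
        graph, corpus, family = pl22
        full = go_occurrence(family, corpus, graph)
        focused = restricted_go_occurrence(
            family, "GO:0016829", corpus, graph
        )
        assert focused.scope == full.scope
        assert focused.go_occurrence == full.go_occurrence

    def test_emptying_restriction_is_error(self, pl22):
        graph, corpus, family = pl22
        with pytest.raises(EmptyScopeError, match="GO:0005509"):
            restricted_go_occurrence(family, "GO:0005509", corpus, graph)


def test_report_round_trips_through_table(pl22, pl5):
    graph, corpus, family = pl22
    _, corpus5, family5 = pl5
    buf = StringIO()
    report = go_score(family, corpus, graph)
    write_coherence_table([report], buf)
    lines = buf.getvalue().strip().splitlines()
    assert lines[0].split("\t") == ["Family", "Size", "GOocc", "GOscore", "ArgmaxTerm"]
    fam, size, occ, score, argmax = lines[1].split("\t")
    assert fam == "PL22" and int(size) == 29
    assert float(occ) == round(report.go_occurrence, 3) == 0.879
    assert float(score) == round(report.go_score, 3)
    assert argmax == report.argmax_term
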