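"""Information content and family annotation-coherence metrics.

For a reference corpus with ``N`` proteins, the information content of a
term ``t`` annotating ``n_t`` of them (directly or by true-path
propagation) is

    IC(t) = -log2 f(t),        f(t) = n_t / N

so ubiquitous terms score near 0 bits and rare, specific terms score high.
The normalized IC divides by the maximum IC over all annotated terms, so
the rarest term(s) score exactly 1.

Two family-level summaries are computed over the family's *term scope* —
the distinct directly-asserted terms of its members (aspect roots
excluded), with each term's within-family frequency ``freq_fam`` counted
after propagation:

    GOscore(fam)      = max over scoped terms of freq_fam(term) * IC_norm(term)
    GOoccurrence(fam) = mean over scoped terms of freq_fam(term)

GOscore rewards a predominant *and* informative term; GOoccurrence equals 1
exactly when every scoped term is shared by every annotated protein, and is
penalized by incomplete or heterogeneous annotation. For families of
multifunctional proteins the occurrence metric can mislead; the
descendant-restricted variant recomputes it over only the scoped terms
descending from a chosen focus term, discarding secondary-function terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .corpus import (
    DEFAULT_ASPECT,
    AnnotationCorpus,
    Family,
    FamilyTermFrequency,
    UnannotatedFamilyError,
)
from .ontology import OntologyGraph


class EmptyCorpusError(ValueError):
    """IC is undefined on an empty corpus."""


class EmptyScopeError(ValueError):
    """The family's term scope is empty (no directly-asserted terms)."""


@dataclass(frozen=True)
class TermStats:
    """Corpus frequency and information content of one term."""

    term: str
    corpus_freq: float
    ic: float
    ic_norm: float


@dataclass
class CoherenceReport:
    family: str
    size: int
    go_occurrence: float
    go_score: float | None = None
    argmax_term: str | None = None
    term_frequencies: dict[str, FamilyTermFrequency] = field(default_factory=dict)
    scope: frozenset[str] = frozenset()


def term_stats(
    corpus: AnnotationCorpus,
    graph: OntologyGraph | None = None,
    normalize: bool = True,
) -> dict[str, TermStats]:
    """IC for every term annotating >=1 protein of the (propagated) corpus.

    ``ic_norm`` scales by the maximum IC over all annotated terms, so the
    rarest term(s) get 1.0 and a term annotating everything gets 0.0. With
    ``normalize=False`` raw bits are reported in both fields.
    """
    n = corpus.protein_count
    if n == 0:
        raise EmptyCorpusError("IC undefined on empty corpus")
    counts: dict[str, int] = {}
    for ann in corpus.annotations:
        counts[ann.term] = counts.get(ann.term, 0) + 1
    ics = {t: -math.log2(c / n) for t, c in counts.items()}
    max_ic = max(ics.values()) if ics else 0.0
    out = {}
    for t, ic in ics.items():
        norm = ic / max_ic if (normalize and max_ic > 0) else ic
        out[t] = TermStats(term=t, corpus_freq=counts[t] / n, ic=ic, ic_norm=norm)
    return out


def _scoped_frequencies(
    family: Family,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str,
    scope: Iterable[str] | None = None,
) -> tuple[dict[str, FamilyTermFrequency], set[str], int]:
    freqs = corpus.family_frequencies(family, aspect)
    if scope is None:
        scope = corpus.family_direct_terms(family, aspect, graph)
        scope = {graph.resolve(t) for t in scope if t in graph}
    else:
        scope = set(scope)
    scope &= set(freqs)
    if not scope:
        raise EmptyScopeError(
            f"family {family.name!r} has an empty term scope in aspect {aspect!r}"
        )
    size = family.annotated_size(corpus, aspect)
    return freqs, scope, size


def go_occurrence(
    family: Family,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str = DEFAULT_ASPECT,
    scope: Iterable[str] | None = None,
) -> CoherenceReport:
    """Mean within-family frequency over the family's scoped terms.

    Equals 1 iff every scoped term annotates every annotated family protein.
    ``scope`` overrides the default direct-term scope (used by the
    descendant-restricted variant).
    """
    freqs, scope, size = _scoped_frequencies(family, corpus, graph, aspect, scope)
    occ = sum(freqs[t].freq for t in scope) / len(scope)
    return CoherenceReport(
        family=family.name,
        size=size,
        go_occurrence=occ,
        term_frequencies={t: freqs[t] for t in scope},
        scope=frozenset(scope),
    )


def go_score(
    family: Family,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str = DEFAULT_ASPECT,
    stats: Mapping[str, TermStats] | None = None,
    reference: AnnotationCorpus | None = None,
) -> CoherenceReport:
    """Max over scoped terms of within-family frequency x normalized IC.

    IC comes from ``stats`` if given, else from ``reference`` (defaulting to
    the analysis corpus itself). Ties break toward higher IC, then
    lexicographically smaller term id.
    """
    if stats is None:
        stats = term_stats(reference if reference is not None else corpus, graph)
    freqs, scope, size = _scoped_frequencies(family, corpus, graph, aspect)
    best_term, best = None, -1.0
    for t in sorted(scope):
        ic = stats[t].ic_norm if t in stats else 0.0
        val = freqs[t].freq * ic
        better = val > best or (
            val == best
            and best_term is not None
            and ic > (stats[best_term].ic_norm if best_term in stats else 0.0)
        )
        if better:
            best_term, best = t, val
    report = go_occurrence(family, corpus, graph, aspect)
    report.go_score = best
    report.argmax_term = best_term
    return report


def restricted_go_occurrence(
    family: Family,
    focus: str,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str = DEFAULT_ASPECT,
) -> CoherenceReport:
    """GOoccurrence over only the scoped terms in descendants(focus) + focus.

    Discards scoped terms off the focus lineage — the remedy for secondary
    functional modules depressing the unrestricted score.
    """
    focus = graph.resolve(focus)
    full_scope = corpus.family_direct_terms(family, aspect, graph)
    full_scope = {graph.resolve(t) for t in full_scope if t in graph}
    lineage = graph.descendants(focus) | {focus}
    restricted = full_scope & lineage
    if not restricted:
        raise EmptyScopeError(
            f"restriction to focus term {focus} empties the scope of family "
            f"{family.name!r}"
        )
    return go_occurrence(family, corpus, graph, aspect, scope=restricted)


def coherence_table(
    families: Iterable[Family],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str = DEFAULT_ASPECT,
    stats: Mapping[str, TermStats] | None = None,
) -> list[CoherenceReport]:
    if stats is None:
        stats = term_stats(corpus, graph)
    return [
        go_score(f, corpus, graph, aspect, stats=stats)
        for f in sorted(families, key=lambda f: f.name)
    ]


def write_coherence_table(reports: Iterable[CoherenceReport], stream: TextIO) -> None:
    """Tab-separated report: Family, Size, GOocc, GOscore, ArgmaxTerm.
    Scores rounded to 3 decimal places."""
    stream.write("Family\tSize\tGOocc\tGOscore\tArgmaxTerm\n")
    for r in reports:
        score = "" if r.go_score is None else f"{r.go_score:.3f}"
        stream.write(
            f"{r.family}\t{r.size}\t{r.go_occurrence:.3f}\t{score}\t"
            f"{r.argmax_term or ''}\n"
        )
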