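"""Semi-automatic annotation-extension pipeline.

Families curated as functionally related (e.g. enzyme families) often carry
incomplete annotation: some members hold a specific term while others stop
at a generic ancestor. The pipeline identifies, per family:

1. *relevant terms* — terms significantly enriched in the family against a
   background corpus, optionally intersected with manually curated
   allow/deny rules and restricted to a focus lineage;
2. the family's annotation coherence (GOoccurrence) under those terms;
3. per relevant term, the *support set* — proteins already carrying the
   term, exportable as a training corpus for an external per-term
   classifier (alignments, PSSMs, HMMs, SVMs — built outside this package);
4. the *candidate set* — annotated family proteins not carrying the term,
   which the classifier could extend;
5. the coherence differential: GOoccurrence before vs. after hypothetically
   extending the term to every candidate.

Proposals are emitted, never silently applied: the methodology is
semi-automatic and the decision to assert a term on a candidate belongs to
a classifier or curator. An explicit :func:`apply_proposal` step exists for
simulation and writes provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Mapping

from .corpus import (
    DEFAULT_ASPECT,
    Annotation,
    AnnotationCorpus,
    Family,
)
from .enrichment import EnrichmentConfig, enrich_family
from .metrics import TermStats, go_occurrence
from .ontology import OntologyGraph


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the extension pipeline.

    ``min_support`` is the smallest support set deemed able to seed a
    per-term classifier; terms below it are reported but flagged. ``focus``
    restricts relevant terms to descendants(focus) + focus. ``allow`` /
    ``deny`` are the manually created rule lists. ``within``, when set to
    an ancestor term, restricts candidates to proteins already carrying
    that term (the pool refined toward the proposal's term).
    """

    alpha: float = 0.01
    correction: str = "BY"
    min_support: int = 10
    focus: str | None = None
    within: str | None = None
    allow: frozenset[str] | None = None
    deny: frozenset[str] = frozenset()
    aspect: str = DEFAULT_ASPECT

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")

    def snapshot(self) -> dict:
        return {
            "alpha": self.alpha,
            "correction": self.correction,
            "min_support": self.min_support,
            "focus": self.focus,
            "within": self.within,
            "allow": sorted(self.allow) if self.allow is not None else None,
            "deny": sorted(self.deny),
            "aspect": self.aspect,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class ExtensionProposal:
    family: str
    term: str
    support: frozenset[str]
    candidates: frozenset[str]
    min_support_met: bool
    coherence_before: float
    coherence_after: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    def to_json_record(self) -> dict:
        return {
            "family": self.family,
            "term": self.term,
            "support": sorted(self.support),
            "candidates": sorted(self.candidates),
            "min_support_met": self.min_support_met,
            "coherence_before": round(self.coherence_before, 6),
            "coherence_after": round(self.coherence_after, 6),
            "provenance": dict(self.provenance),
        }


def select_relevant_terms(
    family: Family,
    background: AnnotationCorpus,
    graph: OntologyGraph,
    config: PipelineConfig = PipelineConfig(),
    stats: Mapping[str, TermStats] | None = None,
) -> set[str]:
    """Terms characteristic of the family: significantly enriched at
    ``config.alpha``, filtered by allow/deny rules and, when a focus is
    set, kept inside descendants(focus) + focus. An empty result is
    returned as-is (not an error)."""
    results = enrich_family(
        family,
        background,
        graph,
        EnrichmentConfig(alpha=config.alpha, correction=config.correction),
        aspect=config.aspect,
        stats=stats,
    )
    relevant = {r.term for r in results if r.significant}
    if config.allow is not None:
        relevant &= {graph.resolve(t) for t in config.allow}
    relevant -= {graph.resolve(t) for t in config.deny if t in graph}
    if config.focus is not None:
        focus = graph.resolve(config.focus)
        relevant &= graph.descendants(focus) | {focus}
    return relevant


def extension_candidates(
    family: Family,
    term: str,
    corpus: AnnotationCorpus,
    aspect: str = DEFAULT_ASPECT,
    within: str | None = None,
) -> frozenset[str]:
    """Annotated family proteins lacking ``term`` (direct or propagated).

    ``within`` restricts the pool to proteins already carrying an ancestor
    term — the proteins one refinement step away from the proposal.
    Disjoint from the term's support set by construction.
    """
    pool = set(family.annotated_proteins(corpus, aspect))
    if within is not None:
        pool &= corpus.proteins_with(within)
    return frozenset(pool - corpus.proteins_with(term))


def coherence_differential(
    family: Family,
    term: str,
    candidates: Iterable[str],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str = DEFAULT_ASPECT,
) -> tuple[float, float]:
    """GOoccurrence before and after hypothetically asserting ``term`` on
    every candidate. The extension is evaluated on a corpus copy; the input
    corpus is untouched. after >= before always."""
    before = go_occurrence(family, corpus, graph, aspect).go_occurrence
    extended = apply_extension(corpus, graph, term, candidates, aspect)
    after = go_occurrence(family, extended, graph, aspect).go_occurrence
    return before, after


def apply_extension(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    term: str,
    candidates: Iterable[str],
    aspect: str = DEFAULT_ASPECT,
    evidence: str = "IEA-EXT",
) -> AnnotationCorpus:
    """Corpus copy with ``term`` asserted (and propagated) on each
    candidate, under a distinguishing evidence note."""
    tid = graph.resolve(term)
    extra = [
        Annotation(protein=p, term=tid, evidence=(evidence,), aspect=aspect)
        for p in candidates
    ]
    out = AnnotationCorpus(corpus.annotations, propagated=corpus.propagated)
    for ann in extra:
        out._add(ann)
        for anc in graph.ancestors(tid):
            out._add(
                Annotation(
                    protein=ann.protein,
                    term=anc,
                    evidence=(evidence,),
                    aspect=graph.terms[anc].aspect or aspect,
                    direct=False,
                )
            )
    return out


def propose_extensions(
    family: Family,
    background: AnnotationCorpus,
    graph: OntologyGraph,
    config: PipelineConfig = PipelineConfig(),
    stats: Mapping[str, TermStats] | None = None,
) -> list[ExtensionProposal]:
    """One proposal per relevant term with a non-empty candidate set and
    support size >= ``config.min_support``, sorted by support size
    descending (ties by term id).

    When a focus term is set it defines the functional context being
    refined and is itself never proposed as an extension target; its
    descendants are. Terms already carried by every annotated protein
    yield no proposal (nothing to extend).
    """
    relevant = select_relevant_terms(family, background, graph, config, stats=stats)
    if config.focus is not None:
        relevant -= {graph.resolve(config.focus)}
    annotated = family.annotated_proteins(background, config.aspect)
    proposals = []
    for term in sorted(relevant):
        support = frozenset(background.proteins_with(term) & annotated)
        candidates = extension_candidates(
            family, term, background, config.aspect, within=config.within
        )
        if not candidates:
            continue
        met = len(support) >= config.min_support
        if not met:
            continue
        before, after = coherence_differential(
            family, term, candidates, background, graph, config.aspect
        )
        proposals.append(
            ExtensionProposal(
                family=family.name,
                term=term,
                support=support,
                candidates=candidates,
                min_support_met=met,
                coherence_before=before,
                coherence_after=after,
                provenance={"config": config.snapshot(), "config_hash": config.digest()},
            )
        )
    proposals.sort(key=lambda p: (-len(p.support), p.term))
    return proposals


def export_support_accessions(proposal: ExtensionProposal) -> str:
    """Accession list (one per line) of the support set, for external
    sequence retrieval and classifier construction."""
    return "\n".join(sorted(proposal.support)) + "\n"
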