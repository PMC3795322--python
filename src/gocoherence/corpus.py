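"""GAF annotation corpora, family tables, and true-path propagation.

A corpus is a set of protein–term associations with evidence codes, read
from GAF 2.1/2.2 tab-separated files. Propagation applies the true path
rule: every protein's term set is closed under the ontology's ancestor
relation, with propagated annotations marked non-direct so that reports and
flow graphs can distinguish asserted from inherited annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, TextIO

from .ontology import DEFAULT_RELATIONS, OntologyGraph, UnknownTermError

logger = logging.getLogger(__name__)

ASPECT_CODES = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}
ASPECT_LETTERS = {v: k for k, v in ASPECT_CODES.items()}

#: Default analysis aspect; enzymatic-function analyses operate here.
DEFAULT_ASPECT = "molecular_function"


class GafParseError(ValueError):
    """A GAF row could not be parsed; message carries the line number."""


class UnannotatedFamilyError(ValueError):
    """A family has no protein with a direct annotation in the chosen aspect."""


@dataclass(frozen=True)
class Annotation:
    """One protein–term association.

    ``direct`` distinguishes asserted rows from true-path-propagated ones;
    propagated annotations inherit the evidence codes of the direct
    annotation(s) they derive from.
    """

    protein: str
    term: str
    evidence: tuple[str, ...]
    aspect: str
    direct: bool = True


@dataclass(frozen=True)
class Family:
    """A named protein set evaluated against a corpus.

    Reported family *size* counts only proteins with at least one direct
    annotation in the analysis aspect; unannotated members are retained for
    reporting but excluded from frequency denominators.
    """

    name: str
    proteins: frozenset[str]

    def annotated_proteins(self, corpus: "AnnotationCorpus", aspect: str = DEFAULT_ASPECT) -> frozenset[str]:
        return frozenset(
            p for p in self.proteins if corpus.direct_terms_of(p, aspect)
        )

    def annotated_size(self, corpus: "AnnotationCorpus", aspect: str = DEFAULT_ASPECT) -> int:
        return len(self.annotated_proteins(corpus, aspect))


@dataclass(frozen=True)
class FamilyTermFrequency:
    """Within-family annotation frequency of one term: ``count`` proteins of
    the family carry the term (direct or propagated) out of the family's
    annotated-protein count."""

    term: str
    count: int
    freq: float


class AnnotationCorpus:
    """Protein–term association set, indexable in both directions."""

    def __init__(self, annotations: Iterable[Annotation] = (), propagated: bool = False):
        # protein -> {term -> Annotation}; duplicates collapsed in _add
        self._by_protein: dict[str, dict[str, Annotation]] = {}
        # term -> protein set (inverse index, kept consistent by _add)
        self._by_term: dict[str, set[str]] = {}
        self.propagated = propagated
        for ann in annotations:
            self._add(ann)

    def _add(self, ann: Annotation) -> None:
        terms = self._by_protein.setdefault(ann.protein, {})
        prev = terms.get(ann.term)
        if prev is not None:
            codes = tuple(dict.fromkeys(prev.evidence + ann.evidence))
            ann = replace(prev, evidence=codes, direct=prev.direct or ann.direct)
        terms[ann.term] = ann
        self._by_term.setdefault(ann.term, set()).add(ann.protein)

    # -- indexes ---------------------------------------------------------
    @property
    def annotations(self) -> list[Annotation]:
        return [a for terms in self._by_protein.values() for a in terms.values()]

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._by_protein)

    @property
    def protein_count(self) -> int:
        """Distinct proteins — the denominator for corpus frequencies."""
        return len(self._by_protein)

    def terms_of(self, protein: str, aspect: str | None = None) -> set[str]:
        anns = self._by_protein.get(protein, {})
        return {
            t for t, a in anns.items() if aspect is None or a.aspect == aspect
        }

    def direct_terms_of(self, protein: str, aspect: str | None = None) -> set[str]:
        anns = self._by_protein.get(protein, {})
        return {
            t
            for t, a in anns.items()
            if a.direct and (aspect is None or a.aspect == aspect)
        }

    def proteins_with(self, term: str) -> set[str]:
        return set(self._by_term.get(term, set()))

    def annotation(self, protein: str, term: str) -> Annotation | None:
        return self._by_protein.get(protein, {}).get(term)

    def __len__(self) -> int:
        return sum(len(t) for t in self._by_protein.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        protein, term = key
        return term in self._by_protein.get(protein, {})

    # -- construction-time filters --------------------------------------
    def filter_evidence(
        self,
        include: Iterable[str] | None = None,
        exclude: Iterable[str] | None = None,
    ) -> "AnnotationCorpus":
        """Corpus restricted by evidence code (applied to direct rows).

        Default keeps every code; pass e.g. ``exclude={"IEA"}`` to drop
        electronically inferred annotations.
        """
        include = set(include) if include is not None else None
        exclude = set(exclude) if exclude is not None else set()
        kept = []
        for ann in self.annotations:
            codes = set(ann.evidence)
            if include is not None and not (codes & include):
                continue
            if codes and codes <= exclude:
                continue
            kept.append(ann)
        return AnnotationCorpus(kept, propagated=self.propagated)

    # -- frequency model -------------------------------------------------
    def family_frequencies(
        self, family: Family, aspect: str = DEFAULT_ASPECT
    ) -> dict[str, FamilyTermFrequency]:
        """Per-term within-family frequencies over propagated annotations.

        One entry per term annotating at least one family protein in the
        aspect; the denominator is the family's annotated-protein count.
        """
        annotated = family.annotated_proteins(self, aspect)
        if not annotated:
            raise UnannotatedFamilyError(
                f"family {family.name!r} has no annotated protein in aspect {aspect!r}"
            )
        n = len(annotated)
        counts: dict[str, int] = {}
        for p in annotated:
            for t, a in self._by_protein[p].items():
                if a.aspect == aspect:
                    counts[t] = counts.get(t, 0) + 1
        return {
            t: FamilyTermFrequency(term=t, count=c, freq=c / n)
            for t, c in counts.items()
        }

    def family_direct_terms(
        self,
        family: Family,
        aspect: str = DEFAULT_ASPECT,
        graph: OntologyGraph | None = None,
    ) -> set[str]:
        """Distinct directly-asserted terms of family members in the aspect,
        excluding aspect roots when a graph is supplied. This is the term
        scope over which the coherence metrics aggregate."""
        terms: set[str] = set()
        for p in family.proteins:
            terms |= self.direct_terms_of(p, aspect)
        if graph is not None:
            terms -= set(graph.roots().values())
        return terms


def propagate(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> AnnotationCorpus:
    """True-path propagation: close every protein's term set under
    :meth:`OntologyGraph.ancestors`.

    Direct flags are preserved; each propagated annotation inherits the
    union of evidence codes of the direct annotations implying it.
    Annotations to terms absent from the graph (after alt_id resolution) or
    obsolete are dropped with a warning. Idempotent.
    """
    out = AnnotationCorpus(propagated=True)
    anc_cache: dict[str, set[str]] = {}
    for ann in corpus.annotations:
        if not ann.direct:
            continue  # re-derive propagated rows from direct ones
        try:
            tid = graph.resolve(ann.term)
            if graph.terms[tid].obsolete:
                raise UnknownTermError(tid)
            if tid not in anc_cache:
                anc_cache[tid] = graph.ancestors(tid, relations)
            ancestors = anc_cache[tid]
        except UnknownTermError:
            logger.warning(
                "dropping annotation %s -> %s: term unknown or obsolete",
                ann.protein,
                ann.term,
            )
            continue
        aspect = graph.terms[tid].aspect or ann.aspect
        out._add(replace(ann, term=tid, aspect=aspect))
        for anc in ancestors:
            out._add(
                Annotation(
                    protein=ann.protein,
                    term=anc,
                    evidence=ann.evidence,
                    aspect=graph.terms[anc].aspect or aspect,
                    direct=False,
                )
            )
    return out


# -- GAF input/output -----------------------------------------------------

_GAF_MIN_COLUMNS = 15


def parse_gaf(source) -> AnnotationCorpus:
    """Read a GAF 2.1/2.2 stream or path into an (unpropagated) corpus.

    Consumes columns 2 (accession), 4 (qualifier; rows carrying NOT are
    excluded), 5 (term), 7 (evidence) and 9 (aspect letter). Duplicate
    (protein, term) rows collapse into one annotation retaining all
    evidence codes. An empty file yields an empty corpus.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    corpus = AnnotationCorpus()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _GAF_MIN_COLUMNS:
            raise GafParseError(
                f"line {lineno}: expected >={_GAF_MIN_COLUMNS} tab-separated "
                f"columns, got {len(cols)}"
            )
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            continue
        corpus._add(
            Annotation(
                protein=cols[1],
                term=cols[4],
                evidence=(cols[6],) if cols[6] else (),
                aspect=ASPECT_CODES.get(cols[8], cols[8]),
            )
        )
    return corpus


def write_gaf(corpus: AnnotationCorpus, stream: TextIO, db: str = "SYN") -> None:
    """Write the direct annotations of a corpus as GAF 2.2 rows."""
    stream.write("!gaf-version: 2.2\n")
    rows = sorted(
        (a for a in corpus.annotations if a.direct),
        key=lambda a: (a.protein, a.term),
    )
    for a in rows:
        aspect = ASPECT_LETTERS.get(a.aspect, a.aspect)
        cols = [
            db, a.protein, a.protein, "enables", a.term, "REF:0000001",
            a.evidence[0] if a.evidence else "ND", "", aspect, "", "",
            "protein", "taxon:0", "20200101", db, "", "",
        ]
        stream.write("\t".join(cols) + "\n")


# -- family tables --------------------------------------------------------

def parse_family_table(source) -> dict[str, Family]:
    """Read a two-column tab-separated (family_id, protein_accession) table;
    '#'-prefixed comment lines allowed."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    members: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise GafParseError(
                f"line {lineno}: family table rows need exactly 2 columns"
            )
        members.setdefault(cols[0], set()).add(cols[1])
    return {
        name: Family(name=name, proteins=frozenset(prots))
        for name, prots in members.items()
    }


def write_family_table(families: Mapping[str, Family], stream: TextIO) -> None:
    for name in sorted(families):
        for protein in sorted(families[name].proteins):
            stream.write(f"{name}\t{protein}\n")
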