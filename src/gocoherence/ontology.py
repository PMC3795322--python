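"""Ontology parsing and DAG traversal.

An ontology such as the Gene Ontology is a rooted directed acyclic graph of
terms connected by typed relations (``is_a``, ``part_of``, ``regulates``),
split into orthogonal aspects (for GO: molecular function, biological
process, cellular component). Annotation obeys the *true path rule*: a
protein annotated to a term is implicitly annotated to every ancestor of
that term, because the path from a child up to its top-level parents must
always hold.

This module parses OBO flat files into an :class:`OntologyGraph` and
provides ancestor/descendant traversal over a configurable relation set.
``regulates`` edges are parsed and stored but never traversed by default:
they may cross aspects, and the within-aspect frequency model used by the
coherence metrics requires traversal to stay inside one aspect.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations traversed by default. ``part_of`` may be added by callers;
#: ``regulates`` is stored but deliberately never traversed by default.
DEFAULT_RELATIONS: frozenset[str] = frozenset({"is_a"})

REGULATES_RELATIONS = {"regulates", "positively_regulates", "negatively_regulates"}


class OntologyError(Exception):
    """Base class for ontology structural or parse errors."""


class OboParseError(OntologyError):
    """A [Term] stanza could not be parsed (e.g. missing ``id:`` tag)."""


class CycleError(OntologyError):
    """The parsed relation graph is not acyclic."""

    def __init__(self, cycle: Sequence[tuple[str, str]]):
        self.cycle = list(cycle)
        path = " -> ".join(e[0] for e in self.cycle) + " -> " + self.cycle[-1][1]
        super().__init__(f"cycle detected in ontology: {path}")


class UnknownTermError(OntologyError, KeyError):
    """A term id is absent from the graph even after alt_id resolution."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    ``parents`` lists ``(parent_id, relation)`` pairs for every stored
    relation, including ones excluded from default traversal.
    """

    id: str
    name: str = ""
    aspect: str = ""
    parents: tuple[tuple[str, str], ...] = ()
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """A rooted DAG of terms with typed parent relations.

    Parameters
    ----------
    terms
        Mapping of primary term id to :class:`Term`.
    alt_ids
        Mapping of secondary (alt) id to primary id.
    """

    terms: dict[str, Term]
    alt_ids: dict[str, str] = field(default_factory=dict)
    _traversal_cache: dict[frozenset, nx.DiGraph] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Resolve a possibly-secondary id to its primary id.

        Raises :class:`UnknownTermError` if the id is unknown under either
        mapping.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            primary = self.alt_ids[term_id]
            logger.info("resolved alt_id %s -> %s", term_id, primary)
            return primary
        raise UnknownTermError(f"unknown term id: {term_id!r}")

    def term(self, term_id: str) -> Term:
        return self.terms[self.resolve(term_id)]

    def name(self, term_id: str) -> str:
        return self.term(term_id).name

    @property
    def aspects(self) -> set[str]:
        return {t.aspect for t in self.terms.values() if not t.obsolete}

    def roots(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> dict[str, str]:
        """One root per aspect: the term with no outgoing parent edges."""
        g = self._graph(relations)
        out: dict[str, str] = {}
        for tid in g.nodes:
            if g.out_degree(tid) == 0:
                out[self.terms[tid].aspect] = tid
        return out

    def _graph(self, relations: Iterable[str]) -> nx.DiGraph:
        """Child->parent DiGraph restricted to non-obsolete terms and the
        requested relation set. Cached per relation set."""
        key = frozenset(relations)
        if key not in self._traversal_cache:
            g = nx.DiGraph()
            for tid, term in self.terms.items():
                if term.obsolete:
                    continue
                g.add_node(tid)
                for parent, rel in term.parents:
                    if rel in key and parent in self.terms and not self.terms[parent].obsolete:
                        g.add_edge(tid, parent)
            self._traversal_cache[key] = g
        return self._traversal_cache[key]

    def ancestors(
        self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> set[str]:
        """All terms reachable upward from ``term_id`` via ``relations``.

        Excludes the query term itself. The result is transitively closed:
        every ancestor's ancestors are included. This is the term set implied
        by the true path rule for an annotation to ``term_id``.
        """
        tid = self.resolve(term_id)
        if self.terms[tid].obsolete:
            raise UnknownTermError(f"term {tid} is obsolete")
        # edges run child->parent, so graph-descendants are ontology-ancestors
        return nx.descendants(self._graph(relations), tid)

    def descendants(
        self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> set[str]:
        """All terms from which ``term_id`` is reachable (mirror of
        :meth:`ancestors`)."""
        tid = self.resolve(term_id)
        if self.terms[tid].obsolete:
            raise UnknownTermError(f"term {tid} is obsolete")
        return nx.ancestors(self._graph(relations), tid)

    def to_graphml(self) -> str:
        """GraphML export of the full stored graph for external inspection."""
        g = nx.DiGraph()
        for tid, term in self.terms.items():
            g.add_node(tid, name=term.name, aspect=term.aspect, obsolete=term.obsolete)
        for tid, term in self.terms.items():
            for parent, rel in term.parents:
                if parent in self.terms:
                    g.add_edge(tid, parent, relation=rel)
        return "\n".join(nx.generate_graphml(g))


_RELATIONSHIP_RE = re.compile(r"^(\S+)\s+(\S+)")


def _check_stanzas(text: str) -> None:
    """Pre-scan [Term] stanzas for a missing ``id:`` tag, which obonet does
    not report with a useful location."""
    for i, stanza in enumerate(re.split(r"^\[Term\]\s*$", text, flags=re.M)[1:], 1):
        body = stanza.split("\n[", 1)[0]
        if not re.search(r"^id:\s*\S", body, flags=re.M):
            head = next((ln for ln in body.splitlines() if ln.strip()), "<empty>")
            raise OboParseError(
                f"[Term] stanza #{i} has no id tag (starts: {head.strip()!r})"
            )


def parse_obo(
    source, relations_to_load: Iterable[str] | None = None
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 stream or path into an :class:`OntologyGraph`.

    Parameters
    ----------
    source
        File path or text stream containing OBO.
    relations_to_load
        Relation types to store from ``relationship:`` tags, in addition to
        ``is_a`` which is always stored. Default: ``part_of`` and the
        ``regulates`` family (all stored; traversal still defaults to
        ``is_a`` only).

    Raises
    ------
    OboParseError
        On a [Term] stanza with no id.
    CycleError
        If the loaded relation graph contains a cycle (one cycle listed).
    """
    if relations_to_load is None:
        relations_to_load = {"part_of"} | REGULATES_RELATIONS
    relations_to_load = set(relations_to_load) | {"is_a"}

    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    _check_stanzas(text)

    multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    for tid, data in multigraph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        parents: list[tuple[str, str]] = []
        if not obsolete:
            for parent in data.get("is_a", []):
                parents.append((parent, "is_a"))
            for entry in data.get("relationship", []):
                m = _RELATIONSHIP_RE.match(entry)
                if m and m.group(1) in relations_to_load:
                    parents.append((m.group(2), m.group(1)))
        term = Term(
            id=tid,
            name=data.get("name", ""),
            aspect=data.get("namespace", ""),
            parents=tuple(parents),
            obsolete=obsolete,
            alt_ids=tuple(data.get("alt_id", [])),
        )
        terms[tid] = term
        for alt in term.alt_ids:
            alt_ids[alt] = tid

    graph = OntologyGraph(terms=terms, alt_ids=alt_ids)

    full = nx.DiGraph()
    full.add_nodes_from(terms)
    for tid, term in terms.items():
        for parent, _rel in term.parents:
            if parent in terms:
                full.add_edge(tid, parent)
    if not nx.is_directed_acyclic_graph(full):
        raise CycleError(nx.find_cycle(full))
    return graph
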