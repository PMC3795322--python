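"""Annotation flow graphs for protein families.

The flow graph renders a family's annotation structure: nodes are the
ontology terms annotating at least one family protein (after true-path
propagation), restricted to one aspect; edges run from generic parent to
specific child — the reverse of the ontology's child-to-parent edges — and
carry the number of family proteins "flowing down" into the child, i.e.
receiving the child's more specific annotation. Directly asserted terms
render as gray, name-labelled nodes; purely inherited terms as unlabelled
white nodes; the aspect root is drawn unlabelled. Edge thickness is
proportional to flow, giving visual cues about annotation specificity and
homogeneity within the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .corpus import DEFAULT_ASPECT, AnnotationCorpus, Family, UnannotatedFamilyError
from .ontology import DEFAULT_RELATIONS, OntologyGraph


@dataclass(frozen=True)
class FlowNode:
    term: str
    label: str
    direct: bool
    protein_count: int


@dataclass(frozen=True)
class FlowEdge:
    parent: str
    child: str
    weight: int


@dataclass
class FlowGraph:
    family: str
    nodes: dict[str, FlowNode] = field(default_factory=dict)
    edges: list[FlowEdge] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(family=self.family)
        for n in self.nodes.values():
            g.add_node(
                n.term, label=n.label, direct=n.direct, protein_count=n.protein_count
            )
        for e in self.edges:
            g.add_edge(e.parent, e.child, weight=e.weight)
        return g


def build_flow_graph(
    family: Family,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    aspect: str = DEFAULT_ASPECT,
    relations=DEFAULT_RELATIONS,
    reduce_transitive: bool = True,
) -> FlowGraph:
    """Flow graph of a family's propagated annotations in one aspect.

    Included terms are those carried by >=1 annotated family protein.
    Ontology edges between included terms are reoriented parent->child;
    with ``reduce_transitive`` (default) an edge is dropped when a longer
    included path connects the same pair, matching a compact rendering.
    Each drawn edge to a child carries the child's protein count (flow is
    not split across multiple parents).
    """
    annotated = family.annotated_proteins(corpus, aspect)
    if not annotated:
        raise UnannotatedFamilyError(
            f"family {family.name!r} has no annotated protein in aspect {aspect!r}"
        )
    counts: dict[str, int] = {}
    direct_terms: set[str] = set()
    for p in annotated:
        for t in corpus.terms_of(p, aspect):
            counts[t] = counts.get(t, 0) + 1
        direct_terms |= corpus.direct_terms_of(p, aspect)
    included = set(counts)

    # parent -> child over included terms only
    g = nx.DiGraph()
    g.add_nodes_from(included)
    for child in included:
        for parent, rel in graph.terms[graph.resolve(child)].parents:
            if rel in set(relations) and parent in included:
                g.add_edge(parent, child)
    if reduce_transitive and g.number_of_edges():
        g = nx.transitive_reduction(g)

    flow = FlowGraph(family=family.name)
    for t in included:
        flow.nodes[t] = FlowNode(
            term=t,
            label=graph.name(t),
            direct=t in direct_terms,
            protein_count=counts[t],
        )
    for parent, child in sorted(g.edges):
        flow.edges.append(FlowEdge(parent=parent, child=child, weight=counts[child]))
    return flow


def export_dot(flow: FlowGraph, style: Mapping[str, str] | None = None) -> str:
    """Serialize a flow graph as a DOT digraph.

    Direct nodes: gray fill, term-name label. Inherited nodes: white,
    unlabelled. Edge penwidth scales linearly with weight (minimum 1).
    """
    style = dict(style or {})
    max_penwidth = float(style.get("max_penwidth", 8.0))
    max_w = max((e.weight for e in flow.edges), default=1)
    lines = [f'digraph "{flow.family}" {{', "  rankdir=TB;"]
    for term in sorted(flow.nodes):
        n = flow.nodes[term]
        if n.direct:
            attrs = f'label="{n.label}", style=filled, fillcolor=gray'
        else:
            attrs = 'label="", style=filled, fillcolor=white'
        lines.append(f'  "{n.term}" [{attrs}];')
    for e in flow.edges:
        penwidth = max(1.0, max_penwidth * e.weight / max_w)
        lines.append(
            f'  "{e.parent}" -> "{e.child}" [penwidth={penwidth:.3f}, '
            f'label="{e.weight}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graphml(flow: FlowGraph) -> str:
    return "\n".join(nx.generate_graphml(flow.to_networkx()))


def export_json(flow: FlowGraph) -> dict:
    """Node/edge dump for interactive front-ends."""
    return {
        "family": flow.family,
        "nodes": [
            {
                "term": n.term,
                "label": n.label,
                "direct": n.direct,
                "protein_count": n.protein_count,
            }
            for n in flow.nodes.values()
        ],
        "edges": [
            {"parent": e.parent, "child": e.child, "weight": e.weight}
            for e in flow.edges
        ],
    }
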