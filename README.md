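# gocoherence

Annotation-coherence metrics and semi-automatic annotation extension for
protein families annotated with DAG-structured ontologies such as the Gene
Ontology (GO).

## The problem

Curated protein families (enzyme families in particular) are expected to be
functionally homogeneous, yet their GO annotation rarely is: some members
carry a specific term while others stop at a generic ancestor, and secondary
functions annotate only a few members. Incomplete or heterogeneous
annotation can make a coherent family look incoherent — or worse, make an
incoherent set look fine when comparisons are made only at generic levels.
`gocoherence` quantifies this, visualizes it, and turns the well-annotated
part of a family into concrete proposals for extending annotation to its
under-annotated members.

## The metrics

All annotation is first closed under the **true path rule**: an annotation
to a term implies annotation to every ancestor reachable through `is_a`
(optionally `part_of`) relations within one ontology aspect.

For a reference corpus of *N* proteins, a term *t* annotating *n_t* of them
has information content

```
IC(t) = -log2 f(t),   f(t) = n_t / N
```

normalized by the maximum IC over all annotated terms so the rarest term
scores 1. For a family *fam*, with `freq_fam(term)` the fraction of the
family's annotated proteins carrying *term* (after propagation) and the
scope running over the family's directly-asserted terms:

```
GOscore(fam)      = MAX_{term in fam} [ freq_fam(term) x IC(term) ]
GOoccurrence(fam) = AVG_{term in fam} [ freq_fam(term) ]
```

GOscore is high when a predominant term is also informative; GOoccurrence
equals 1 exactly when every scoped term is shared by every annotated
protein. A descendant-restricted GOoccurrence variant recomputes the mean
over only the terms descending from a chosen focus term, discarding
secondary-function terms.

The extension pipeline then, per family: (1) selects *relevant terms* by
one-sided hypergeometric enrichment against a background corpus with
Benjamini–Yekutieli FDR correction (default α = 0.01) plus optional manual
allow/deny rules; (2) reports coherence; (3) exports each relevant term's
*support set* (proteins already carrying it) for external classifier
construction; (4) lists *extension candidates* (annotated family proteins
lacking the term); and (5) reports the coherence differential obtained if
the term were extended to all candidates. Proposals are emitted, not
applied — applying them is an explicit, logged step.

## Worked example

The builtin `PL22` scenario models a mono-specific family of 29 proteins in
which 22 are annotated to a specific leaf term (an oligogalacturonide-lyase
analogue) and 7 stop at its generic ancestor:

```python
from gocoherence import builtin_scenario, go_occurrence, propose_extensions

graph, corpus, family = builtin_scenario("PL22")
report = go_occurrence(family, corpus, graph)
print(f"GOoccurrence = {report.go_occurrence:.3f}")
for p in propose_extensions(family, corpus, graph):
    print(f"extend {p.term}: support={len(p.support)} "
          f"candidates={len(p.candidates)} "
          f"coherence {p.coherence_before:.3f} -> {p.coherence_after:.3f}")
```

prints

```
GOoccurrence = 0.879
extend GO:0047487: support=22 candidates=7 coherence 0.879 -> 1.000
```

The family scores 0.879 — penalized by the 7 proteins lacking the specific
term — and the pipeline proposes exactly that term, with the 22 already
annotated proteins as classifier support and the 7 incomplete ones as
candidates; extending it would restore perfect coherence (1.000).

The same workflow is available from the shell over standard OBO, GAF and
family-table files:

```
gocoherence simulate --scenario PL22 --outdir fx
gocoherence coherence --obo fx/PL22.obo --gaf fx/PL22.gaf --families fx/PL22.families.tsv
gocoherence extend    --obo fx/PL22.obo --gaf fx/PL22.gaf --families fx/PL22.families.tsv --outdir out
gocoherence flowgraph --obo fx/PL22.obo --gaf fx/PL22.gaf --families fx/PL22.families.tsv --family PL22 --out pl22.dot
```

The flow graph renders terms annotating the family with edges carrying the
number of proteins "flowing down" from generic to specific terms; directly
asserted terms appear as gray labelled nodes, inherited ones as unlabelled
white nodes.

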