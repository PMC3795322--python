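# Methods notes

## Model and assumptions

The package operates on three objects: an ontology (a rooted DAG of terms
with typed `is_a`/`part_of`/`regulates` parent relations, split into
aspects), an annotation corpus (protein–term associations with evidence
codes), and families (named protein sets). Every analysis first applies the
true path rule: a protein's term set is closed under the ancestor relation,
with propagated annotations flagged non-direct and inheriting the evidence
of the direct annotations implying them. Propagation is idempotent.

Traversal defaults to `is_a` edges only, with `part_of` available by
option. `regulates`-family edges are parsed and stored but never traversed:
they can cross aspects, and the frequency model underlying the metrics
assumes all counting stays within one aspect. The analysis aspect defaults
to molecular function. Obsolete terms are kept in the graph but excluded
from traversal; annotations to unknown or obsolete terms are dropped with a
warning rather than failing a whole corpus load. Alternate (merged) ids
resolve silently to their primary id with a logged notice.

## Metric definitions and conventions

* **IC**: `-log2` of the fraction of corpus proteins carrying the term
  (direct or propagated). Reported normalized by the maximum IC over all
  annotated terms of the reference corpus, so the rarest term(s) score
  exactly 1 and a ubiquitous term scores 0. The reference corpus defaults
  to the full loaded corpus; a separate background corpus may be supplied.
* **Term scope**: `GOscore` and `GOoccurrence` aggregate over the family's
  *directly asserted* terms (aspect roots excluded), while each scoped
  term's within-family frequency is counted *after* propagation and divided
  by the family's annotated-protein count. This is the only scope
  convention under which a two-term family with frequencies 1 and 22/29
  averages to ≈ 0.879 while a family whose only direct term is shared by
  everyone scores exactly 1; including all propagated ancestors in the
  scope would inflate the mean, and counting direct-only frequencies would
  halve it.
* **GOscore ties** break toward the higher normalized IC, then the
  lexicographically smaller term id, making reports deterministic.
* Family *size* counts proteins with ≥ 1 direct annotation in the analysis
  aspect; unannotated members stay in the family but never enter
  denominators.
* Report tables round scores to 3 decimals and print p-values with 2
  significant digits.

## Enrichment

Each scoped term is tested with the one-sided hypergeometric upper tail
P(X ≥ k) (the enrichment side of Fisher's exact test; the two coincide for
this tail). Correction is Benjamini–Yekutieli by default — term tests are
strongly positively and negatively dependent through the hierarchy, and BY
controls FDR under arbitrary dependence — applied per family across that
family's scoped term list, matching per-family reporting; a cross-family
correction and Benjamini–Hochberg are available by configuration.
Significance uses strict `p_adj < α`, α = 0.01 by default. The background
defaults to the full loaded corpus (for fixtures: family plus filler).

## Extension pipeline conventions

* `min_support` (default 10) is the smallest support set considered able to
  seed a per-term classifier. It is an operational knob, not an estimated
  quantity: supports of 1–4 proteins are too thin to train on, ~30 is
  comfortable.
* Candidates default to *all* annotated family proteins lacking the term.
  An optional `within` pool term restricts candidates to carriers of an
  ancestor — the proteins exactly one refinement step away — which is the
  natural pool when extending a leaf under an already-established generic
  annotation.
* When a `focus` term is configured, relevant-term selection keeps
  descendants(focus) ∪ {focus}, but the focus itself is never proposed as
  an extension target: it defines the functional context being refined.
  Without this rule any generic focus term with incomplete coverage would
  always dominate the proposal list.
* Classifier construction (alignments, PSSMs, HMMs, SVMs) is out of scope
  by design; proposals export support/candidate accession sets for external
  tools, and applying an extension is an explicit step recorded with a
  config hash and a distinguishing evidence note (`IEA-EXT`).

## Synthetic scenarios

The builtin scenarios emulate recurring annotation patterns of curated
polysaccharide-lyase-like enzyme families: partial specific annotation
(PL22: 29 proteins, 22 specific + 7 generic-only), a dominant term plus
rare secondary terms (PL3: 228 + 12 + six terms of ≤ 2), a multi-functional
family whose most specific term is off the main lineage (PL4: 43 proteins,
25 generic-term carriers), asymmetric leaf siblings (PL8: supports
31/4/2/1/1 under a 180-carrier parent), and a perfectly coherent
mono-specific family (PL5). Counts are realized exactly by block placement
over protein indices — no sampling — so every downstream number is
deterministic; random DAG/corpus generators (seeded) exist for property
tests. Term ids follow the GO code style but the ontology is synthetic and
illustrative.

Each scenario pads its corpus with deterministic filler proteins so that
enrichment contrasts exist: a catalytic-activity analogue is ubiquitous in
the background (hence never significant in a family), while
family-concentrated terms are significant. The default filler is 600
proteins; PL8 uses 70 000 so that even its singleton leaf terms clear
per-family BY correction at α = 0.01, mirroring the situation against a
large reference corpus where a family-exclusive term is extreme evidence.
What the fixtures deliberately do not emulate: realistic GO topology
(thousands of terms, deep multi-parent paths), evidence-code mixtures,
multi-aspect annotation, or the exact IC values a real GO-annotation
corpus snapshot would give — so passing tests demonstrate metric and
pipeline correctness, not agreement with any particular database release.

## Numerical choices and degenerate inputs

Hypergeometric tails come from `scipy.stats.hypergeom.sf`; tests verify
them against exhaustive tail sums for all table sizes N ≤ 60. FDR
adjustment delegates to `statsmodels` (`fdr_by`/`fdr_bh`), verified against
the hand-evaluated step-up formula. An empty corpus makes IC undefined
(error); a family with no annotated protein in the aspect is an explicit
error, as is a term scope emptied by a focus restriction. k = 0 yields
p = 1 (no enrichment evidence). Flow-graph edge weights equal the child's
protein count on every incoming drawn edge (flow through multi-parent terms
is not split — there is no principled split without per-protein path
attribution); transitive edges between included terms are reduced by
default and available behind a flag. DOT penwidth scales linearly with
weight (max 8, min 1).

## Problem sizes

The test suite and acceptance script run the builtin scenarios as
specified above (largest corpus ≈ 70 000 proteins, ≈ 300 000 propagated
annotations) plus property suites over random DAGs of 20–40 terms with up
to 100 seeds per property; the whole suite completes in well under a
minute on one CPU.

## Known limitations

* GOoccurrence is deliberately naive: families of multifunctional proteins
  with unevenly shared functions depress it even when annotation is
  correct; the descendant-restricted variant is the provided remedy and
  requires a domain-informed focus choice.
* The candidate/pool ambiguity (family-wide vs. parent-carrier pool) is
  surfaced as the `within` option rather than resolved; both conventions
  are defensible and give different candidate counts.
* GAF handling covers qualifier `NOT`, evidence filtering and aspect
  mapping only — no GPAD, taxon filtering or date semantics.
* Per-family correction means a term's adjusted p-value depends on how
  many terms its family uses.
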