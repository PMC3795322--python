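"""Synthetic ontologies, corpora and families for testing and demos.

Builds small molecular-function ontologies and annotation corpora with the
statistical structure of recurring real-world annotation patterns in
curated enzyme families:

``PL22``
    a mono-specific family with partial specific annotation — 29 proteins,
    22 directly annotated to a specific leaf term and 7 stopping at its
    generic ancestor;
``PL3``
    one dominant term carried by all 228 proteins plus a second substantial
    term and six rare off-lineage secondary terms (at most 2 proteins each);
``PL4``
    a multi-functional family of 43 proteins whose most specific term is
    not on the main enzymatic lineage;
``PL8``
    a family of 184 proteins with five leaf descendants of the generic
    enzymatic term at strongly asymmetric supports (31, 4, 2, 1, 1);
``PL5``
    a perfectly coherent mono-specific family (37 proteins, one term).

Term identifiers follow the GO code style but the ontology is synthetic:
ids and names are illustrative, not authoritative GO content. Builtin
scenarios realize their per-term protein counts exactly (block placement,
not Bernoulli sampling), so every downstream number is deterministic; the
random generators exist for property testing and are reproducible per
seed. Each scenario pads its corpus with deterministic filler ("BG")
proteins so that term-enrichment contrasts exist: ubiquitous terms are not
enriched in a family while family-concentrated terms are.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import (
    Annotation,
    AnnotationCorpus,
    Family,
    propagate,
    write_family_table,
    write_gaf,
)
from .ontology import OntologyGraph, parse_obo

MF = "molecular_function"

# (id, name, parent ids); synthetic molecular-function fragment
_BASE_TERMS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("GO:0003674", "molecular_function", ()),
    ("GO:0003824", "catalytic activity", ("GO:0003674",)),
    ("GO:0016829", "lyase activity", ("GO:0003824",)),
    ("GO:0016837", "carbon-oxygen lyase activity, acting on polysaccharides", ("GO:0016829",)),
    ("GO:0030570", "pectate lyase activity", ("GO:0016837",)),
    ("GO:0047490", "pectin lyase activity", ("GO:0016837",)),
    ("GO:0047487", "oligogalacturonide lyase activity", ("GO:0016837",)),
    ("GO:0030340", "hyaluronate lyase activity", ("GO:0016837",)),
    ("GO:0034000", "chondroitin-sulfate-ABC endolyase activity", ("GO:0016837",)),
    ("GO:0034001", "chondroitin-sulfate-ABC exolyase activity", ("GO:0016837",)),
    ("GO:0030341", "chondroitin AC lyase activity", ("GO:0016837",)),
    ("GO:0085030", "xanthan lyase activity", ("GO:0016837",)),
    ("GO:0016787", "hydrolase activity", ("GO:0003824",)),
    ("GO:0008233", "peptidase activity", ("GO:0016787",)),
    ("GO:0004180", "carboxypeptidase activity", ("GO:0008233",)),
    ("GO:0016491", "oxidoreductase activity", ("GO:0003824",)),
    ("GO:0016740", "transferase activity", ("GO:0003824",)),
    ("GO:0016853", "isomerase activity", ("GO:0003824",)),
    ("GO:0005488", "binding", ("GO:0003674",)),
    ("GO:0030246", "carbohydrate binding", ("GO:0005488",)),
    ("GO:0001871", "pattern binding", ("GO:0005488",)),
    ("GO:0030247", "polysaccharide binding", ("GO:0030246", "GO:0001871")),
    ("GO:0043167", "ion binding", ("GO:0005488",)),
    ("GO:0046872", "metal ion binding", ("GO:0043167",)),
    ("GO:0005509", "calcium ion binding", ("GO:0046872",)),
    ("GO:0008270", "zinc ion binding", ("GO:0046872",)),
    ("GO:0005515", "protein binding", ("GO:0005488",)),
    ("GO:0003677", "DNA binding", ("GO:0005488",)),
    # rare filler leaves giving the corpus an IC spread
    ("GO:0777001", "background activity 1", ("GO:0003824",)),
    ("GO:0777002", "background activity 2", ("GO:0003824",)),
    ("GO:0777003", "background activity 3", ("GO:0003824",)),
    ("GO:0777004", "background binding 1", ("GO:0005488",)),
    ("GO:0777005", "background binding 2", ("GO:0005488",)),
    ("GO:0777006", "background binding 3", ("GO:0005488",)),
)


class ScenarioSpecError(ValueError):
    """The scenario specification is not exactly realizable."""


#: term -> ((start_index, count), ...) block placements over a protein range
Blocks = Mapping[str, tuple[tuple[int, int], ...]]


@dataclass(frozen=True)
class BackgroundSpec:
    """Deterministic filler corpus padding a scenario's background."""

    n_proteins: int
    blocks: Blocks
    prefix: str = "BG"


@dataclass(frozen=True)
class ScenarioSpec:
    """Exact-count layout of one synthetic family scenario.

    ``coverage`` maps a term to the fraction (or integer count) of family
    proteins directly annotated to it, placed from protein index 0;
    ``blocks`` overrides placement with explicit (start, count) runs.
    Fractions must realize integral counts (exact mode): a non-integral
    request raises :class:`ScenarioSpecError`. ``focus`` records the
    recommended focus term for descendant-restricted analyses of the
    scenario. Generated output is reproducible from (spec, seed); builtin
    scenarios use no randomness at all.
    """

    name: str
    n_proteins: int
    coverage: Mapping[str, float] = field(default_factory=dict)
    blocks: Blocks = field(default_factory=dict)
    background: BackgroundSpec | None = None
    focus: str | None = None
    seed: int = 0
    prefix: str = "F"

    def resolved_blocks(self) -> dict[str, tuple[tuple[int, int], ...]]:
        out: dict[str, tuple[tuple[int, int], ...]] = dict(self.blocks)
        for term, cov in self.coverage.items():
            if isinstance(cov, float):
                exact = cov * self.n_proteins
                count = round(exact)
                if abs(exact - count) > 1e-9:
                    raise ScenarioSpecError(
                        f"{self.name}: coverage {cov} of {self.n_proteins} "
                        f"proteins for {term} is not an integral count"
                    )
            else:
                count = int(cov)
            if not 0 < count <= self.n_proteins:
                raise ScenarioSpecError(
                    f"{self.name}: count {count} for {term} outside (0, n]"
                )
            out[term] = ((0, count),)
        return out


def base_ontology_obo() -> str:
    """OBO 1.2 text of the synthetic molecular-function ontology."""
    out = ["format-version: 1.2", "ontology: synthetic-mf", ""]
    for tid, name, parents in _BASE_TERMS:
        out.append("[Term]")
        out.append(f"id: {tid}")
        out.append(f"name: {name}")
        out.append(f"namespace: {MF}")
        for p in parents:
            out.append(f"is_a: {p}")
        out.append("")
    return "\n".join(out)


def base_ontology() -> OntologyGraph:
    return parse_obo(StringIO(base_ontology_obo()))


def write_obo(graph: OntologyGraph) -> str:
    """Deterministic OBO serialization (round-trips through parse_obo)."""
    out = ["format-version: 1.2", ""]
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        out.append("[Term]")
        out.append(f"id: {t.id}")
        if t.name:
            out.append(f"name: {t.name}")
        if t.aspect:
            out.append(f"namespace: {t.aspect}")
        for alt in t.alt_ids:
            out.append(f"alt_id: {alt}")
        for parent, rel in t.parents:
            if rel == "is_a":
                out.append(f"is_a: {parent}")
            else:
                out.append(f"relationship: {rel} {parent}")
        if t.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out)


def _annotations(prefix: str, width: int, blocks: Blocks, evidence: str):
    for term, runs in blocks.items():
        for start, count in runs:
            for i in range(start, start + count):
                yield Annotation(
                    protein=f"{prefix}{i + 1:0{width}d}",
                    term=term,
                    evidence=(evidence,),
                    aspect=MF,
                )


def make_scenario(
    spec: ScenarioSpec, propagated: bool = True
) -> tuple[OntologyGraph, AnnotationCorpus, Family]:
    """Materialize a scenario: ontology, (propagated) corpus with filler
    background, and the family under study."""
    graph = base_ontology()
    blocks = spec.resolved_blocks()
    anns = list(_annotations(spec.prefix, 4, blocks, "IDA"))
    if spec.background is not None:
        anns += list(
            _annotations(
                spec.background.prefix, 5, spec.background.blocks, "IEA"
            )
        )
    corpus = AnnotationCorpus(anns)
    if propagated:
        corpus = propagate(corpus, graph)
    family = Family(
        name=spec.name,
        proteins=frozenset(
            f"{spec.prefix}{i + 1:04d}" for i in range(spec.n_proteins)
        ),
    )
    return graph, corpus, family


def _default_background(n: int = 600) -> BackgroundSpec:
    """Generic filler: catalytic activity ubiquitous, binding common,
    a handful of specific-term carriers, rare leaves for IC spread."""
    return BackgroundSpec(
        n_proteins=n,
        blocks={
            "GO:0003824": ((0, 480),),
            "GO:0005488": ((240, 360),),
            "GO:0030246": ((0, 30),),
            "GO:0016829": ((480, 5),),
            "GO:0046872": ((500, 20),),
            "GO:0005515": ((520, 20),),
            "GO:0777001": ((540, 3),),
            "GO:0777002": ((543, 3),),
            "GO:0777003": ((546, 3),),
            "GO:0777004": ((549, 3),),
            "GO:0777005": ((552, 3),),
            "GO:0777006": ((555, 3),),
        },
    )


def _large_background(n: int = 70_000) -> BackgroundSpec:
    """Scaled-up filler so that even singleton family-exclusive terms reach
    significance under per-family Benjamini–Yekutieli correction."""
    return BackgroundSpec(
        n_proteins=n,
        blocks={
            "GO:0003824": ((0, 56_000),),
            "GO:0005488": ((28_000, 42_000),),
            "GO:0030246": ((0, 30),),
            "GO:0016829": ((56_000, 5),),
            "GO:0046872": ((60_000, 2_000),),
            "GO:0005515": ((62_000, 1_000),),
            "GO:0777001": ((63_000, 3),),
            "GO:0777002": ((63_003, 3),),
            "GO:0777003": ((63_006, 3),),
            "GO:0777004": ((63_009, 3),),
            "GO:0777005": ((63_012, 3),),
            "GO:0777006": ((63_015, 3),),
        },
    )


BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    # 22 of 29 proteins on the specific leaf, 7 stopping at the ancestor
    "PL22": ScenarioSpec(
        name="PL22",
        n_proteins=29,
        blocks={
            "GO:0047487": ((0, 22),),
            "GO:0016829": ((22, 7),),
        },
        background=_default_background(),
        focus="GO:0016829",
    ),
    # dominant term on all 228 proteins, a second substantial term, and six
    # rare off-lineage secondary terms (<= 2 proteins each)
    "PL3": ScenarioSpec(
        name="PL3",
        n_proteins=228,
        blocks={
            "GO:0030570": ((0, 228),),
            "GO:0047490": ((0, 12),),
            "GO:0005515": ((0, 2),),
            "GO:0003677": ((2, 2),),
            "GO:0016491": ((4, 2),),
            "GO:0016740": ((6, 1),),
            "GO:0016853": ((7, 1),),
            "GO:0008270": ((8, 1),),
        },
        background=_default_background(),
        focus="GO:0016829",
    ),
    # multi-functional family; most specific term off the enzymatic lineage
    "PL4": ScenarioSpec(
        name="PL4",
        n_proteins=43,
        blocks={
            "GO:0030246": ((0, 43),),
            "GO:0016837": ((0, 16),),
            "GO:0016829": ((16, 9),),
            "GO:0004180": ((0, 6), (25, 1)),
            "GO:0005509": ((26, 1),),
            "GO:0003824": ((27, 6),),
        },
        background=_default_background(),
        focus="GO:0016829",
    ),
    # five asymmetric leaf descendants (31, 4, 2, 1, 1) of the generic term
    "PL8": ScenarioSpec(
        name="PL8",
        n_proteins=184,
        blocks={
            "GO:0030340": ((0, 31),),
            "GO:0034000": ((31, 4),),
            "GO:0030341": ((35, 2),),
            "GO:0034001": ((37, 1),),
            "GO:0085030": ((38, 1),),
            "GO:0016837": ((39, 141),),
            "GO:0016829": ((180, 1),),
            "GO:0030246": ((4, 178),),
            "GO:0046872": ((182, 2),),
        },
        background=_large_background(),
        focus="GO:0016837",
    ),
    # perfectly coherent mono-specific family
    "PL5": ScenarioSpec(
        name="PL5",
        n_proteins=37,
        blocks={"GO:0030570": ((0, 37),)},
        background=_default_background(),
        focus="GO:0016829",
    ),
}


def builtin_scenario(
    name: str, propagated: bool = True
) -> tuple[OntologyGraph, AnnotationCorpus, Family]:
    if name not in BUILTIN_SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(BUILTIN_SCENARIOS)}"
        )
    return make_scenario(BUILTIN_SCENARIOS[name], propagated=propagated)


# -- random fixtures for property testing ---------------------------------

def random_dag_corpus(
    n_terms: int,
    n_proteins: int,
    depth: int = 4,
    seed: int = 0,
    max_parents: int = 2,
    max_terms_per_protein: int = 3,
) -> tuple[OntologyGraph, AnnotationCorpus]:
    """A random rooted DAG ontology plus an unpropagated corpus in which
    every protein carries at least one direct annotation. Reproducible per
    seed (term layout, parent choice and annotation draws all come from one
    seeded generator)."""
    if n_terms < 1:
        raise ValueError("need at least one term (the root)")
    rng = random.Random(seed)
    ids = [f"T:{i:07d}" for i in range(n_terms)]
    levels: dict[str, int] = {ids[0]: 0}
    parents: dict[str, list[str]] = {ids[0]: []}
    for i, tid in enumerate(ids[1:], 1):
        level = rng.randint(1, max(1, depth - 1))
        pool = [t for t in ids[:i] if levels[t] < level] or [ids[0]]
        k = min(len(pool), rng.randint(1, max_parents))
        parents[tid] = rng.sample(pool, k)
        levels[tid] = max(levels[p] for p in parents[tid]) + 1

    obo = ["format-version: 1.2", ""]
    for tid in ids:
        obo += [
            "[Term]",
            f"id: {tid}",
            f"name: random term {tid}",
            f"namespace: {MF}",
            *[f"is_a: {p}" for p in parents[tid]],
            "",
        ]
    graph = parse_obo(StringIO("\n".join(obo)))

    anns = []
    for j in range(n_proteins):
        protein = f"P{j + 1:05d}"
        k = rng.randint(1, max_terms_per_protein)
        for term in rng.sample(ids, min(k, len(ids))):
            anns.append(
                Annotation(protein=protein, term=term, evidence=("IEA",), aspect=MF)
            )
    return graph, AnnotationCorpus(anns)


def write_scenario_files(
    spec: ScenarioSpec, outdir: str | Path
) -> dict[str, Path]:
    """Emit the scenario as standard OBO + GAF + family-table files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, corpus, family = make_scenario(spec, propagated=False)
    paths = {
        "obo": outdir / f"{spec.name}.obo",
        "gaf": outdir / f"{spec.name}.gaf",
        "families": outdir / f"{spec.name}.families.tsv",
    }
    paths["obo"].write_text(write_obo(graph))
    with open(paths["gaf"], "w") as fh:
        write_gaf(corpus, fh)
    with open(paths["families"], "w") as fh:
        write_family_table({family.name: family}, fh)
    return paths
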