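"""Per-family term enrichment with exact one-sided tests and FDR control.

For each scoped term, the family's carrier count ``k`` (out of ``n``
annotated family proteins) is compared with the background carrier count
``K`` (out of ``N`` background proteins) with the one-sided hypergeometric
tail P(X >= k) — the enrichment direction of Fisher's exact test. Raw
p-values are corrected per family with the Benjamini–Yekutieli step-up
procedure, which controls the false discovery rate under arbitrary
dependence between tests (term tests are strongly dependent through the
ontology hierarchy), at a default level alpha = 0.01. Benjamini–Hochberg
is offered as a less conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .corpus import DEFAULT_ASPECT, AnnotationCorpus, Family
from .metrics import TermStats, term_stats
from .ontology import OntologyGraph


@dataclass(frozen=True)
class EnrichmentConfig:
    alpha: float = 0.01
    correction: str = "BY"  # BY | BH | none

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.correction not in {"BY", "BH", "none"}:
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool
    ic_norm: float = float("nan")


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N, K, n); 1.0 when k = 0."""
    if k < 0 or n < 0 or K < 0 or N < n or K > N or k > min(n, K):
        raise ValueError(f"inconsistent table k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    family: Family,
    background: AnnotationCorpus,
    term: str,
    aspect: str = DEFAULT_ASPECT,
) -> tuple[int, int, int, int, float]:
    """Enrichment table (k, n, K, N) and raw one-sided p for one term.

    Counts use propagated annotations; ``n`` is the family's annotated size
    and ``N`` the background protein count.
    """
    annotated = family.annotated_proteins(background, aspect)
    carriers = background.proteins_with(term)
    k = len(carriers & annotated)
    n = len(annotated)
    K = len(carriers)
    N = background.protein_count
    if K == 0 and k > 0:
        raise ValueError(
            f"term {term} annotates family proteins but no background protein: "
            "family is not a subset of the background"
        )
    return k, n, K, N, hypergeom_tail(k, n, K, N)


def by_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Yekutieli adjusted p-values, in input order.

    With m tests and c(m) = sum_{i=1..m} 1/i, the sorted adjusted values are
    the cumulative minimum from the largest rank of min(1, m c(m) p_(j)/j).
    Adjusted values are >= raw and monotone in raw rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1].tolist()


def bh_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (valid under independence or
    positive dependence; elementwise <= the BY adjustment)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


_CORRECTIONS = {"BY": by_correct, "BH": bh_correct, "none": lambda p: list(map(float, p))}


def enrich_family(
    family: Family,
    background: AnnotationCorpus,
    graph: OntologyGraph,
    config: EnrichmentConfig = EnrichmentConfig(),
    aspect: str = DEFAULT_ASPECT,
    stats: Mapping[str, TermStats] | None = None,
    scope: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment over the family's term scope (its directly-asserted
    terms), corrected across that per-family term list.

    Significance uses strict inequality ``p_adj < alpha``. Results sort by
    adjusted p-value, then by normalized IC descending.
    """
    if scope is None:
        scope = background.family_direct_terms(family, aspect, graph)
        scope = {graph.resolve(t) for t in scope if t in graph}
    terms = sorted(scope)
    if stats is None:
        stats = term_stats(background, graph)
    tables = [fisher_enrichment(family, background, t, aspect) for t in terms]
    adjusted = _CORRECTIONS[config.correction]([tab[4] for tab in tables])
    results = [
        EnrichmentResult(
            term=t,
            k=k, n=n, K=K, N=N,
            p_raw=p,
            p_adj=min(1.0, adj),
            significant=adj < config.alpha,
            ic_norm=stats[t].ic_norm if t in stats else float("nan"),
        )
        for t, (k, n, K, N, p), adj in zip(terms, tables, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, -r.ic_norm, r.term))
    return results


def write_enrichment_table(
    results: Iterable[EnrichmentResult], stream: TextIO, graph: OntologyGraph | None = None
) -> None:
    """Tab-separated report: GO_term, p_corr, IC_norm, Annotations.
    p-values in scientific notation with 2 significant digits."""
    stream.write("GO_term\tp_corr\tIC_norm\tAnnotations\n")
    for r in results:
        label = graph.name(r.term) if graph is not None else r.term
        stream.write(f"{label or r.term}\t{r.p_adj:.2e}\t{r.ic_norm:.3f}\t{r.k}\n")
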