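"""GO biological-process assignment by guilt-by-association.

Two contexts provide candidate annotations for a SEP (or any unannotated
node treated as unknown): the annotated coding genes sharing its MCL
module (module method), and its annotated immediate coding-gene
neighbours (hub method; a node qualifies as a hub when it has at least
five such neighbours).  Within a context every GO BP term observed there
is tested for over-representation against the background of all
annotated protein nodes in the network with the one-sided hypergeometric
(Fisher exact upper-tail) test, Benjamini-Hochberg adjusted within the
context; terms with adjusted p below alpha (default 0.05) are assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_networks import AnnotationNetwork
from .formats_io import GoAnnotationMap
from .mcl_clustering import Module

logger = logging.getLogger("sepfun")

DEFAULT_MIN_ANNOTATED_NEIGHBORS = 5
DEFAULT_ALPHA = 0.05


@dataclass
class HubNeighborhood:
    """A network node with its annotated immediate coding-gene neighbours."""

    sep_id: str
    neighbors: set[str]
    annotated_neighbors: set[str]

    def __post_init__(self) -> None:
        if self.sep_id in self.neighbors:
            raise ValueError("node cannot neighbour itself")
        if not self.annotated_neighbors <= self.neighbors:
            raise ValueError("annotated_neighbors must be a subset of neighbors")


@dataclass
class EnrichmentResult:
    """One GO term's hypergeometric test outcome within a context.

    k of n annotated context genes carry the term; K of N background
    genes do.
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float


@dataclass
class SepFunctionReport:
    """Significant terms assigned to one SEP by one method/context."""

    sep_id: str
    method: str  # "hub" | "module"
    context_id: str
    terms: list[EnrichmentResult] = field(default_factory=list)

    @property
    def term_ids(self) -> set[str]:
        return {t.term_id for t in self.terms}


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed stably.

    k: context genes carrying the term, n: context size, K: background
    genes carrying the term, N: background size.
    """
    if k < 0 or n < 0 or K < 0 or n > N or K > N or k > n or k > K:
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def detect_hubs(net: AnnotationNetwork,
                min_annotated_neighbors: int = DEFAULT_MIN_ANNOTATED_NEIGHBORS,
                targets: Iterable[str] | None = None) -> list[HubNeighborhood]:
    """Hub neighbourhoods for SEP nodes (or explicit *targets*).

    A node qualifies when it has at least *min_annotated_neighbors*
    immediate neighbours carrying GO BP annotations (inclusive bound);
    only protein (coding-gene) neighbours count as annotatable context.
    """
    if targets is None:
        targets = net.sep_nodes()
    hubs = []
    for node in sorted(targets):
        if node not in net.graph:
            continue
        neighbors = set(net.graph.neighbors(node))
        annotated = {
            v for v in neighbors
            if net.graph.nodes[v].get("node_type") == "protein" and net.go_terms(v)
        }
        if len(annotated) >= min_annotated_neighbors:
            hubs.append(HubNeighborhood(sep_id=node, neighbors=neighbors,
                                        annotated_neighbors=annotated))
    return hubs


def enrich_context(context_genes: Iterable[str], annotations: GoAnnotationMap,
                   background: Iterable[str],
                   alpha: float = DEFAULT_ALPHA) -> list[EnrichmentResult]:
    """Terms over-represented in *context_genes* relative to *background*.

    Tests one term per GO BP term appearing in at least one context gene;
    Benjamini-Hochberg adjusts across the terms tested within this
    context; returns terms with p_adj < alpha sorted by ascending p_adj.
    """
    background = sorted(set(background))
    context = sorted(set(context_genes) & set(background))
    context_annot = [g for g in context if annotations.get(g)]
    if not context_annot:
        return []
    n = len(context_annot)
    bg_annot = [g for g in background if annotations.get(g)]
    N = len(bg_annot)

    terms = sorted({t for g in context_annot for t in annotations.get(g)})
    results = []
    for term in terms:
        k = sum(1 for g in context_annot if term in annotations.get(g))
        K = sum(1 for g in bg_annot if term in annotations.get(g))
        p = hypergeom_upper_tail(k, n, K, N)
        results.append(EnrichmentResult(
            term_id=term, term_name=annotations.term_names.get(term, ""),
            k=k, K=K, n=n, N=N, p=p, p_adj=p,
        ))
    if results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, p_adj):
            r.p_adj = float(q)
    passing = [r for r in results if r.p_adj < alpha]
    passing.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return passing


def annotate_seps(net: AnnotationNetwork, modules: Sequence[Module],
                  hubs: Sequence[HubNeighborhood],
                  annotations: GoAnnotationMap,
                  alpha: float = DEFAULT_ALPHA,
                  targets: Iterable[str] | None = None,
                  background: Iterable[str] | None = None) -> list[SepFunctionReport]:
    """Module- and hub-method function reports for every annotatable target.

    *modules* must already be filtered by
    :func:`~sepfun.mcl_clustering.select_annotation_modules`.  Targets
    default to the network's SEP nodes; contexts contain annotated coding
    genes only, and the background defaults to all annotated protein
    nodes in the network.
    """
    if targets is None:
        targets = set(net.sep_nodes())
    else:
        targets = set(targets)
    if background is None:
        background = {n for n in net.protein_nodes() if net.go_terms(n)}
    else:
        background = set(background)

    reports: list[SepFunctionReport] = []

    for module in modules:
        context = {
            n for n in module.members
            if n in net.graph
            and net.graph.nodes[n].get("node_type") == "protein"
            and net.go_terms(n)
        }
        module_targets = sorted(module.members & targets)
        if not module_targets or not context:
            continue
        enriched = enrich_context(context, annotations, background, alpha=alpha)
        for node in module_targets:
            reports.append(SepFunctionReport(
                sep_id=node, method="module", context_id=module.module_id,
                terms=list(enriched),
            ))

    for hub in hubs:
        if hub.sep_id not in targets:
            continue
        enriched = enrich_context(hub.annotated_neighbors, annotations,
                                  background, alpha=alpha)
        reports.append(SepFunctionReport(
            sep_id=hub.sep_id, method="hub", context_id=f"hub:{hub.sep_id}",
            terms=list(enriched),
        ))

    reports.sort(key=lambda r: (r.sep_id, r.method, r.context_id))
    return reports


def functional_seps(reports: Sequence[SepFunctionReport]) -> set[str]:
    """Targets with at least one significantly enriched term."""
    return {r.sep_id for r in reports if r.terms}
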