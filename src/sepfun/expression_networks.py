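"""Co-expression edge construction and the merged annotation network.

Two correlation layers are built from TPM matrices over the same samples:
``r`` pairs SEP translation profiles with partner-protein transcription
profiles, ``t`` pairs them with partner translation profiles.  A pair
becomes an edge when |Pearson r| exceeds ``min_abs_r`` (default 0.97) and
the two-sided p-value is below ``max_p`` (default 0.01) — both strict.
Co-location pairs (SEP and protein on the same RNA) enter as layer ``n``
with unit weight.  The merged, undirected annotation network carries edge
provenance tags and per-node GO biological-process sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import MIN_SAMPLES, GoAnnotationMap
from .sep_identification import ColocationPair

logger = logging.getLogger("sepfun")

DEFAULT_MIN_ABS_R = 0.97
DEFAULT_MAX_P = 0.01


@dataclass
class ExpressionMatrix:
    """TPM values, features x samples, at one expression level."""

    values: pd.DataFrame
    level: str  # "transcription" | "translation"

    def __post_init__(self) -> None:
        if self.level not in ("transcription", "translation"):
            raise ValueError(f"unknown expression level {self.level!r}")
        if self.values.shape[1] < MIN_SAMPLES:
            raise ValueError(
                f"{self.values.shape[1]} samples; at least {MIN_SAMPLES} required"
            )
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("TPM values must be finite and non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[wanted], self.level)


@dataclass(frozen=True)
class CorrelationEdge:
    sep_id: str
    partner_id: str
    r: float
    p: float
    level: str  # "r" (transcription) | "t" (translation)

    def __post_init__(self) -> None:
        if abs(self.r) > 1 or not (0 <= self.p <= 1):
            raise ValueError("correlation edge out of range")
        if self.sep_id == self.partner_id:
            raise ValueError("self-correlation edge")


@dataclass
class EdgeFilterParams:
    """Strict thresholds on |r| and p for calling a co-expression edge."""

    min_abs_r: float = DEFAULT_MIN_ABS_R
    max_p: float = DEFAULT_MAX_P

    def __post_init__(self) -> None:
        if not (0 < self.min_abs_r <= 1):
            raise ValueError("min_abs_r must be in (0, 1]")
        if not (0 < self.max_p <= 1):
            raise ValueError("max_p must be in (0, 1]")


class ZeroVarianceError(ValueError):
    """A profile with zero variance has no defined correlation."""


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value.

    p is the two-sided tail of Student's t with n-2 degrees of freedom at
    t = r*sqrt((n-2)/(1-r^2)); |r| = 1 yields p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < MIN_SAMPLES:
        raise ValueError(f"need equal-length vectors with n >= {MIN_SAMPLES}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("zero-variance profile: correlation undefined")
    r = float(np.dot(xc, yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    # |r| within a few ulps of 1 only arises from exact collinearity
    if abs(r) >= 1.0 - 1e-14:
        return math.copysign(1.0, r), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs correlation between rows of *a* and rows of *b*.

    Returns (R, P, ok_a, ok_b) where ok_* flag rows with nonzero variance;
    R rows/cols for constant profiles are NaN.
    """
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    ok_a, ok_b = sa > 0, sb > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    exact = np.abs(r) >= 1.0 - 1e-14
    r = np.where(exact, np.sign(r), r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(exact, 0.0, p)
    return r, p, ok_a, ok_b


def build_coexpression_edges(seps: ExpressionMatrix, partners: ExpressionMatrix,
                             level: str,
                             params: EdgeFilterParams | None = None) -> list[CorrelationEdge]:
    """All (SEP, partner) pairs with |r| > min_abs_r and p < max_p.

    Both inequalities are strict.  The two matrices must share identically
    ordered sample columns.  Constant profiles are skipped and counted.
    """
    if level not in ("r", "t"):
        raise ValueError(f"level must be 'r' or 't', got {level!r}")
    params = params or EdgeFilterParams()
    if seps.sample_ids != partners.sample_ids:
        diff = set(seps.sample_ids) ^ set(partners.sample_ids)
        raise ValueError(
            "sample columns differ between the two matrices; symmetric "
            f"difference: {sorted(diff) or 'same ids, different order'}"
        )
    a = seps.values.to_numpy(dtype=float)
    b = partners.values.to_numpy(dtype=float)
    r, p, ok_a, ok_b = _pairwise_pearson(a, b)
    n_const = int((~ok_a).sum() + (~ok_b).sum())
    if n_const:
        logger.info("skipped %d constant profiles in %s-level correlation", n_const, level)
    mask = np.zeros_like(r, dtype=bool)
    valid = np.outer(ok_a, ok_b)
    mask[valid] = (np.abs(r[valid]) > params.min_abs_r) & (p[valid] < params.max_p)
    sep_ids = seps.feature_ids
    partner_ids = partners.feature_ids
    edges = []
    for i, j in zip(*np.nonzero(mask)):
        if sep_ids[i] == partner_ids[j]:
            continue
        edges.append(CorrelationEdge(sep_ids[i], partner_ids[j],
                                     float(r[i, j]), float(p[i, j]), level))
    return edges


# ---------------------------------------------------------------------------
# Merged annotation network
# ---------------------------------------------------------------------------

@dataclass
class AnnotationNetwork:
    """Undirected graph of SEP and protein nodes with provenance-tagged edges.

    Node attributes: ``node_type`` in {"sep", "protein"}, ``go_terms`` (a
    frozenset, empty for unannotated nodes).  Edge attributes: ``weight``
    in (0, 1] (max |r| over contributing correlation edges, 1.0 for pure
    co-location) and ``provenance``, a non-empty subset of {"r", "t", "n"}.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def sep_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("node_type") == "sep")

    def protein_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("node_type") == "protein")

    def annotated_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("go_terms")}

    def go_terms(self, node: str) -> frozenset:
        return self.graph.nodes[node].get("go_terms", frozenset())

    def restrict_layers(self, layers: Iterable[str]) -> "AnnotationNetwork":
        """Sub-network of edges contributing to the given provenance layers.

        An edge belongs to a layer set if its provenance intersects it (a
        pair found by both the transcription- and translation-level filters
        is present in each single-layer network); provenance is restricted
        to the intersection.  Nodes left without edges are dropped.
        """
        layers = frozenset(layers)
        sub = nx.Graph()
        for u, v, d in self.graph.edges(data=True):
            keep = d["provenance"] & layers
            if keep:
                sub.add_edge(u, v, weight=d["weight"], provenance=keep)
        for n in sub.nodes:
            sub.nodes[n].update(self.graph.nodes[n])
        return AnnotationNetwork(sub)

    def strip_annotations(self, node_ids: Iterable[str]) -> "AnnotationNetwork":
        """Copy of the network with the GO sets of *node_ids* emptied."""
        g = self.graph.copy()
        for n in node_ids:
            if n in g:
                g.nodes[n]["go_terms"] = frozenset()
        return AnnotationNetwork(g)


def merge_networks(edges_r: Sequence[CorrelationEdge],
                   edges_t: Sequence[CorrelationEdge],
                   edges_n: Sequence[ColocationPair],
                   annotations: GoAnnotationMap,
                   sep_ids: Iterable[str]) -> AnnotationNetwork:
    """Union the three edge layers into one annotation network.

    One undirected edge per unordered node pair; provenance is the union
    of contributing layers; weight is the max |r| over contributing
    correlation edges, or 1.0 for pure co-location edges.  Nodes are typed
    ``sep`` iff listed in *sep_ids*; protein nodes carry their GO BP sets.
    """
    sep_ids = set(sep_ids)
    g = nx.Graph()

    def upsert(u: str, v: str, tag: str, weight: float | None) -> None:
        if u == v:
            return
        if g.has_edge(u, v):
            d = g[u][v]
            d["provenance"] = d["provenance"] | {tag}
            if weight is not None:
                d["corr_weight"] = max(d.get("corr_weight", 0.0), weight)
        else:
            g.add_edge(u, v, provenance=frozenset({tag}),
                       corr_weight=weight if weight is not None else 0.0)

    for e in edges_r:
        upsert(e.sep_id, e.partner_id, "r", abs(e.r))
    for e in edges_t:
        upsert(e.sep_id, e.partner_id, "t", abs(e.r))
    for e in edges_n:
        upsert(e.sep_id, e.partner_id, "n", None)

    for u, v, d in g.edges(data=True):
        d["weight"] = d["corr_weight"] if d["corr_weight"] > 0 else 1.0
        del d["corr_weight"]

    for n in g.nodes:
        if n in sep_ids:
            g.nodes[n]["node_type"] = "sep"
            g.nodes[n]["go_terms"] = frozenset()
        else:
            g.nodes[n]["node_type"] = "protein"
            g.nodes[n]["go_terms"] = frozenset(annotations.get(n))
    return AnnotationNetwork(g)


def network_summary(net: AnnotationNetwork) -> dict:
    """Per-layer node/edge counts and the node-set Venn partition."""
    layer_nodes: dict[str, set[str]] = {"r": set(), "t": set(), "n": set()}
    layer_edges = {"r": 0, "t": 0, "n": 0}
    for u, v, d in net.graph.edges(data=True):
        for tag in d["provenance"]:
            layer_nodes[tag].update((u, v))
            layer_edges[tag] += 1
    R, T, N = layer_nodes["r"], layer_nodes["t"], layer_nodes["n"]
    venn = {
        "r_only": len(R - T - N),
        "t_only": len(T - R - N),
        "n_only": len(N - R - T),
        "rt_only": len((R & T) - N),
        "rn_only": len((R & N) - T),
        "tn_only": len((T & N) - R),
        "rtn": len(R & T & N),
    }
    total = len(R | T | N)
    assert sum(venn.values()) == total, "Venn partition does not conserve nodes"
    return {
        "nodes": {k: len(v) for k, v in layer_nodes.items()},
        "edges": layer_edges,
        "intersections": {
            "rt": len(R & T), "rn": len(R & N), "tn": len(T & N),
            "rtn": len(R & T & N),
        },
        "venn": venn,
        "total_nodes": total,
        "total_edges": net.graph.number_of_edges(),
        "n_seps": len(net.sep_nodes()),
        "n_proteins": len(net.protein_nodes()),
    }


# ---------------------------------------------------------------------------
# Edge-list serialisation
# ---------------------------------------------------------------------------

def write_correlation_edges(edges: Sequence[CorrelationEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tr\tp\tlevel\n")
        for e in sorted(edges, key=lambda e: (e.sep_id, e.partner_id)):
            fh.write(f"{e.sep_id}\t{e.partner_id}\t{e.r:.10g}\t{e.p:.10g}\t{e.level}\n")


def read_correlation_edges(path) -> list[CorrelationEdge]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [CorrelationEdge(row.node_a, row.node_b, float(row.r), float(row.p),
                            row.level) for row in df.itertuples()]


def write_colocation_pairs(pairs: Sequence[ColocationPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("sep_id\tpartner_id\ttranscript_id\n")
        for p in sorted(pairs, key=lambda p: (p.sep_id, p.partner_id)):
            fh.write(f"{p.sep_id}\t{p.partner_id}\t{p.transcript_id}\n")


def read_colocation_pairs(path) -> list[ColocationPair]:
    df = pd.read_csv(path, sep="\t")
    return [ColocationPair(row.sep_id, row.partner_id, row.transcript_id)
            for row in df.itertuples()]


def write_network(net: AnnotationNetwork, edge_path, node_path) -> None:
    with open(edge_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tprovenance\n")
        for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{d['weight']:.10g}\t{','.join(sorted(d['provenance']))}\n")
    with open(node_path, "w") as fh:
        fh.write("node_id\tnode_type\tn_go_terms\n")
        for n in sorted(net.graph.nodes):
            d = net.graph.nodes[n]
            fh.write(f"{n}\t{d['node_type']}\t{len(d.get('go_terms', ()))}\n")


def read_network(edge_path, node_path, annotations: GoAnnotationMap) -> AnnotationNetwork:
    g = nx.Graph()
    edges = pd.read_csv(edge_path, sep="\t")
    for row in edges.itertuples():
        g.add_edge(row.node_a, row.node_b, weight=float(row.weight),
                   provenance=frozenset(row.provenance.split(",")))
    nodes = pd.read_csv(node_path, sep="\t")
    for row in nodes.itertuples():
        if row.node_id not in g:
            g.add_node(row.node_id)
        g.nodes[row.node_id]["node_type"] = row.node_type
        g.nodes[row.node_id]["go_terms"] = (
            frozenset() if row.node_type == "sep"
            else frozenset(annotations.get(row.node_id))
        )
    return AnnotationNetwork(g)
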