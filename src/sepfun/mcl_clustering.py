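"""Markov clustering (MCL) over the annotation network.

MCL simulates random-walk flow on the graph: the column-stochastic
transition matrix is alternately expanded (matrix power, favouring flow
within dense regions) and inflated (elementwise power + column
renormalisation, sharpening strong flows and starving weak ones) until
the flow stabilises.  Clusters are read off the attractor structure of
the converged matrix.  Edge weights (|r| for co-expression, 1.0 for
co-location) feed the adjacency directly; self-loops stabilise the
iteration.

The module-based annotation method keeps only clusters with enough
GO-annotated members (default: at least 15, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .expression_networks import AnnotationNetwork

logger = logging.getLogger("sepfun")


@dataclass
class MclParams:
    """MCL tuning constants.

    ``inflation`` (default 1.8) controls cluster granularity — larger
    values fragment the graph more.  ``expansion`` is the matrix-power
    exponent.  Entries below ``prune_threshold`` are zeroed each round to
    keep the flow matrix sparse in spirit.  ``binarize`` ignores edge
    weights and clusters the topology alone.
    """

    inflation: float = 1.8
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    self_loop_weight: float = 1.0
    binarize: bool = False

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.prune_threshold < 0 or self.convergence_tol <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.self_loop_weight <= 0:
            raise ValueError("self_loop_weight must be positive")


@dataclass
class Module:
    """One MCL cluster with its GO-annotated member subset."""

    module_id: str
    members: set[str]
    annotated_members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty module")
        if not self.annotated_members <= self.members:
            raise ValueError("annotated_members must be a subset of members")


def _column_normalize(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_matrix(adjacency: np.ndarray, params: MclParams,
               on_iteration: Callable[[np.ndarray], None] | None = None) -> np.ndarray:
    """Run the expansion/inflation loop on a dense adjacency matrix.

    Self-loops are added before normalisation.  *on_iteration* receives
    the flow matrix right after each inflation/renormalisation step (used
    by tests to check column stochasticity).
    """
    m = adjacency.astype(float).copy()
    if params.binarize:
        m = (m > 0).astype(float)
    np.fill_diagonal(m, params.self_loop_weight)
    m = _column_normalize(m)
    for iteration in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = _column_normalize(np.power(m, params.inflation))
        if on_iteration is not None:
            on_iteration(m)
        m[m < params.prune_threshold] = 0.0
        m = _column_normalize(m)
        if np.max(np.abs(m - prev)) < params.convergence_tol:
            return m
    logger.warning("MCL did not converge in %d iterations; interpreting "
                   "current flow matrix", params.max_iterations)
    return m


def _clusters_from_flow(m: np.ndarray, eps: float = 1e-9) -> list[set[int]]:
    """Read clusters off a converged flow matrix.

    Attractors are nodes with residual self-flow; each attractor's row
    support is a cluster.  Attractor systems reachable from one another
    are merged; a non-attractor node appearing in several clusters is
    assigned where its incoming steady-state column mass is largest, ties
    going to the cluster with the smallest attractor index.
    """
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # degenerate (should not occur with self-loops)
        return [set(range(n))]
    supports = {a: set(np.nonzero(m[a] > eps)[0]) for a in attractors}

    # union attractors that occur in each other's supports
    parent = {a: a for a in attractors}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in attractors:
        for b in attractors:
            if b in supports[a]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)

    clusters: dict[int, set[int]] = {}
    for root, system in systems.items():
        clusters[root] = set().union(*(supports[a] for a in system))

    # resolve node overlaps by steady-state column mass toward each system
    node_home: dict[int, int] = {}
    for j in range(n):
        owners = [root for root, members in clusters.items() if j in members]
        if len(owners) <= 1:
            if owners:
                node_home[j] = owners[0]
            continue
        best = max(owners, key=lambda root: (sum(m[a, j] for a in systems[root]), -root))
        node_home[j] = best

    out: dict[int, set[int]] = {}
    for j, root in node_home.items():
        out.setdefault(root, set()).add(j)
    # nodes never appearing in any support become singletons
    assigned = set(node_home)
    for j in range(n):
        if j not in assigned:
            out.setdefault(-j - 1, set()).add(j)
    return [members for _, members in sorted(out.items())]


def mcl_cluster(net: AnnotationNetwork, params: MclParams | None = None,
                on_iteration: Callable[[np.ndarray], None] | None = None) -> list[Module]:
    """Cluster the annotation network into disjoint modules.

    The returned modules partition the node set and are sorted by size
    descending, ties broken by smallest member id.  Each module records
    which members carry GO annotations.
    """
    params = params or MclParams()
    nodes = sorted(net.graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    index = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for u, v, d in net.graph.edges(data=True):
        adj[index[u], index[v]] = adj[index[v], index[u]] = d.get("weight", 1.0)

    flow = mcl_matrix(adj, params, on_iteration=on_iteration)
    raw = _clusters_from_flow(flow)

    member_sets = [
        {nodes[i] for i in cluster} for cluster in raw
    ]
    member_sets.sort(key=lambda s: (-len(s), min(s)))
    modules = []
    for i, members in enumerate(member_sets, start=1):
        annotated = {n for n in members if net.go_terms(n)}
        modules.append(Module(module_id=f"M{i}", members=members,
                              annotated_members=annotated))
    return modules


def select_annotation_modules(modules: Sequence[Module],
                              min_annotated: int = 15) -> list[Module]:
    """Modules usable for annotation: >= *min_annotated* annotated members."""
    return [m for m in modules if len(m.annotated_members) >= min_annotated]


def write_modules(modules: Sequence[Module], path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tnode_id\n")
        for mod in modules:
            for node in sorted(mod.members):
                fh.write(f"{mod.module_id}\t{node}\n")


def read_modules(path, net: AnnotationNetwork) -> list[Module]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    grouped: dict[str, set[str]] = {}
    for row in df.itertuples():
        grouped.setdefault(row.module_id, set()).add(row.node_id)
    return [
        Module(module_id=mid, members=members,
               annotated_members={n for n in members if n in net.graph and net.go_terms(n)})
        for mid, members in sorted(grouped.items())
    ]
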