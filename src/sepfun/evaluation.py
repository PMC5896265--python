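"""Holdout validation of the annotation pipeline.

The protocol mirrors cross-validation on known proteins: a random 1% of
the annotated proteins in the network is held out, their GO annotations
stripped (edges are kept — only knowledge is removed), the module- and
hub-based annotation is rerun treating them as unknown nodes, and a
held-out protein counts as *detected* when it recovers at least one of
its true (stripped) BP terms at significance.  The experiment is
repeated (default three times) and additionally run on nested edge
layers — co-expression at the transcription level only (r), both
co-expression layers (rt), and everything including co-location (rtn) —
whose detected counts must be monotone non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_networks import AnnotationNetwork
from .formats_io import GoAnnotationMap
from .function_annotation import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_ANNOTATED_NEIGHBORS,
    annotate_seps,
    detect_hubs,
)
from .mcl_clustering import MclParams, mcl_cluster, select_annotation_modules

logger = logging.getLogger("sepfun")

LAYER_SETS: dict[str, frozenset] = {
    "r": frozenset({"r"}),
    "rt": frozenset({"r", "t"}),
    "rtn": frozenset({"r", "t", "n"}),
}


@dataclass
class HoldoutSpec:
    """Holdout design: fraction held out, repeats, RNG seed."""

    fraction: float = 0.01
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction < 1):
            raise ValueError("fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class RepeatResult:
    held_out: list[str]
    detected: list[str]
    per_method: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return len(self.detected)


@dataclass
class EvaluationResult:
    """Recovery of held-out annotations, overall and per network layer."""

    repeats: list[RepeatResult]
    layer_detected: dict[str, set[str]]  # layer -> unique detected ids

    @property
    def total_held_out(self) -> int:
        return sum(len(r.held_out) for r in self.repeats)

    @property
    def total_detected(self) -> int:
        return sum(r.n_detected for r in self.repeats)

    @property
    def detection_rate(self) -> float:
        if self.total_held_out == 0:
            return float("nan")
        return self.total_detected / self.total_held_out

    @property
    def layer_counts(self) -> dict[str, int]:
        return {layer: len(ids) for layer, ids in self.layer_detected.items()}


def _detect_on_network(net: AnnotationNetwork, annotations: GoAnnotationMap,
                       held_out: Sequence[str],
                       true_terms: dict[str, frozenset],
                       mcl_params: MclParams, min_annotated: int,
                       min_annotated_neighbors: int,
                       alpha: float) -> tuple[set[str], dict[str, set[str]]]:
    """Rerun annotation with *held_out* treated as unknown; return detected."""
    stripped_net = net.strip_annotations(held_out)
    stripped_map = annotations.without(held_out)
    if stripped_net.graph.number_of_nodes() == 0:
        return set(), {"module": set(), "hub": set()}
    modules = select_annotation_modules(
        mcl_cluster(stripped_net, mcl_params), min_annotated=min_annotated)
    hubs = detect_hubs(stripped_net, min_annotated_neighbors, targets=held_out)
    reports = annotate_seps(stripped_net, modules, hubs, stripped_map,
                            alpha=alpha, targets=held_out)
    detected: set[str] = set()
    per_method: dict[str, set[str]] = {"module": set(), "hub": set()}
    for rep in reports:
        recovered = rep.term_ids & true_terms[rep.sep_id]
        if recovered:
            detected.add(rep.sep_id)
            per_method[rep.method].add(rep.sep_id)
    return detected, per_method


def run_holdout(net: AnnotationNetwork, annotations: GoAnnotationMap,
                spec: HoldoutSpec | None = None,
                mcl_params: MclParams | None = None,
                min_annotated: int = 15,
                min_annotated_neighbors: int = DEFAULT_MIN_ANNOTATED_NEIGHBORS,
                alpha: float = DEFAULT_ALPHA) -> EvaluationResult:
    """Hold out annotated proteins, strip their GO sets, measure recovery.

    Each repeat samples ``floor(fraction * N)`` annotated protein nodes
    without replacement (seeded, reproducible).  Detection requires
    recovering at least one true stripped term.  Layer breakdowns rerun
    the same repeats on the r / rt / rtn edge-layer restrictions of the
    network; their unique detected sets are accumulated across repeats.
    """
    spec = spec or HoldoutSpec()
    mcl_params = mcl_params or MclParams()
    universe = sorted(
        n for n in net.protein_nodes() if net.go_terms(n)
    )
    sample_size = int(spec.fraction * len(universe))
    if sample_size < 1:
        raise ValueError(
            f"network has {len(universe)} annotated proteins; too few for "
            f"a {spec.fraction:.2%} holdout"
        )
    rng = np.random.default_rng(spec.seed)
    true_terms = {n: frozenset(net.go_terms(n)) for n in universe}

    layer_nets = {layer: net.restrict_layers(tags)
                  for layer, tags in LAYER_SETS.items()}

    repeats: list[RepeatResult] = []
    layer_detected: dict[str, set[str]] = {layer: set() for layer in LAYER_SETS}
    for _ in range(spec.n_repeats):
        held_out = sorted(rng.choice(universe, size=sample_size, replace=False))
        detected_full, per_method = _detect_on_network(
            net, annotations, held_out, true_terms, mcl_params,
            min_annotated, min_annotated_neighbors, alpha)
        repeats.append(RepeatResult(
            held_out=held_out, detected=sorted(detected_full),
            per_method={k: sorted(v) for k, v in per_method.items()},
        ))
        for layer, lnet in layer_nets.items():
            detected, _ = _detect_on_network(
                lnet, annotations, held_out, true_terms, mcl_params,
                min_annotated, min_annotated_neighbors, alpha)
            layer_detected[layer].update(detected)

    return EvaluationResult(repeats=repeats, layer_detected=layer_detected)


def layer_comparison(result: EvaluationResult) -> pd.DataFrame:
    """Detected counts across the nested r ⊆ rt ⊆ rtn layers.

    Adding edge layers can only add annotation contexts, so the counts
    must be monotone non-decreasing; a violation indicates an internal
    inconsistency and raises.
    """
    counts = [result.layer_counts[layer] for layer in ("r", "rt", "rtn")]
    if not (counts[0] <= counts[1] <= counts[2]):
        raise AssertionError(
            f"layer detection counts not monotone: r={counts[0]} "
            f"rt={counts[1]} rtn={counts[2]}"
        )
    return pd.DataFrame({"layer": ["r", "rt", "rtn"], "n_detected": counts})


def write_evaluation(result: EvaluationResult, path) -> None:
    rows = []
    for i, rep in enumerate(result.repeats, start=1):
        for node in rep.held_out:
            rows.append({
                "repeat": i, "protein_id": node,
                "detected": int(node in set(rep.detected)),
            })
    pd.DataFrame(rows, columns=["repeat", "protein_id", "detected"]).to_csv(
        path, sep="\t", index=False)
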