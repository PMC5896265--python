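import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from sepfun.expression_networks import (
    AnnotationNetwork,
    CorrelationEdge,
    EdgeFilterParams,
    ExpressionMatrix,
    ZeroVarianceError,
    build_coexpression_edges,
    merge_networks,
    network_summary,
    pearson_with_p,
)
from sepfun.formats_io import GoAnnotationMap
from sepfun.sep_identification import ColocationPair


def _matrix(values, level="translation", prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
                      columns=samples)
    return ExpressionMatrix(df, level)


# ---------------------------------------------------------------------------
# Pearson r with p-value
# ---------------------------------------------------------------------------

def _oracle_pearson(x, y):
    """Independent oracle: textbook covariance formula plus a two-sided
    p-value obtained by numerically integrating the Student-t density."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / math.sqrt(vx * vy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    df = n - 2
    t_obs = abs(r) * math.sqrt(df / (1 - r * r))

    def t_pdf(t):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + t * t / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(t_pdf, t_obs, np.inf)
    return r, min(1.0, 2 * tail)


def test_perfect_linearity_boundaries():
    assert pearson_with_p([1, 2, 3], [2, 4, 6]) == (1.0, 0.0)
    assert pearson_with_p([1, 2, 3], [3, 2, 1]) == (-1.0, 0.0)


def test_matches_formula_oracle_example():
    r, p = pearson_with_p([1, 2, 3, 4, 5], [1, 2, 3, 4, 6])
    ro, po = _oracle_pearson([1, 2, 3, 4, 5], [1, 2, 3, 4, 6])
    assert r == pytest.approx(ro, abs=1e-12)
    assert p == pytest.approx(po, abs=1e-10)


@pytest.mark.parametrize("n", [3, 5, 38])
def test_matches_formula_oracle_random_pairs(n):
    rng = np.random.default_rng(n)
    for _ in range(40):
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        r, p = pearson_with_p(x, y)
        ro, po = _oracle_pearson(x, y)
        assert abs(r - ro) < 1e-10 and abs(p - po) < 1e-10


def test_zero_variance_signals():
    with pytest.raises(ZeroVarianceError):
        pearson_with_p([1, 1, 1], [1, 2, 3])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=4, max_size=12),
       st.integers(0, 10 ** 6))
def test_symmetry_and_affine_invariance(xs, seed):
    rng = np.random.default_rng(seed)
    x = np.asarray(xs)
    y = rng.normal(size=len(x))
    if np.std(x) < 1e-6 or np.std(y) < 1e-6:
        return
    r_xy, p_xy = pearson_with_p(x, y)
    r_yx, p_yx = pearson_with_p(y, x)
    assert r_xy == pytest.approx(r_yx, abs=1e-12)
    assert p_xy == pytest.approx(p_yx, abs=1e-12)
    # positive-slope affine transform leaves r unchanged; negative flips sign
    r_pos, _ = pearson_with_p(2.5 * x + 3, y)
    r_neg, _ = pearson_with_p(-1.5 * x + 1, y)
    assert r_pos == pytest.approx(r_xy, abs=1e-9)
    assert r_neg == pytest.approx(-r_xy, abs=1e-9)


# ---------------------------------------------------------------------------
# edge filter
# ---------------------------------------------------------------------------

def test_identical_profiles_make_an_edge():
    base = np.linspace(1, 10, 5)
    edges = build_coexpression_edges(
        _matrix([base], prefix="sep"), _matrix([base, [1, 10, 2, 9, 3]], prefix="p"),
        "t")
    assert [(e.sep_id, e.partner_id) for e in edges] == [("sep0", "p0")]
    assert edges[0].r == 1.0 and edges[0].p == 0.0 and edges[0].level == "t"


def test_threshold_is_strict():
    rng = np.random.default_rng(5)
    x = rng.normal(size=10)
    y = 0.9 * x + 0.3 * rng.normal(size=10)
    shift = min(x.min(), y.min()) - 1
    sep_m = _matrix([x - shift], prefix="sep")
    part_m = _matrix([y - shift], prefix="p")
    (edge,) = build_coexpression_edges(sep_m, part_m, "r",
                                       EdgeFilterParams(min_abs_r=0.5, max_p=0.5))
    # with the threshold set exactly at the measured |r|, the strict
    # inequality must exclude the pair; nudged just below, it passes
    at = build_coexpression_edges(sep_m, part_m, "r",
                                  EdgeFilterParams(min_abs_r=abs(edge.r), max_p=0.5))
    below = build_coexpression_edges(sep_m, part_m, "r",
                                     EdgeFilterParams(min_abs_r=abs(edge.r) - 1e-12, max_p=0.5))
    assert at == [] and len(below) == 1


def test_sample_mismatch_is_a_hard_error():
    a = _matrix(np.ones((1, 3)) * [1, 2, 3], samples=["a", "b", "c"])
    b = _matrix(np.ones((1, 3)) * [1, 2, 3], samples=["a", "b", "d"])
    with pytest.raises(ValueError, match="sample columns"):
        build_coexpression_edges(a, b, "t")


def test_planted_pairs_recovered_exactly_against_brute_force():
    """10 SEPs x 100 partners, 5 planted correlated pairs at noise sd 0.01
    around a shared latent, n = 38: the filter recovers exactly the
    planted pairs, and the vectorised path agrees with per-pair calls."""
    rng = np.random.default_rng(8)
    n = 38
    latents = rng.normal(size=(5, n))
    seps = rng.normal(size=(10, n))
    partners = rng.normal(size=(100, n))
    planted = []
    for k in range(5):
        seps[k] = latents[k] + 0.01 * rng.normal(size=n)
        partners[10 + k] = latents[k] + 0.01 * rng.normal(size=n)
        planted.append((f"sep{k}", f"p{10 + k}"))
    shift = min(seps.min(), partners.min()) - 1.0  # affine: r-invariant
    sep_m = _matrix(seps - shift, prefix="sep")
    part_m = _matrix(partners - shift, prefix="p")
    edges = build_coexpression_edges(sep_m, part_m, "r")
    assert sorted((e.sep_id, e.partner_id) for e in edges) == sorted(planted)
    # brute-force all-pairs oracle with the scalar routine
    params = EdgeFilterParams()
    expected = set()
    for i, sid in enumerate(sep_m.feature_ids):
        for j, pid in enumerate(part_m.feature_ids):
            r, p = pearson_with_p(sep_m.values.iloc[i], part_m.values.iloc[j])
            if abs(r) > params.min_abs_r and p < params.max_p:
                expected.add((sid, pid))
    assert {(e.sep_id, e.partner_id) for e in edges} == expected


def test_null_pairs_essentially_never_pass():
    """Independent standard-normal pairs at n = 38 pass |r|>0.97 & p<0.01
    with probability far below 1e-4; 10^4 simulated pairs yield none."""
    rng = np.random.default_rng(12)
    n = 38
    a = rng.normal(size=(100, n))
    b = rng.normal(size=(100, n))
    from sepfun.expression_networks import _pairwise_pearson

    r, p, _, _ = _pairwise_pearson(a, b)  # 10^4 null pairs
    assert int(((np.abs(r) > 0.97) & (p < 0.01)).sum()) == 0


# ---------------------------------------------------------------------------
# merged network
# ---------------------------------------------------------------------------

GO = GoAnnotationMap(terms={"p1": {"GO:0000001"}, "p2": {"GO:0000002"}})


def test_merge_union_semantics():
    er = [CorrelationEdge("s1", "p1", 0.99, 1e-8, "r")]
    et = [CorrelationEdge("s1", "p1", -0.98, 1e-7, "t")]
    en = [ColocationPair("s1", "p2", "tx1")]
    net = merge_networks(er, et, en, GO, {"s1"})
    d = net.graph["s1"]["p1"]
    assert d["provenance"] == {"r", "t"}
    assert d["weight"] == pytest.approx(0.99)  # max |r| across layers
    d2 = net.graph["s1"]["p2"]
    assert d2["provenance"] == {"n"} and d2["weight"] == 1.0
    assert net.graph.nodes["s1"]["node_type"] == "sep"
    assert net.graph.nodes["p1"]["go_terms"] == {"GO:0000001"}


def test_merge_is_idempotent_and_order_independent():
    er = [CorrelationEdge("s1", "p1", 0.99, 1e-8, "r"),
          CorrelationEdge("s1", "p2", 0.98, 1e-6, "r")]
    et = [CorrelationEdge("s1", "p1", 0.985, 1e-7, "t")]
    en = [ColocationPair("s1", "p2", "tx1")]
    a = merge_networks(er, et, en, GO, {"s1"})
    b = merge_networks(list(reversed(er)), et, en, GO, {"s1"})
    c = merge_networks(er + er, et + et, en + en, GO, {"s1"})
    for other in (b, c):
        assert set(a.graph.edges) == set(other.graph.edges)
        for u, v in a.graph.edges:
            assert a.graph[u][v] == other.graph[u][v]


def test_merge_counts_disjoint_edge_sets():
    er = [CorrelationEdge(f"s{i}", f"a{i}", 0.99, 1e-8, "r") for i in range(3)]
    et = [CorrelationEdge(f"s{i}", f"b{i}", 0.99, 1e-8, "t") for i in range(4)]
    en = [ColocationPair(f"s{i}", f"c{i}", f"tx{i}") for i in range(5)]
    net = merge_networks(er, et, en, GoAnnotationMap(terms={"x": {"GO:0000009"}}),
                         {f"s{i}" for i in range(5)})
    assert net.graph.number_of_edges() == 12


def test_network_summary_venn_conservation():
    er = [CorrelationEdge("s1", "p1", 0.99, 1e-8, "r")]
    et = [CorrelationEdge("s1", "p1", 0.98, 1e-7, "t"),
          CorrelationEdge("s2", "p2", 0.98, 1e-7, "t")]
    en = [ColocationPair("s3", "p3", "tx")]
    net = merge_networks(er, et, en, GO, {"s1", "s2", "s3"})
    s = network_summary(net)
    assert s["nodes"] == {"r": 2, "t": 4, "n": 2}
    assert s["intersections"]["rt"] == 2 and s["intersections"]["rtn"] == 0
    assert sum(s["venn"].values()) == s["total_nodes"] == 6
    # n-only network: r and t counts zero
    only_n = merge_networks([], [], en, GO, {"s3"})
    sn = network_summary(only_n)
    assert sn["nodes"]["r"] == 0 and sn["nodes"]["t"] == 0 and sn["nodes"]["n"] == 2


def test_restrict_layers_intersection_semantics():
    er = [CorrelationEdge("s1", "p1", 0.99, 1e-8, "r")]
    et = [CorrelationEdge("s1", "p1", 0.98, 1e-7, "t"),
          CorrelationEdge("s1", "p2", 0.98, 1e-7, "t")]
    net = merge_networks(er, et, [], GO, {"s1"})
    r_only = net.restrict_layers({"r"})
    # the shared edge keeps its place in the single-layer network
    assert set(r_only.graph.edges) == {("s1", "p1")}
    assert r_only.graph["s1"]["p1"]["provenance"] == {"r"}
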