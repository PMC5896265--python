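import networkx as nx
import pytest

from sepfun.expression_networks import AnnotationNetwork
from sepfun.pipeline import PipelineConfig, run_pipeline
from sepfun.synthetic_fixtures import benchmark_config, simulate


def toy_network(edges, annotations=None, sep_ids=()):
    """Build an AnnotationNetwork from (u, v[, weight[, provenance]]) tuples."""
    annotations = annotations or {}
    g = nx.Graph()
    for edge in edges:
        u, v = edge[0], edge[1]
        weight = edge[2] if len(edge) > 2 else 1.0
        prov = frozenset(edge[3]) if len(edge) > 3 else frozenset({"n"})
        g.add_edge(u, v, weight=weight, provenance=prov)
    for n in g.nodes:
        g.nodes[n]["node_type"] = "sep" if n in sep_ids else "protein"
        g.nodes[n]["go_terms"] = frozenset(annotations.get(n, ()))
    return AnnotationNetwork(g)


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """The default synthetic benchmark: 10 planted modules of 20 proteins
    + 2 SEPs, 1000 background proteins, 38 samples; full pipeline run."""
    root = tmp_path_factory.mktemp("benchmark")
    files, truth = simulate(benchmark_config(seed=7), root / "fixtures")
    config = PipelineConfig(
        transcripts=files.transcripts, orfs=files.orfs, peptides=files.peptides,
        sep_translation=files.sep_translation,
        protein_transcription=files.protein_transcription,
        protein_translation=files.protein_translation,
        go=files.go, out_dir=root / "out", seed=7,
    )
    result = run_pipeline(config)
    return files, truth, result
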