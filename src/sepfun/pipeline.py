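"""End-to-end orchestration: identify -> coexpress -> colocate -> network
-> cluster -> annotate -> evaluate, with one config and deterministic
seeding.

Each stage writes its artifact plus an entry in ``run_summary.json``
(counts, parameters used).  Rerunning with unchanged inputs and seed
reproduces byte-identical outputs: all floating-point output is written
with fixed precision and all collections are emitted in sorted order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import formats_io
from .evaluation import HoldoutSpec, layer_comparison, run_holdout, write_evaluation
from .expression_networks import (
    EdgeFilterParams,
    build_coexpression_edges,
    merge_networks,
    network_summary,
    write_colocation_pairs,
    write_correlation_edges,
    write_network,
)
from .function_annotation import annotate_seps, detect_hubs, functional_seps
from .mcl_clustering import MclParams, mcl_cluster, select_annotation_modules, write_modules
from .sep_identification import (
    SMORF_MAX_CODONS,
    colocation_pairs,
    filter_smorfs,
    identify_authentic_seps,
)

logger = logging.getLogger("sepfun")

#: Offsets fanned out from the top-level seed so each stage that draws
#: random numbers is independently reproducible.
HOLDOUT_SEED_OFFSET = 101


@dataclass
class PipelineConfig:
    """Input paths and parameters for a full run."""

    transcripts: Path
    orfs: Path
    peptides: Path
    sep_translation: Path
    protein_transcription: Path
    protein_translation: Path
    go: Path
    out_dir: Path
    transcript_format: str | None = None
    min_codons_excluded: int = SMORF_MAX_CODONS
    frame_check: bool = True
    edge_filter: EdgeFilterParams = field(default_factory=EdgeFilterParams)
    mcl: MclParams = field(default_factory=MclParams)
    min_annotated: int = 15
    min_annotated_neighbors: int = 5
    alpha: float = 0.05
    holdout: HoldoutSpec = field(default_factory=HoldoutSpec)
    run_evaluation: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("transcripts", "orfs", "peptides", "sep_translation",
                     "protein_transcription", "protein_translation", "go",
                     "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        self.holdout.seed = self.seed + HOLDOUT_SEED_OFFSET

    def validate(self) -> None:
        missing = [name for name in ("transcripts", "orfs", "peptides",
                                     "sep_translation", "protein_transcription",
                                     "protein_translation", "go")
                   if not getattr(self, name).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "edge_filter" in raw and isinstance(raw["edge_filter"], dict):
            raw["edge_filter"] = EdgeFilterParams(**raw["edge_filter"])
        if "mcl" in raw and isinstance(raw["mcl"], dict):
            raw["mcl"] = MclParams(**raw["mcl"])
        if "holdout" in raw and isinstance(raw["holdout"], dict):
            raw["holdout"] = HoldoutSpec(**raw["holdout"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    seps: list
    network: object
    modules: list
    selected_modules: list
    hubs: list
    reports: list
    summary: dict
    evaluation: object | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in dependency order, writing artifacts to out_dir."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "seed": config.seed,
        "min_codons_excluded": config.min_codons_excluded,
        "frame_check": config.frame_check,
        "min_abs_r": config.edge_filter.min_abs_r,
        "max_p": config.edge_filter.max_p,
        "inflation": config.mcl.inflation,
        "min_annotated": config.min_annotated,
        "min_annotated_neighbors": config.min_annotated_neighbors,
        "alpha": config.alpha,
    }, "stages": {}}
    # wall times go to a separate file so run_summary.json (like every
    # other artifact) is byte-identical across reruns of the same seed
    timings: dict = {}

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            timings[name] = round(time.perf_counter() - t0, 3)
            summary["stages"][name] = dict(counts)
        return done

    # --- identify ------------------------------------------------------
    done = stage("identify")
    transcripts = formats_io.read_transcripts(config.transcripts,
                                              config.transcript_format)
    orfs = formats_io.read_orf_calls(config.orfs)
    peptides = formats_io.read_peptide_matches(config.peptides)
    smorfs = filter_smorfs(orfs, config.min_codons_excluded)
    proteins = [o for o in orfs if o.codon_length >= config.min_codons_excluded]
    seps = identify_authentic_seps(smorfs, peptides, transcripts,
                                   frame_check=config.frame_check)
    _write_seps(seps, out / "seps.tsv")
    done(n_orfs=len(orfs), n_smorfs=len(smorfs), n_peptides=len(peptides),
         n_authentic_seps=len(seps))

    # --- colocate ------------------------------------------------------
    done = stage("colocate")
    pairs = colocation_pairs(seps, transcripts, proteins)
    write_colocation_pairs(pairs, out / "edges_n.tsv")
    done(n_colocation_pairs=len(pairs))

    # --- coexpress -----------------------------------------------------
    done = stage("coexpress")
    sep_tl = formats_io.read_expression_matrix(config.sep_translation, "translation")
    sep_tl = sep_tl.subset([s.sep_id for s in seps])
    prot_tx = formats_io.read_expression_matrix(config.protein_transcription,
                                                "transcription")
    prot_tl = formats_io.read_expression_matrix(config.protein_translation,
                                                "translation")
    edges_r = build_coexpression_edges(sep_tl, prot_tx, "r", config.edge_filter)
    edges_t = build_coexpression_edges(sep_tl, prot_tl, "t", config.edge_filter)
    write_correlation_edges(edges_r, out / "edges_r.tsv")
    write_correlation_edges(edges_t, out / "edges_t.tsv")
    done(n_edges_r=len(edges_r), n_edges_t=len(edges_t))

    # --- network -------------------------------------------------------
    done = stage("network")
    annotations = formats_io.read_go_annotations(config.go)
    net = merge_networks(edges_r, edges_t, pairs, annotations,
                         sep_ids={s.sep_id for s in seps})
    write_network(net, out / "network_edges.tsv", out / "network_nodes.tsv")
    net_stats = network_summary(net)
    done(**net_stats)

    # --- cluster -------------------------------------------------------
    done = stage("cluster")
    modules = mcl_cluster(net, config.mcl)
    selected = select_annotation_modules(modules, config.min_annotated)
    write_modules(modules, out / "modules.tsv")
    done(n_modules=len(modules), n_selected_modules=len(selected))

    # --- annotate ------------------------------------------------------
    done = stage("annotate")
    hubs = detect_hubs(net, config.min_annotated_neighbors)
    reports = annotate_seps(net, selected, hubs, annotations, alpha=config.alpha)
    formats_io.write_annotation_report(reports, out / "annotation_report.tsv")
    n_functional = len(functional_seps(reports))
    done(n_hubs=len(hubs), n_reports=len(reports), n_functional_seps=n_functional)

    # --- evaluate ------------------------------------------------------
    evaluation = None
    if config.run_evaluation:
        done = stage("evaluate")
        evaluation = run_holdout(
            net, annotations, config.holdout, mcl_params=config.mcl,
            min_annotated=config.min_annotated,
            min_annotated_neighbors=config.min_annotated_neighbors,
            alpha=config.alpha)
        write_evaluation(evaluation, out / "evaluation.tsv")
        layers = layer_comparison(evaluation)
        layers.to_csv(out / "layer_comparison.tsv", sep="\t", index=False)
        done(total_held_out=evaluation.total_held_out,
             total_detected=evaluation.total_detected,
             detection_rate=round(evaluation.detection_rate, 6),
             layer_counts=evaluation.layer_counts)

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1, sort_keys=True)

    return PipelineResult(seps=seps, network=net, modules=modules,
                          selected_modules=selected, hubs=hubs,
                          reports=reports, summary=summary,
                          evaluation=evaluation)


def _write_seps(seps, path) -> None:
    with open(path, "w") as fh:
        fh.write("sep_id\ttranscript_id\ttx_start\ttx_end\tcodon_length\t"
                 "classification\tms_supported\tn_peptides\n")
        for s in sorted(seps, key=lambda s: s.sep_id):
            fh.write("\t".join(map(str, [
                s.sep_id, s.orf.transcript_id, s.orf.tx_start, s.orf.tx_end,
                s.orf.codon_length, s.classification, int(s.ms_supported),
                len(s.supporting_peptides),
            ])) + "\n")
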