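"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the annotation method
relies on: transcripts carrying uORFs, MS peptide evidence for a subset
of smORFs plus intergenic decoys, and dual-level TPM matrices in which
planted modules of proteins (and the SEPs that regulate them) share a
latent expression profile.  Correlations are planted in log space — each
module m draws a latent standard-normal sample profile L_m, every member
profile is L_m plus per-sample Gaussian noise, and TPM is obtained by
exponentiating and normalising each sample to a fixed library size —
which preserves Pearson structure at low noise while keeping TPM
non-negative.  With ``noise_sd <= 0.05`` and 38 samples, within-module
pairs exceed the |r| > 0.97 filter with probability > 0.99.

Two structural knobs create the nested network layers the evaluation
compares: a fraction of module proteins is correlated only at the
translation level (their transcription profile is independent noise, so
they enter network_t but not network_r), and a few SEPs are hosted on
otherwise-background transcripts whose main protein is reachable only
through the co-location layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io
from .formats_io import GenomicInterval, GoAnnotationMap, TranscriptModel
from .sep_identification import OrfCall, PeptideMatch, make_sep_id

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
LIBRARY_SIZE = 1_000_000.0

# transcript geometry (transcript-space coordinates, nt)
_EXON1, _GAP, _EXON2 = 400, 100, 450      # two exons, 850 nt spliced length
_TX_SPACING = 1200                         # genomic span reserved per transcript
_CDS_START, _CDS_END = 300, 750            # main ORF: 149 codons + stop
_UORF_START, _UORF_END = 30, 180           # uORF smORF: 49 codons + stop
_PEPTIDE_CODON_OFFSET = 3                  # supported peptides start at codon 3
_PEPTIDE_LEN = 9


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic benchmark.

    Defaults mirror the design scale of the method's published
    evaluation: 38 samples, planted co-expression modules tight enough
    that within-module pairs pass the |r| > 0.97 filter.
    """

    n_transcripts: int = 1205
    n_samples: int = 38
    n_modules: int = 10
    module_size: int = 20
    n_seps: int = 20
    sep_ms_fraction: float = 1.0
    noise_sd: float = 0.05
    decoy_peptides: int = 10
    terms_per_module: int = 2
    background_terms: int = 20
    seed: int = 0
    tx_uncorrelated_fraction: float = 0.1
    n_colocation_only: int = 5

    def __post_init__(self) -> None:
        if min(self.n_transcripts, self.n_samples, self.n_modules,
               self.module_size, self.n_seps, self.terms_per_module) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.sep_ms_fraction <= 1 and 0 <= self.tx_uncorrelated_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        needed = self.n_modules * self.module_size + self.n_colocation_only
        if self.n_transcripts < needed:
            raise ValueError(
                f"n_transcripts={self.n_transcripts} cannot host "
                f"{self.n_modules}x{self.module_size} module proteins plus "
                f"{self.n_colocation_only} co-location-only hosts"
            )
        if self.n_seps < self.n_colocation_only:
            raise ValueError("n_seps must cover the co-location-only hosts")
        per_module_slots = self.module_size * self.n_modules
        if self.n_seps - self.n_colocation_only > per_module_slots:
            raise ValueError("more SEPs than module host transcripts")


@dataclass
class GroundTruth:
    """Everything the tests need to verify each stage exactly."""

    module_proteins: dict[str, list[str]]
    module_seps: dict[str, list[str]]
    module_terms: dict[str, list[str]]
    sep_module: dict[str, str]
    ms_supported_sep_ids: list[str]
    decoy_sources: list[str]
    colocation_pairs: list[list[str]]
    colocation_only_hosts: list[str]
    tx_uncorrelated_proteins: list[str]
    background_proteins: list[str]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    # -- analytic expectations ------------------------------------------

    def network_modules(self) -> list[str]:
        """Modules that materialise in the network (>= 1 supported SEP)."""
        supported = set(self.ms_supported_sep_ids)
        return sorted(m for m, seps in self.module_seps.items()
                      if supported & set(seps))

    def expected_network_proteins(self) -> set[str]:
        """Annotated proteins expected to appear in the merged network."""
        live = set(self.network_modules())
        out: set[str] = set()
        for m in live:
            out.update(self.module_proteins[m])
        supported = set(self.ms_supported_sep_ids)
        for sep, host in self.colocation_pairs:
            if host in self.colocation_only_hosts and sep in supported:
                if self.sep_module[sep] in live:
                    out.add(host)
        return out

    def expected_detection_rate(self, min_annotated: int = 15) -> float:
        """Analytic holdout expectation from generator redundancy.

        A held-out module protein is recoverable when its module survives
        in the network and still has >= *min_annotated* annotated
        co-members after stripping; a pendant co-location host joins its
        SEP's cluster and is recoverable under the same module condition.
        """
        detectable = 0
        universe = self.expected_network_proteins()
        for m in self.network_modules():
            members = [p for p in self.module_proteins[m] if p in universe]
            hosts = [h for h in self.colocation_only_hosts
                     if h in universe and any(
                         s in self.module_seps[m] for s, hh in self.colocation_pairs
                         if hh == h)]
            annotated_in_module = len(members) + len(hosts)
            if annotated_in_module - 1 >= min_annotated:
                detectable += annotated_in_module
        if not universe:
            return float("nan")
        return detectable / len(universe)


@dataclass
class SimFiles:
    """Paths of every emitted pipeline input."""

    transcripts: Path
    orfs: Path
    peptides: Path
    sep_translation: Path
    protein_transcription: Path
    protein_translation: Path
    go: Path
    ground_truth: Path


def _build_transcript(i: int) -> TranscriptModel:
    g = i * _TX_SPACING
    strand = "+" if i % 2 == 0 else "-"
    exons = [
        GenomicInterval("chr1", g, g + _EXON1, strand),
        GenomicInterval("chr1", g + _EXON1 + _GAP, g + _EXON1 + _GAP + _EXON2, strand),
    ]
    return TranscriptModel(
        transcript_id=f"tx{i:05d}", gene_id=f"prot{i:05d}", exons=exons,
        cds_start=_CDS_START, cds_end=_CDS_END,
    )


def _main_orf(t: TranscriptModel) -> OrfCall:
    span = _CDS_END - _CDS_START
    return OrfCall(
        orf_id=t.gene_id, transcript_id=t.transcript_id,
        tx_start=_CDS_START, tx_end=_CDS_END,
        genomic_blocks=t.tx_to_genomic_blocks(_CDS_START, _CDS_END),
        codon_length=span // 3 - 1,
    )


def _uorf(t: TranscriptModel) -> OrfCall:
    span = _UORF_END - _UORF_START
    sep_id = make_sep_id(t.transcript_id, _UORF_START, _UORF_END)
    return OrfCall(
        orf_id=sep_id, transcript_id=t.transcript_id,
        tx_start=_UORF_START, tx_end=_UORF_END,
        genomic_blocks=t.tx_to_genomic_blocks(_UORF_START, _UORF_END),
        codon_length=span // 3 - 1,
    )


def _tpm(log_profiles: np.ndarray) -> np.ndarray:
    raw = np.exp(log_profiles)
    return raw / raw.sum(axis=0, keepdims=True) * LIBRARY_SIZE


def simulate(config: SimConfig, out_dir: str | Path) -> tuple[SimFiles, GroundTruth]:
    """Generate all pipeline inputs plus ground truth under *out_dir*.

    Deterministic for a fixed config (byte-identical files on re-run).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    c = config

    transcripts = [_build_transcript(i) for i in range(c.n_transcripts)]
    n_module_prot = c.n_modules * c.module_size
    module_ids = [f"mod{m:02d}" for m in range(c.n_modules)]
    protein_ids = [t.gene_id for t in transcripts]

    module_proteins = {
        module_ids[m]: protein_ids[m * c.module_size:(m + 1) * c.module_size]
        for m in range(c.n_modules)
    }
    host_base = n_module_prot
    colocation_hosts = protein_ids[host_base:host_base + c.n_colocation_only]
    background = protein_ids[host_base + c.n_colocation_only:]

    # --- SEP placement: uORFs on module transcripts, plus co-location-only
    # hosts on otherwise-background transcripts -------------------------
    sep_orfs: list[OrfCall] = []
    sep_module: dict[str, str] = {}
    module_seps: dict[str, list[str]] = {m: [] for m in module_ids}
    n_regular = c.n_seps - c.n_colocation_only
    for j in range(n_regular):
        m = j % c.n_modules
        slot = j // c.n_modules
        t = transcripts[m * c.module_size + slot]
        orf = _uorf(t)
        sep_orfs.append(orf)
        sep_module[orf.orf_id] = module_ids[m]
        module_seps[module_ids[m]].append(orf.orf_id)
    # co-location-only SEPs fill modules from the top so SEP counts stay
    # even across modules at the default configuration
    for k in range(c.n_colocation_only):
        m = c.n_modules - 1 - (k % c.n_modules)
        t = transcripts[host_base + k]
        orf = _uorf(t)
        sep_orfs.append(orf)
        sep_module[orf.orf_id] = module_ids[m]
        module_seps[module_ids[m]].append(orf.orf_id)

    main_orfs = [_main_orf(t) for t in transcripts]
    all_orfs = main_orfs + sep_orfs

    # --- MS support: stratified per module so support is spread evenly -
    supported: list[str] = []
    for m in module_ids:
        seps = module_seps[m]
        n_keep = int(round(c.sep_ms_fraction * len(seps)))
        keep = sorted(rng.choice(len(seps), size=n_keep, replace=False))
        supported.extend(seps[i] for i in keep)
    supported = sorted(supported)

    tx_by_id = {t.transcript_id: t for t in transcripts}
    peptides: list[PeptideMatch] = []
    for sep_id in supported:
        orf = next(o for o in sep_orfs if o.orf_id == sep_id)
        t = tx_by_id[orf.transcript_id]
        p0 = orf.tx_start + 3 * _PEPTIDE_CODON_OFFSET
        blocks = t.tx_to_genomic_blocks(p0, p0 + 3 * _PEPTIDE_LEN)
        seq = "".join(rng.choice(AA_ALPHABET, size=_PEPTIDE_LEN))
        peptides.append(PeptideMatch(peptide=seq, genomic_blocks=blocks,
                                     source_id=f"ms_{sep_id}"))

    decoy_sources = []
    for d in range(c.decoy_peptides):
        i = d % c.n_transcripts
        gap_start = i * _TX_SPACING + _EXON1 + _GAP + _EXON2 + 10
        block = GenomicInterval("chr1", gap_start, gap_start + 3 * _PEPTIDE_LEN, "+")
        seq = "".join(rng.choice(AA_ALPHABET, size=_PEPTIDE_LEN))
        sid = f"decoy_{d:03d}"
        peptides.append(PeptideMatch(peptide=seq, genomic_blocks=[block],
                                     source_id=sid))
        decoy_sources.append(sid)

    # --- expression: module latents in log space -----------------------
    latents = rng.standard_normal((c.n_modules, c.n_samples))
    sample_ids = [f"S{s + 1:02d}" for s in range(c.n_samples)]

    n_uncorr = int(math.floor(c.tx_uncorrelated_fraction * c.module_size))
    tx_uncorrelated: list[str] = []
    prot_tx = np.empty((c.n_transcripts, c.n_samples))
    prot_tl = np.empty((c.n_transcripts, c.n_samples))
    for i, pid in enumerate(protein_ids):
        if i < n_module_prot:
            m = i // c.module_size
            within = i % c.module_size
            noise = rng.standard_normal(c.n_samples) * c.noise_sd
            prot_tl[i] = latents[m] + noise
            if within >= c.module_size - n_uncorr:
                tx_uncorrelated.append(pid)
                prot_tx[i] = rng.standard_normal(c.n_samples)
            else:
                prot_tx[i] = latents[m] + rng.standard_normal(c.n_samples) * c.noise_sd
        else:
            prot_tx[i] = rng.standard_normal(c.n_samples)
            prot_tl[i] = rng.standard_normal(c.n_samples)

    sep_ids_all = [o.orf_id for o in sep_orfs]
    sep_tl = np.empty((len(sep_orfs), c.n_samples))
    for i, orf in enumerate(sep_orfs):
        m = module_ids.index(sep_module[orf.orf_id])
        sep_tl[i] = latents[m] + rng.standard_normal(c.n_samples) * c.noise_sd

    # SEPs and proteins are quantified from the same Ribo-seq library, so
    # the translation-level TPM normalisation shares one per-sample
    # denominator across both feature sets (normalising the handful of SEP
    # rows by their own sum would inject a large shared sample effect)
    tl_joint = _tpm(np.vstack([prot_tl, sep_tl]))
    prot_tx_df = pd.DataFrame(_tpm(prot_tx), index=protein_ids, columns=sample_ids)
    prot_tl_df = pd.DataFrame(tl_joint[:c.n_transcripts], index=protein_ids,
                              columns=sample_ids)
    sep_tl_df = pd.DataFrame(tl_joint[c.n_transcripts:], index=sep_ids_all,
                             columns=sample_ids)

    # --- GO annotations ------------------------------------------------
    term_counter = 1
    module_terms: dict[str, list[str]] = {}
    go_terms: dict[str, set[str]] = {}
    for m in module_ids:
        terms = [f"GO:{term_counter + j:07d}" for j in range(c.terms_per_module)]
        term_counter += c.terms_per_module
        module_terms[m] = terms
        for pid in module_proteins[m]:
            go_terms.setdefault(pid, set()).update(terms)
    bg_terms = [f"GO:{term_counter + j:07d}" for j in range(c.background_terms)]
    for pid in background:
        go_terms.setdefault(pid, set()).add(str(rng.choice(bg_terms)))
    # co-location-only hosts carry their SEP's module's first term so the
    # co-location layer contributes recoverable annotations
    colocation_pairs_gt: list[list[str]] = []
    for orf in sep_orfs:
        host = f"prot{int(orf.transcript_id[2:]):05d}"
        colocation_pairs_gt.append([orf.orf_id, host])
        if host in colocation_hosts:
            go_terms.setdefault(host, set()).add(module_terms[sep_module[orf.orf_id]][0])

    annotations = GoAnnotationMap(terms=go_terms)

    # --- emit ----------------------------------------------------------
    files = SimFiles(
        transcripts=out_dir / "transcripts.bed",
        orfs=out_dir / "orfs.tsv",
        peptides=out_dir / "peptides.tsv",
        sep_translation=out_dir / "sep_translation.tsv",
        protein_transcription=out_dir / "protein_transcription.tsv",
        protein_translation=out_dir / "protein_translation.tsv",
        go=out_dir / "go.tsv",
        ground_truth=out_dir / "ground_truth.json",
    )
    formats_io.write_bed12(transcripts, files.transcripts)
    formats_io.write_orf_calls(all_orfs, files.orfs)
    formats_io.write_peptide_matches(peptides, files.peptides)
    sep_tl_df.to_csv(files.sep_translation, sep="\t", index_label="feature_id")
    prot_tx_df.to_csv(files.protein_transcription, sep="\t", index_label="feature_id")
    prot_tl_df.to_csv(files.protein_translation, sep="\t", index_label="feature_id")
    formats_io.write_go_annotations(annotations, files.go)

    truth = GroundTruth(
        module_proteins=module_proteins,
        module_seps=module_seps,
        module_terms=module_terms,
        sep_module=sep_module,
        ms_supported_sep_ids=supported,
        decoy_sources=decoy_sources,
        colocation_pairs=sorted(colocation_pairs_gt),
        colocation_only_hosts=colocation_hosts,
        tx_uncorrelated_proteins=sorted(tx_uncorrelated),
        background_proteins=background,
        config=asdict(config),
    )
    truth.to_json(files.ground_truth)
    return files, truth


def benchmark_config(seed: int = 0) -> SimConfig:
    """The default end-to-end benchmark: 10 modules x (20 proteins + 2
    SEPs), 1000 background proteins, 38 samples, log-space noise 0.05."""
    return SimConfig(seed=seed)
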