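"""Readers and writers for every external representation the pipeline touches.

Transcript models arrive as Ensembl-dialect GTF or BED12; ORF calls and
peptide-to-genome matches as documented TSV tables; expression as TPM
matrices (features x samples, tab separated); GO biological-process
annotations as a flat two-column TSV or GAF 2.x; annotation results as a
sorted report TSV.

Every genomic coordinate in this package is 0-based half-open (BED
convention); GTF input is converted on read.  Transcript-space coordinates
are 0-based half-open measured 5'->3' along the spliced transcript.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("sepfun")

GO_TERM_RE = re.compile(r"^GO:\d{7}$")

#: Minimum number of expression samples required for co-expression analysis.
MIN_SAMPLES = 3


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered exons plus the optional main ORF.

    ``cds_start``/``cds_end`` are transcript-space coordinates of the
    canonical coding sequence; ``None`` for transcripts without an
    annotated main ORF.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons mix chromosomes or strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: cds_start/cds_end must be set together")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    # -- coordinate mapping -------------------------------------------------

    def _tx_ordered_exons(self) -> list[GenomicInterval]:
        """Exons in 5'->3' transcript order (reversed genomic order on '-')."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic base position to its transcript-space offset."""
        offset = 0
        for exon in self._tx_ordered_exons():
            if exon.start <= pos < exon.end:
                if self.strand == "+":
                    return offset + (pos - exon.start)
                return offset + (exon.end - 1 - pos)
            offset += len(exon)
        raise ValueError(f"{self.transcript_id}: genomic position {pos} not exonic")

    def tx_to_genomic_blocks(self, tx_start: int, tx_end: int) -> list[GenomicInterval]:
        """Project a transcript-space interval onto genomic blocks.

        Returned blocks are sorted by genomic start; their total length is
        ``tx_end - tx_start``.
        """
        if not (0 <= tx_start < tx_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: [{tx_start}, {tx_end}) outside transcript of length {self.length}"
            )
        blocks: list[GenomicInterval] = []
        offset = 0
        for exon in self._tx_ordered_exons():
            lo = max(tx_start, offset)
            hi = min(tx_end, offset + len(exon))
            if lo < hi:
                if self.strand == "+":
                    g0 = exon.start + (lo - offset)
                    g1 = exon.start + (hi - offset)
                else:
                    g1 = exon.end - (lo - offset)
                    g0 = exon.end - (hi - offset)
                blocks.append(GenomicInterval(self.chrom, g0, g1, self.strand))
            offset += len(exon)
        return sorted(blocks, key=lambda b: b.start)


@dataclass
class GoAnnotationMap:
    """Gene/protein identifier -> set of GO biological-process terms."""

    terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, ts in self.terms.items():
            if not ts:
                raise ValueError(f"{gene}: empty GO term set")
            for t in ts:
                if not GO_TERM_RE.match(t):
                    raise ValueError(f"{gene}: malformed GO term {t!r}")

    def get(self, gene: str) -> set[str]:
        return self.terms.get(gene, set())

    def annotated(self, ids: Iterable[str]) -> set[str]:
        """Subset of *ids* that carry at least one BP term."""
        return {i for i in ids if self.terms.get(i)}

    def without(self, stripped: Iterable[str]) -> "GoAnnotationMap":
        """Copy with all annotations of *stripped* removed."""
        drop = set(stripped)
        return GoAnnotationMap(
            terms={g: set(ts) for g, ts in self.terms.items() if g not in drop},
            term_names=dict(self.term_names),
        )


# ---------------------------------------------------------------------------
# Transcript models: GTF / BED12
# ---------------------------------------------------------------------------

def read_transcripts(path: str | Path, format: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from GTF or BED12.

    The dialect is taken from *format* ({'gtf', 'bed12'}) or inferred from
    the file suffix.  Transcripts whose exons mix strands are dropped with
    a warning; otherwise malformed lines raise :class:`FormatError` naming
    the offending line.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed12"
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown transcript format {format!r}")


def _read_gtf(path: Path) -> list[TranscriptModel]:
    import gffutils

    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated GTF fields")

    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, force=True,
        merge_strategy="create_unique", keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    genes: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise FormatError(f"{path}: {feat.featuretype} feature without transcript_id")
        genes.setdefault(tid, feat.attributes.get("gene_id", [tid])[0])
        # GTF is 1-based inclusive; convert to 0-based half-open.
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start - 1, feat.end, feat.strand))

    models: list[TranscriptModel] = []
    for tid in sorted(exons):
        parts = exons[tid]
        if len({strand for _, _, strand in parts}) > 1:
            logger.warning("%s: transcript %s mixes strands; skipped", path, tid)
            continue
        strand = parts[0][2]
        chrom = next(f.seqid for f in db.all_features() if
                     f.attributes.get("transcript_id", [None])[0] == tid)
        ivals = [GenomicInterval(chrom, s, e, strand) for s, e, _ in parts]
        model = TranscriptModel(tid, genes[tid], ivals)
        if tid in cds:
            g_positions = [p for s, e, _ in cds[tid] for p in (s, e - 1)]
            tx = sorted(model.genomic_to_tx(p) for p in g_positions)
            model.cds_start, model.cds_end = tx[0], tx[-1] + 1
        models.append(model)
    return models


def _read_bed12(path: Path) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 BED12 fields, got {len(fields)}")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: line {lineno}: blockCount disagrees with block lists")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
            model = TranscriptModel(name, name, exons)
            if thick_end > thick_start:
                ends = sorted((model.genomic_to_tx(thick_start),
                               model.genomic_to_tx(thick_end - 1)))
                model.cds_start, model.cds_end = ends[0], ends[1] + 1
            if model.exons[0].start != start or model.exons[-1].end != end:
                raise FormatError(f"{path}: line {lineno}: blocks do not span chromStart..chromEnd")
            models.append(model)
    return models


def write_bed12(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12 (thickStart/thickEnd carry the CDS)."""
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.exons[0].start, t.exons[-1].end
            if t.cds_start is not None:
                cds_blocks = t.tx_to_genomic_blocks(t.cds_start, t.cds_end)
                thick_start, thick_end = cds_blocks[0].start, cds_blocks[-1].end
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(len(e)) for e in t.exons)
            offs = ",".join(str(e.start - start) for e in t.exons)
            fh.write("\t".join(map(str, [
                t.exons[0].chrom, start, end, t.transcript_id, 0, t.strand,
                thick_start, thick_end, 0, len(t.exons), sizes, offs,
            ])) + "\n")


# ---------------------------------------------------------------------------
# ORF calls and peptide matches (documented TSV tables)
# ---------------------------------------------------------------------------

ORF_COLUMNS = ["orf_id", "transcript_id", "tx_start", "tx_end", "codon_length",
               "chrom", "strand", "blocks"]
PEPTIDE_COLUMNS = ["peptide", "chrom", "strand", "blocks", "source_id"]


def _format_blocks(blocks: Sequence[GenomicInterval]) -> str:
    return ",".join(f"{b.start}-{b.end}" for b in blocks)


def _parse_blocks(text: str, chrom: str, strand: str) -> list[GenomicInterval]:
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return out


def read_orf_calls(path: str | Path) -> list:
    """Read Ribo-seq ORF calls from the documented TSV layout."""
    from .sep_identification import OrfCall

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ORF_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing ORF columns {sorted(missing)}")
    return [
        OrfCall(
            orf_id=row.orf_id,
            transcript_id=row.transcript_id,
            tx_start=int(row.tx_start),
            tx_end=int(row.tx_end),
            codon_length=int(row.codon_length),
            genomic_blocks=_parse_blocks(row.blocks, row.chrom, row.strand),
        )
        for row in df.itertuples()
    ]


def write_orf_calls(orfs: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ORF_COLUMNS) + "\n")
        for o in orfs:
            fh.write("\t".join(map(str, [
                o.orf_id, o.transcript_id, o.tx_start, o.tx_end, o.codon_length,
                o.genomic_blocks[0].chrom, o.genomic_blocks[0].strand,
                _format_blocks(o.genomic_blocks),
            ])) + "\n")


def read_peptide_matches(path: str | Path) -> list:
    """Read MS peptide-to-genome matches from the documented TSV layout."""
    from .sep_identification import PeptideMatch

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing peptide columns {sorted(missing)}")
    return [
        PeptideMatch(
            peptide=row.peptide,
            genomic_blocks=_parse_blocks(row.blocks, row.chrom, row.strand),
            source_id=row.source_id,
        )
        for row in df.itertuples()
    ]


def write_peptide_matches(peptides: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEPTIDE_COLUMNS) + "\n")
        for p in peptides:
            fh.write("\t".join([
                p.peptide, p.genomic_blocks[0].chrom, p.genomic_blocks[0].strand,
                _format_blocks(p.genomic_blocks), p.source_id,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, level: str):
    """Read a TPM matrix (first column feature ids, header sample ids).

    Enforces the experimental-design contract that co-expression analysis
    needs at least three samples, and that TPM values are finite and
    non-negative.
    """
    from .expression_networks import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < MIN_SAMPLES:
        raise FormatError(
            f"{path}: only {df.shape[1]} samples; three or more samples are "
            "required for expression profiling"
        )
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate feature ids {dupes}")
    values = df.to_numpy(dtype=float)
    if not (values >= 0).all() or not math.isfinite(values.sum()):
        raise FormatError(f"{path}: TPM values must be finite and non-negative")
    return ExpressionMatrix(values=df, level=level)


def write_expression_matrix(matrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def read_go_annotations(path: str | Path) -> GoAnnotationMap:
    """Read gene -> GO BP annotations from a two-column TSV or GAF 2.x.

    GAF input keeps only aspect "P" rows (this pipeline annotates the
    biological-process aspect only); the number of dropped rows is logged.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x row
                gene, term, aspect = fields[2], fields[4], fields[8]
                if aspect != "P":
                    dropped += 1
                    continue
            elif len(fields) == 2:
                gene, term = fields
            else:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2-column TSV or GAF 2.x row"
                )
            if not GO_TERM_RE.match(term):
                raise FormatError(f"{path}: line {lineno}: malformed GO term {term!r}")
            terms.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("%s: dropped %d non-BP GAF rows", path, dropped)
    if not terms:
        raise FormatError(f"{path}: no biological-process annotations found")
    return GoAnnotationMap(terms=terms)


def write_go_annotations(annotations: GoAnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations.terms):
            for term in sorted(annotations.terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Annotation reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["sep_id", "method", "context_id", "term_id", "term_name",
                  "k", "K", "n", "N", "p", "p_adj"]


def write_annotation_report(reports: Sequence, path: str | Path) -> None:
    """Write SEP function reports as a TSV sorted by (sep_id, p_adj).

    The layout round-trips exactly through :func:`read_annotation_report`.
    """
    rows = []
    for rep in reports:
        for res in rep.terms:
            rows.append({
                "sep_id": rep.sep_id, "method": rep.method,
                "context_id": rep.context_id, "term_id": res.term_id,
                "term_name": res.term_name, "k": res.k, "K": res.K,
                "n": res.n, "N": res.N, "p": res.p, "p_adj": res.p_adj,
            })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(["sep_id", "p_adj", "term_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_annotation_report(path: str | Path) -> list:
    from .function_annotation import EnrichmentResult, SepFunctionReport

    df = pd.read_csv(path, sep="\t", dtype={"term_name": str},
                     float_precision="round_trip")
    reports: dict[tuple, SepFunctionReport] = {}
    for row in df.itertuples():
        key = (row.sep_id, row.method, row.context_id)
        rep = reports.get(key)
        if rep is None:
            rep = reports[key] = SepFunctionReport(
                sep_id=row.sep_id, method=row.method,
                context_id=row.context_id, terms=[],
            )
        rep.terms.append(EnrichmentResult(
            term_id=row.term_id,
            term_name="" if pd.isna(row.term_name) else str(row.term_name),
            k=int(row.k), K=int(row.K), n=int(row.n), N=int(row.N),
            p=float(row.p), p_adj=float(row.p_adj),
        ))
    return list(reports.values())
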