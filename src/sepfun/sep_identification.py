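"""Authentic-SEP calling: size filter, Ribo-seq x MS intersection, classing.

A smORF (small open reading frame, < 100 codons) called from ribosome
profiling counts as an authentic SEP only when at least one MS peptide
supports it: every base of the peptide's genomic mapping lies inside the
ORF's genomic blocks, the strands agree, and the peptide starts in-frame
with the ORF in transcript space.  Frame agreement can be relaxed to pure
containment with ``frame_check=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .formats_io import GenomicInterval, TranscriptModel

logger = logging.getLogger("sepfun")

#: ORFs strictly below this codon count (stop codon excluded) are smORFs.
SMORF_MAX_CODONS = 100


@dataclass
class OrfCall:
    """One translated ORF called from Ribo-seq, in transcript coordinates.

    ``tx_start``/``tx_end`` include the stop codon; ``codon_length``
    excludes it.
    """

    orf_id: str
    transcript_id: str
    tx_start: int
    tx_end: int
    genomic_blocks: list[GenomicInterval]
    codon_length: int

    def __post_init__(self) -> None:
        span = self.tx_end - self.tx_start
        if span % 3:
            raise ValueError(f"{self.orf_id}: ORF span {span} not divisible by 3")
        if self.codon_length != span // 3 - 1:
            raise ValueError(
                f"{self.orf_id}: codon_length {self.codon_length} inconsistent with span {span}"
            )
        if sum(len(b) for b in self.genomic_blocks) != span:
            raise ValueError(f"{self.orf_id}: genomic blocks do not sum to ORF span")

    @property
    def strand(self) -> str:
        return self.genomic_blocks[0].strand

    @property
    def chrom(self) -> str:
        return self.genomic_blocks[0].chrom


@dataclass
class PeptideMatch:
    """One MS peptide with its best genomic location."""

    peptide: str
    genomic_blocks: list[GenomicInterval]
    source_id: str

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("empty peptide")
        total = sum(len(b) for b in self.genomic_blocks)
        if total != 3 * len(self.peptide):
            raise ValueError(
                f"{self.source_id}: genomic length {total} != 3 x peptide length {len(self.peptide)}"
            )


@dataclass
class SepRecord:
    """An authentic smORF-encoded peptide: MS-supported smORF."""

    sep_id: str
    orf: OrfCall
    ms_supported: bool
    classification: str = "standalone"
    peptide_sequence: str = ""
    supporting_peptides: list[str] = field(default_factory=list)


def filter_smorfs(orfs: Sequence[OrfCall],
                  max_codons_excluded: int = SMORF_MAX_CODONS) -> list[OrfCall]:
    """Keep ORFs shorter than *max_codons_excluded* codons (stop excluded)."""
    return [o for o in orfs if o.codon_length < max_codons_excluded]


def _peptide_tx_interval(peptide: PeptideMatch,
                         transcript: TranscriptModel) -> tuple[int, int] | None:
    """Transcript-space interval of a peptide, or None if it does not map
    contiguously onto the transcript."""
    try:
        tx = []
        for block in peptide.genomic_blocks:
            tx.append(transcript.genomic_to_tx(block.start))
            tx.append(transcript.genomic_to_tx(block.end - 1))
    except ValueError:
        return None
    lo, hi = min(tx), max(tx) + 1
    if hi - lo != 3 * len(peptide.peptide):
        return None
    return lo, hi


def peptide_supports_orf(peptide: PeptideMatch, orf: OrfCall,
                         transcript: TranscriptModel,
                         frame_check: bool = True) -> bool:
    """True if the peptide's genomic mapping supports the ORF.

    Support = strand match, full base-level containment of the peptide's
    blocks in the ORF's blocks, and (optionally) an in-frame start relative
    to the ORF start in transcript space.
    """
    if peptide.genomic_blocks[0].strand != orf.strand:
        return False
    if peptide.genomic_blocks[0].chrom != orf.chrom:
        return False
    orf_blocks = sorted(orf.genomic_blocks, key=lambda b: b.start)
    for pb in peptide.genomic_blocks:
        if not _contained_in_union(pb, orf_blocks):
            return False
    if not frame_check:
        return True
    tx = _peptide_tx_interval(peptide, transcript)
    if tx is None:
        return False
    return (tx[0] - orf.tx_start) % 3 == 0


def _contained_in_union(block: GenomicInterval,
                        sorted_blocks: list[GenomicInterval]) -> bool:
    pos = block.start
    for ob in sorted_blocks:
        if ob.end <= pos:
            continue
        if ob.start > pos:
            return False
        pos = min(block.end, ob.end)
        if pos >= block.end:
            return True
    return pos >= block.end


def make_sep_id(transcript_id: str, tx_start: int, tx_end: int) -> str:
    """Stable SEP identifier, e.g. ``ENST00000347364.3_182_326``.

    Coordinates are 0-based half-open transcript positions.
    """
    return f"{transcript_id}_{tx_start}_{tx_end}"


def identify_authentic_seps(smorfs: Sequence[OrfCall],
                            peptides: Sequence[PeptideMatch],
                            transcripts: Sequence[TranscriptModel],
                            frame_check: bool = True) -> list[SepRecord]:
    """Intersect Ribo-seq smORF calls with MS peptide matches.

    A smORF is emitted iff at least one peptide supports it; the emitted
    :class:`SepRecord` is classified against the transcript's main ORF.
    One peptide may support several smORFs.
    """
    tx_by_id = {t.transcript_id: t for t in transcripts}
    known_chroms = {t.chrom for t in transcripts}

    # interval index over ORF blocks for candidate lookup
    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, orf in enumerate(smorfs):
        key = (orf.chrom, orf.strand)
        tree = trees.setdefault(key, IntervalTree())
        for block in orf.genomic_blocks:
            tree.addi(block.start, block.end, idx)

    support: dict[int, list[PeptideMatch]] = {}
    for pep in peptides:
        chrom = pep.genomic_blocks[0].chrom
        if chrom not in known_chroms:
            logger.warning("peptide %s on unknown chromosome %s; skipped",
                           pep.source_id, chrom)
            continue
        key = (chrom, pep.genomic_blocks[0].strand)
        tree = trees.get(key)
        if tree is None:
            continue
        candidates = {iv.data for block in pep.genomic_blocks
                      for iv in tree.overlap(block.start, block.end)}
        for idx in sorted(candidates):
            orf = smorfs[idx]
            transcript = tx_by_id.get(orf.transcript_id)
            if transcript is None:
                raise KeyError(f"{orf.orf_id}: unknown transcript {orf.transcript_id}")
            if peptide_supports_orf(pep, orf, transcript, frame_check=frame_check):
                support.setdefault(idx, []).append(pep)

    records = []
    for idx, orf in enumerate(smorfs):
        peps = support.get(idx)
        if not peps:
            continue
        rec = SepRecord(
            sep_id=make_sep_id(orf.transcript_id, orf.tx_start, orf.tx_end),
            orf=orf,
            ms_supported=True,
            peptide_sequence=peps[0].peptide,
            supporting_peptides=[p.source_id for p in peps],
        )
        rec.classification = classify_sep(rec, tx_by_id[orf.transcript_id])
        records.append(rec)
    return records


def classify_sep(sep: SepRecord, transcript: TranscriptModel) -> str:
    """Place a SEP relative to the transcript's main ORF.

    uORF: entirely 5' of the CDS; dORF: entirely 3'; internal: overlapping
    the CDS; standalone: the transcript has no annotated main ORF.
    """
    if transcript.cds_start is None:
        return "standalone"
    if sep.orf.tx_end <= transcript.cds_start:
        return "uORF"
    if sep.orf.tx_start >= transcript.cds_end:
        return "dORF"
    return "internal"


@dataclass(frozen=True)
class ColocationPair:
    """A SEP / protein ORF pair encoded on the same RNA."""

    sep_id: str
    partner_id: str
    transcript_id: str


def colocation_pairs(seps: Sequence[SepRecord],
                     transcripts: Sequence[TranscriptModel],
                     proteins: Sequence[OrfCall]) -> list[ColocationPair]:
    """All deduplicated (SEP, protein) pairs sharing a transcript."""
    proteins_by_tx: dict[str, list[OrfCall]] = {}
    for p in proteins:
        proteins_by_tx.setdefault(p.transcript_id, []).append(p)
    seen: set[tuple[str, str]] = set()
    pairs: list[ColocationPair] = []
    for sep in seps:
        for partner in proteins_by_tx.get(sep.orf.transcript_id, []):
            if partner.orf_id == sep.sep_id:
                continue
            key = (sep.sep_id, partner.orf_id)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(ColocationPair(sep.sep_id, partner.orf_id,
                                        sep.orf.transcript_id))
    return pairs
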