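import numpy as np
import pytest

from sepfun.formats_io import GenomicInterval, TranscriptModel
from sepfun.sep_identification import (
    ColocationPair,
    OrfCall,
    PeptideMatch,
    SepRecord,
    classify_sep,
    colocation_pairs,
    filter_smorfs,
    identify_authentic_seps,
    make_sep_id,
)
from sepfun.synthetic_fixtures import SimConfig, simulate
from sepfun import formats_io


def _orf(transcript: TranscriptModel, tx_start: int, tx_end: int, orf_id="orf"):
    return OrfCall(
        orf_id=orf_id, transcript_id=transcript.transcript_id,
        tx_start=tx_start, tx_end=tx_end,
        genomic_blocks=transcript.tx_to_genomic_blocks(tx_start, tx_end),
        codon_length=(tx_end - tx_start) // 3 - 1,
    )


def _peptide(transcript: TranscriptModel, tx_start: int, n_aa: int, source="pep"):
    return PeptideMatch(
        peptide="A" * n_aa,
        genomic_blocks=transcript.tx_to_genomic_blocks(tx_start, tx_start + 3 * n_aa),
        source_id=source,
    )


@pytest.fixture
def single_exon_tx():
    return TranscriptModel("tx1", "g1", [GenomicInterval("chr1", 0, 1000, "+")],
                           cds_start=100, cds_end=400)


# ---------------------------------------------------------------------------
# smORF size filter
# ---------------------------------------------------------------------------

def test_smorf_filter_boundary(single_exon_tx):
    at_99 = _orf(single_exon_tx, 0, 300, "short")    # 99 codons, kept
    at_100 = _orf(single_exon_tx, 0, 303, "long")    # 100 codons, removed
    assert filter_smorfs([at_99, at_100]) == [at_99]
    assert filter_smorfs([]) == []


def test_smorf_filter_preserves_order(single_exon_tx):
    orfs = [_orf(single_exon_tx, 3 * i, 3 * i + 30, f"o{i}") for i in range(5)]
    assert filter_smorfs(orfs) == orfs


# ---------------------------------------------------------------------------
# Ribo-seq x MS intersection
# ---------------------------------------------------------------------------

def test_in_frame_contained_peptide_yields_one_sep(single_exon_tx):
    smorf = _orf(single_exon_tx, 30, 63)
    pep = _peptide(single_exon_tx, 36, 9)  # codon 2 of the smORF, in frame
    records = identify_authentic_seps([smorf], [pep], [single_exon_tx])
    assert len(records) == 1
    rec = records[0]
    assert rec.ms_supported and rec.sep_id == "tx1_30_63"


def test_out_of_frame_peptide_is_rejected(single_exon_tx):
    smorf = _orf(single_exon_tx, 30, 63)
    pep = _peptide(single_exon_tx, 37, 8)  # shifted 1 nt: out of frame
    assert identify_authentic_seps([smorf], [pep], [single_exon_tx]) == []
    # containment-only mode accepts it
    relaxed = identify_authentic_seps([smorf], [pep], [single_exon_tx],
                                      frame_check=False)
    assert len(relaxed) == 1


def test_peptide_escaping_orf_is_rejected(single_exon_tx):
    smorf = _orf(single_exon_tx, 30, 63)
    pep = _peptide(single_exon_tx, 57, 9)  # in frame but runs past tx_end
    assert identify_authentic_seps([smorf], [pep], [single_exon_tx]) == []


def test_unknown_chromosome_peptide_is_skipped(single_exon_tx):
    smorf = _orf(single_exon_tx, 30, 63)
    stray = PeptideMatch("AAA", [GenomicInterval("chrUn", 0, 9, "+")], "stray")
    assert identify_authentic_seps([smorf], [stray], [single_exon_tx]) == []


def test_sep_id_format(single_exon_tx):
    assert make_sep_id("ENST00000347364.3", 182, 326) == "ENST00000347364.3_182_326"


def _brute_force_identify(smorfs, peptides, transcripts, frame_check=True):
    """O(n*m) oracle: explicit per-base containment and frame via position
    lists built by walking exons one base at a time."""
    tx_by_id = {t.transcript_id: t for t in transcripts}
    order = {}
    for t in transcripts:
        exons = t.exons if t.strand == "+" else list(reversed(t.exons))
        positions = []
        for e in exons:
            rng = range(e.start, e.end) if t.strand == "+" else range(e.end - 1, e.start - 1, -1)
            positions.extend((e.chrom, p) for p in rng)
        order[t.transcript_id] = positions

    pep_bases_all = [
        {(b.chrom, b.strand, p) for b in pep.genomic_blocks
         for p in range(b.start, b.end)}
        for pep in peptides
    ]
    supported = set()
    for i, orf in enumerate(smorfs):
        orf_bases = {(b.chrom, b.strand, p) for b in orf.genomic_blocks
                     for p in range(b.start, b.end)}
        t = tx_by_id[orf.transcript_id]
        for pep, pep_bases in zip(peptides, pep_bases_all):
            if not pep_bases <= orf_bases:
                continue
            if frame_check:
                tx_positions = sorted(
                    order[orf.transcript_id].index((b.chrom, p))
                    for b in pep.genomic_blocks for p in range(b.start, b.end)
                )
                if tx_positions != list(range(tx_positions[0], tx_positions[0] + len(tx_positions))):
                    continue
                if (tx_positions[0] - orf.tx_start) % 3 != 0:
                    continue
            supported.add(i)
    return sorted(supported)


def test_planted_fixture_matches_ground_truth_and_brute_force(tmp_path):
    config = SimConfig(n_transcripts=25, n_modules=2, module_size=10,
                       n_seps=10, sep_ms_fraction=0.7, n_colocation_only=2,
                       decoy_peptides=5, seed=3)
    files, truth = simulate(config, tmp_path)
    transcripts = formats_io.read_transcripts(files.transcripts, "bed12")
    orfs = formats_io.read_orf_calls(files.orfs)
    peptides = formats_io.read_peptide_matches(files.peptides)
    smorfs = filter_smorfs(orfs)
    records = identify_authentic_seps(smorfs, peptides, transcripts)
    assert sorted(r.sep_id for r in records) == truth.ms_supported_sep_ids
    # all emitted SEPs honour the contract
    assert all(r.ms_supported and r.orf.codon_length < 100 for r in records)
    # decoys never support anything
    decoys = set(truth.decoy_sources)
    assert all(not (set(r.supporting_peptides) & decoys) for r in records)
    # equality with the brute-force all-pairs oracle
    oracle_idx = _brute_force_identify(smorfs, peptides, transcripts)
    assert sorted(r.sep_id for r in records) == sorted(
        make_sep_id(smorfs[i].transcript_id, smorfs[i].tx_start, smorfs[i].tx_end)
        for i in oracle_idx)


def test_identify_equals_brute_force_on_random_spliced_instances():
    """Randomised two-exon transcripts on both strands: interval-arithmetic
    support must agree with the per-base oracle, in- and out-of-frame."""
    rng = np.random.default_rng(42)
    transcripts, smorfs, peptides = [], [], []
    for i in range(40):
        g = i * 2000
        strand = "+" if rng.random() < 0.5 else "-"
        t = TranscriptModel(f"tx{i}", f"g{i}", [
            GenomicInterval("chr1", g, g + 350, strand),
            GenomicInterval("chr1", g + 500, g + 800, strand),
        ])
        transcripts.append(t)
        start = int(rng.integers(0, 100)) * 3
        smorfs.append(_orf(t, start, start + 150, f"orf{i}"))
        # random peptides: some inside, some straddling, random frames
        for j in range(3):
            p0 = int(rng.integers(0, 200))
            n_aa = int(rng.integers(3, 12))
            if p0 + 3 * n_aa <= t.length:
                peptides.append(_peptide(t, p0, n_aa, f"p{i}_{j}"))
    got = identify_authentic_seps(smorfs, peptides, transcripts)
    oracle = _brute_force_identify(smorfs, peptides, transcripts)
    assert sorted(r.orf.orf_id for r in got) == sorted(smorfs[i].orf_id for i in oracle)
    # subset invariant
    assert {r.orf.orf_id for r in got} <= {o.orf_id for o in smorfs}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tx_start,tx_end,expected", [
    (10, 40, "uORF"),        # entirely 5' of CDS [100, 400)
    (400, 430, "dORF"),      # starts at cds_end
    (150, 210, "internal"),  # inside the CDS
    (90, 120, "internal"),   # straddles the CDS start
])
def test_classify_against_main_orf(single_exon_tx, tx_start, tx_end, expected):
    rec = SepRecord("s", _orf(single_exon_tx, tx_start, tx_end), True)
    assert classify_sep(rec, single_exon_tx) == expected


def test_classify_without_main_orf_is_standalone():
    t = TranscriptModel("tx1", "g1", [GenomicInterval("chr1", 0, 1000, "+")])
    rec = SepRecord("s", _orf(t, 10, 40), True)
    assert classify_sep(rec, t) == "standalone"


# ---------------------------------------------------------------------------
# co-location pairs
# ---------------------------------------------------------------------------

def test_colocation_cartesian_product(single_exon_tx):
    tx2 = TranscriptModel("tx2", "g2", [GenomicInterval("chr1", 2000, 3000, "+")],
                          cds_start=100, cds_end=400)
    seps = [SepRecord("s1", _orf(single_exon_tx, 0, 30), True),
            SepRecord("s2", _orf(single_exon_tx, 30, 60), True)]
    prots = [_orf(single_exon_tx, 100, 400, "pA"),
             _orf(single_exon_tx, 400, 700, "pB"),
             _orf(tx2, 100, 400, "pC")]
    pairs = colocation_pairs(seps, [single_exon_tx, tx2], prots)
    assert len(pairs) == 4  # 2 SEPs x 2 same-RNA proteins; pC unrelated
    assert {(p.sep_id, p.partner_id) for p in pairs} == {
        ("s1", "pA"), ("s1", "pB"), ("s2", "pA"), ("s2", "pB")}
    # no pairs when proteins live on other transcripts
    assert colocation_pairs(seps, [single_exon_tx, tx2], [prots[2]]) == []
    # deduplication
    again = colocation_pairs(seps, [single_exon_tx, tx2], prots + prots[:1])
    assert len(again) == 4
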