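# Methods

## Problem and approach

Small open reading frames (smORFs, < 100 codons) were historically
excluded from genome annotation by the 100-codon cutoff, yet many encode
peptides (SEPs) with real regulatory, membrane-transport or antimicrobial
roles. Because SEPs rarely contain recognisable protein domains,
domain-based function prediction does not apply; `sepfun` instead uses
guilt-by-association on a relation network built from expression data.

The pipeline has three parts:

1. **Authentic-SEP identification.** Ribo-seq ORF calls are filtered to
   smORFs (`codon_length < 100`, stop codon excluded) and intersected
   with MS peptide-to-genome matches. A smORF is accepted as an authentic
   SEP when at least one peptide (a) maps with every base inside the
   ORF's genomic blocks, (b) on the same strand, and (c) starts in-frame
   with the ORF in transcript coordinates. Intersection alone would be
   satisfied by any overlapping peptide; frame agreement is the
   biologically defensible reading of proteogenomic support, and a
   containment-only mode remains available (`frame_check=False`).
2. **Relation network.** Two co-expression layers are computed by Pearson
   correlation between SEP translation-level TPM profiles and partner
   protein profiles: layer `r` against protein *transcription* and layer
   `t` against protein *translation*. A pair becomes an edge when
   |r| > 0.97 **and** p < 0.01, both strict. The p-value is the two-sided
   tail of Student's t with n − 2 degrees of freedom at
   t = r·√((n−2)/(1−r²)); no multiple-testing correction is applied to
   edges because at n = 38 the |r| threshold dominates by many orders of
   magnitude (the null probability of passing both filters is ≪ 1e−6;
   the package asserts a zero pass count over 1e5 simulated null pairs).
   Layer `n` contains co-location edges: SEP/protein pairs encoded on the
   same RNA, weight 1. The merged undirected network keeps one edge per
   node pair with provenance = union of contributing layers and weight =
   max |r| (1.0 for pure co-location).
3. **Function transfer.** Markov clustering (inflation 1.8) partitions
   the network into modules; modules with ≥ 15 GO-annotated members are
   annotation contexts (module method). Independently, every SEP with
   ≥ 5 annotated immediate coding-gene neighbours is a hub whose
   neighbourhood is a context (hub method). Within a context, each GO
   biological-process term observed there is tested for over-representation
   with the one-sided hypergeometric (Fisher exact upper-tail) test
   against the background of all annotated protein nodes in the network,
   Benjamini–Hochberg adjusted within the context; terms with adjusted
   p < 0.05 are assigned to the SEP.

## Markov clustering

An in-house dense implementation: the weighted adjacency (|r| for
co-expression edges, 1.0 for co-location; no rescaling) gains unit
self-loops, is column-normalised and iterated with expansion (matrix
square) and inflation (elementwise power 1.8 followed by column
renormalisation), pruning entries < 1e−5 and renormalising each round,
until the flow matrix changes by < 1e−6 or 100 iterations elapse
(non-convergence interprets the current matrix with a warning rather
than failing). Clusters are attractor-row supports; attractor systems
reachable from one another are merged, and a node appearing in several
supports is assigned to the cluster receiving the largest share of its
steady-state column mass, ties to the smallest attractor index — MCL
permits overlapping cluster systems, but annotation needs a partition.
Modules are emitted sorted by size (ties by smallest member id), so the
procedure is fully deterministic. Clustering runs on the weighted
network by default; `MclParams(binarize=True)` clusters topology alone.

## Holdout evaluation

`run_holdout` samples ⌊fraction·N⌋ (default 1%) of the annotated protein
nodes in the network, without replacement, in each of 3 repeats (seeded
RNG; identical seeds give identical samples). Sampled proteins keep
their edges — only their GO annotations are stripped, from the network
and the annotation map — and the module/hub annotation is rerun with
them as targets. A protein counts as *detected* when it recovers at
least one of its true stripped BP terms at significance; this
at-least-one criterion is the weakest literal reading of "functions
reproduced" and is the documented contract. The same repeats are rerun
on nested edge-layer restrictions r ⊆ rt ⊆ rtn. An edge belongs to a
layer set when its provenance intersects it: a pair found by both
co-expression filters is present in each single-layer network, which is
what makes the layers genuinely nested; detected counts must then be
monotone non-decreasing, and `layer_comparison` raises on a violation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_codons_excluded` | 100 | smORF cutoff, codons excluding the stop |
| `min_abs_r` | 0.97 | strict lower bound on \|Pearson r\| for an edge |
| `max_p` | 0.01 | strict upper bound on the correlation p-value |
| `inflation` | 1.8 | MCL granularity; larger fragments more |
| `min_annotated` | 15 | annotated members needed for a module context |
| `min_annotated_neighbors` | 5 | annotated coding neighbours for a hub |
| `alpha` | 0.05 | BH-adjusted significance for term assignment |
| `fraction` / `n_repeats` | 0.01 / 3 | holdout design |

The enrichment significance level is a package default — there is no
canonical cutoff for guilt-by-association term assignment, so α = 0.05
after BH is stated explicitly here for reproducibility. The
background universe is the set of annotated protein nodes in the merged
network — the universe the network method can see — not the whole
genome; it is overridable in `annotate_seps`.

## Synthetic benchmark

The generator plants every structure the pipeline is meant to find and
exposes the ground truth. Expression is modelled in log space: module
*m* draws a latent profile L_m with independent standard-normal entries
over the samples; each member feature is L_m + ε with per-sample
Gaussian noise (sd 0.05 by default; 38 samples). TPM is obtained by
exponentiating and normalising each sample to a fixed library of 1e6 —
log-space planting preserves the Pearson structure at low noise while
keeping TPM non-negative. SEP and protein translation profiles share
one per-sample denominator, mirroring joint quantification from a
single Ribo-seq library; normalising the handful of SEP rows by their
own column sums would inject a large shared sample effect and destroy
the planted correlations. At the default noise, planted within-module
correlations sit near 0.996 with sampling sd ~1e−3, comfortably above
the 0.97 threshold (test-asserted).

Geometry: each transcript has two exons (850 nt spliced), alternating
strands, a main ORF of 149 codons and, on SEP-hosting transcripts, a
49-codon uORF. Supported smORFs get an in-frame 9-aa peptide starting
at codon 3; decoy peptides are placed in intergenic gaps guaranteed
disjoint from every ORF block, so false-attribution tests are exact.
Two structural knobs create the nested layers the evaluation compares:
10% of each module's proteins are correlated only at the translation
level (independent transcription profile → t-only edges), and a few
SEPs sit on otherwise-background host transcripts whose main protein is
reachable only through the co-location edge, carrying the module's
first term. GO labels: every module protein carries its module's
`terms_per_module` terms; background proteins each draw one of the
`background_terms` pool.

The default configuration — 10 modules × (20 proteins + 2 SEPs), 1000
background proteins, 38 samples — is the benchmark the acceptance
script and end-to-end tests run; it executes in a few seconds on one
CPU, which is why the full suite can rerun it freely.

**Analytic holdout expectation.** Annotated proteins appear in the
network only via planted structure, so the expected detection rate is
computed from the ground truth: a held-out module protein is
recoverable when its module survives (≥ 1 MS-supported SEP) and retains
≥ 15 annotated co-members after stripping; a pendant co-location host is
recoverable under the same condition because a degree-1 node always
joins its neighbour's MCL cluster. At the default configuration the
expectation is 100%, and the measured rate matches within the tests'
5-point band.

**What passing does not show.** The generator emulates the statistical
skeleton, not real data: no read-level noise, no isoform ambiguity, no
MS identification error (decoys are placed, not searched), block-latent
expression rather than empirical TPM distributions, and a flat GO
vocabulary without the ontology DAG. Recovery rates here bound what the
method can do when its assumptions hold exactly; they say nothing about
miscalibrated Ribo-seq ORF calls or spectra mismatches.

## Numerical and convention choices

- All genomic coordinates are 0-based half-open (BED convention); GTF is
  converted on read. Transcript-space coordinates are 0-based half-open,
  5'→3'. SEP identifiers are `transcript_tx-start_tx-end` with 0-based
  transcript coordinates (the convention is documented rather than
  inferred from upstream identifier examples, which do not state their
  base).
- Pearson r is clamped to [−1, 1]; values within 1e−14 of ±1 are snapped
  to exact ±1 with p = 0, since sample correlations that close to unity
  arise only from exact collinearity. Zero-variance profiles are skipped
  and counted at matrix scale (scalar calls raise `ZeroVarianceError`).
- The hypergeometric tail is computed through `scipy.stats.hypergeom.sf`
  (log-space stable); BH through `statsmodels.multipletests`.
- GO annotations are used as given: no ancestor propagation up the
  ontology is performed, and only the biological-process aspect is kept
  from GAF input.
- Wall-clock timings are written to a separate `timings.json` so every
  other artifact of a seeded run is byte-identical across reruns.
- SEP–SEP correlation edges are not built by default (the method pairs
  SEPs with protein profiles); passing the SEP matrix as the partner
  matrix builds them if wanted.

## Known limitations

- MCL is dense (O(n³) per iteration): intended for desk-scale networks
  (≤ a few thousand nodes), not the full 80k-ORF genome-wide case.
- Module detection is not formally monotone in edge addition (MCL may
  re-partition); monotonicity of the layer counts is asserted rather
  than proven, and holds on all tested inputs since layers only densify
  existing contexts.
- A single enrichment background (annotated network proteins) is used
  for both methods; per-method backgrounds are not implemented.
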