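# Methods

`pirliver` implements a small-RNA profiling workflow for PIWI-interacting
RNAs (piRNAs) and novel piRNA-like sequences in bulk liver tissue across the
stepwise lesions of hepatocarcinogenesis (cirrhotic nodule CN, low- and
high-grade dysplastic nodules LGDN/HGDN, early and progressed hepatocellular
carcinoma eHCC/pHCC).  This note records the models, defaults and numerical
choices, and what the synthetic data does and does not establish.

## Read classification

Adapter-trimmed reads are collapsed to unique sequences with per-sample
counts (default length window 18–40 nt; reads containing N are excluded and
tallied).  Each sequence is assigned to a known sncRNA class by **exact
match** against the annotation (FASTA with `>ID|CLASS` headers).  Ambiguous
sequences are resolved by a configurable class priority, default
miRNA > rRNA > tRNA > snoRNA > piRNA: non-piRNA classes absorb shared reads
first, so only reads matching nothing else count toward piRNAs.  Sequence
variants (3′ isoforms) sharing one annotation identifier are summed into
that identifier, since expression is reported per piRNA, not per isoform.
Exact matching (no mismatches, no untemplated tails) was chosen for
bit-reproducibility and oracle checkability; real small-RNA quantifiers
often tolerate 3′ heterogeneity, so absolute counts on real data would
differ at the margins.

Library size for normalization is the number of reads passing the ingest
filters per sample; RPM = count × 10⁶ / library size.

## piRNA-like discovery

Unannotated sequences of 25–35 nt (configurable; some somatic studies use
21–35) are scored by a transparent k-mer discriminant: per-k
length-normalized k-mer frequencies (k = 1..5, 1364 features) feed a
logistic regression trained on the known piRNA set (positives) versus decoy
sncRNAs plus per-positive mononucleotide shuffles (negatives).  Balanced
class weights keep probability 0.5 a usable retention threshold when the
two training sets differ in size.  The discriminant is deterministic given
its random state.  Retained candidates (score ≥ 0.5) are placed in the
genome by exact matching on both strands; candidates with more than
`max_placements` (default 30, motivated by the most promiscuous somatic
piRNAs mapping to ~28 loci) are set aside in a repetitive-sequence report,
like a short-read aligner's `-m` cutoff, and candidates with no placement
are reported unmapped.

Placements on the same contig and strand that overlap, or whose gap is at
most `merge_distance` (default 0), merge into a locus (`piR_LLi_N`,
numbered in (contig, start, strand) order).  Each member sequence
contributes its full count to **every** locus it maps in; a per-locus
multimap fraction is reported so users can filter.  Merging is idempotent,
and coverage is conserved up to that multimapping multiplicity.

## Differential expression

Features are filtered by mean RPM > threshold (default 1 RPM) in at least
one stage group — a deliberately simple stand-in for count-filter heuristics
whose exact form varies between tools.  The two-group test is the two-sided
unpaired Wilcoxon/Mann-Whitney rank-sum: exact enumeration of all
C(n+m, n) labelings (midranks for ties) when both groups have ≤ 8 samples,
otherwise the tie-corrected normal approximation with continuity correction
(scipy).  The unpaired form is the primary test even though patients are
matched; a paired signed-rank alternative is available behind a flag.  Fold
change is the ratio of group medians, with 0.5 RPM added to both medians
when either is zero (avoids infinite FC; flagged in output).
Benjamini–Hochberg adjustment (statsmodels step-up) is applied within each
feature family — known piRNAs and piR_LLi loci separately, mirroring the
two separate signatures such studies report.  Signature membership requires
|FC| ≥ 1.5 and FDR ≤ 0.05.

Stage-wise patterns: each intermediate stage (LGDN, HGDN, eHCC) is compared
to CN and to pHCC at raw p ≤ 0.05 (a per-comparison convention, as opposed
to the FDR rule used for signatures).  Features are then labeled `flat`,
`<stage>-restricted` (deviating from both anchors at a single stage),
`up-from-<stage>` / `down-from-<stage>` (deviating from CN from that stage
onward at pHCC-like levels), `pHCC-restricted`, or `mixed`.  High-expression
flagging marks features whose mean RPM in any one stage reaches 5,000 and
reports their share of total RPM.

## Biogenesis statistics

Positional nucleotide composition (1-based from the 5′ end, optionally
expression-weighted; information content 2 + Σ f·log₂f per position) feeds
exact binomial bias tests against a 0.25 background.  A position/base is
called biased when p ≤ 0.01 **and** the observed fraction is ≥ 2× the
background; the ratio condition prevents large repertoires from flagging
trivial deviations.  The primary-pathway signature is a biased position-1 T
(5′-U) together with an unbiased position-10 A; the ping-pong (secondary)
pathway would instead show a 10A bias.  Ping-pong pair detection itself
(10-nt 5′ overlaps) is out of scope: somatic tissue is expected to carry
only primary piRNAs.

## Genomic context

Coordinates are 0-based half-open (BED) throughout.  A placement is
assigned exactly one category by overlap against gene-model regions with
precedence 5′UTR > CDS > 3′UTR > intron > intergenic, requiring ≥ 50% of the
placement inside the region (robust to 1-bp boundary jitter; the threshold
is configurable).  Orientation is sense when the read strand matches the
host transcript.  For multi-placed features both a per-placement table and
a per-feature table (best placement by the same precedence, ties broken by
coordinate) are emitted.  Cluster membership is any overlap with the piRNA
cluster BED; contigs are classed nuclear or mitochondrial-like.

## Target prediction

The guide is the 20-nt subsequence from piRNA position 2 (piRNAs shorter
than 21 nt are skipped with a reason).  A target site is any 20-nt
transcript window whose reverse complement is within Hamming distance 3
(configurable) of the guide — antisense pairing, gap-free, sense strand of
the transcript only.  The search is seed-and-extend: the matching pattern
splits into four non-overlapping 5-mers, so by pigeonhole any window with
≤ 3 mismatches contains an exact seed; every hit is verified by direct
Hamming count, making the result provably identical to the brute-force
scan (and property-tested against it).  For thresholds above 3 the code
falls back to the full scan.  Site regions (5′UTR/CDS/3′UTR) are assigned
by window midpoint.

## Clustering and export

Samples are compared by Kendall tau-b (tie-corrected) over a feature set
(default: the DE signature), distance 1 − τ ∈ [0, 2]; Ward agglomeration is
applied to this non-Euclidean dissimilarity directly — a standard, knowingly
approximate practice, noted in the run manifest.  scipy's deterministic
nearest-neighbor-chain implementation fixes tie order; rerunning a
configuration reproduces the tree byte-for-byte, which is the property the
design protects.  Heatmap export is log₂(RPM + 1) median-centered per
feature row (row medians exactly 0).

## Synthetic data generator

The generator emulates the statistical structure of a bulk small-RNA study
of hepatocarcinogenesis; all outputs are pure functions of the
configuration, including its seed.

* **Design**: five stages with default sizes CN 14, LGDN 9, HGDN 6, eHCC 6,
  pHCC 20 (55 samples); each tumor-stage sample shares a patient identifier
  with a CN sample (matched design), though the default test is unpaired.
* **Counts**: gamma-Poisson (negative binomial), mean 50 and size 5 by
  default (variance m + m²/r).  No count model is canonical for this
  assay; NB is the standard overdispersed choice and enables
  parameter-recovery tests.  A configurable fraction (default 0.8,
  matching the dominant low-expression tail seen in somatic piRNA
  repertoires) of features is near-zero (mean scaled by 10⁻³); a
  configurable fraction (default 0.3) carries a planted fold change
  (default 4, half up / half down) in every non-reference stage.
  Per-stage mean multipliers can be overridden per feature to plant
  stage-restricted patterns.
* **Sequences**: piRNA-like sequences start with T with probability
  `u1_prob` (default 0.8) and continue by a fixed order-1 Markov
  composition.  The dinucleotide structure is what makes piRNA-likeness
  learnable: shuffling preserves mononucleotide content but erases it.
  Decoy sncRNAs (miRNA/rRNA/tRNA/snoRNA at class-typical lengths) are
  uniform random.
* **Genome**: random contigs plus a small mitochondrial-like contig; gene
  models with explicit 5′UTR/CDS/intron/3′UTR blocks on both strands.
  Known piRNAs and planted loci are embedded across context categories
  (weights roughly matching the reported somatic intragenic/intergenic
  split), predominantly on the transcribed strand when intragenic.
* **Reads**: emitted already adapter-trimmed (trimming is upstream of this
  pipeline's contract), constant quality `I` (quality is never consumed).
  Known sncRNAs emit their annotated sequence count-many times.  Planted
  loci emit reads tiled across the locus — first read anchored at the 5′
  end, last at the 3′ end — so the read union recovers the locus interval
  whenever per-sample coverage is ≥ 2; intermediate read starts snap to a
  nearby T with probability `u1_prob`, emulating 5′-U-preferring
  processing.  Loci whose samples each carry ≤ 1 read are recovered only
  partially (a realistic failure mode of coverage-based locus calling).
* **Target truth**: 20-nt transcript windows are overwritten with the
  reverse complement of a guide mutated at exactly m positions (m ≤ 4;
  sites with m = 4 are recorded as undetectable at the default threshold 3).

Not emulated: sequencing error, quality variation, PCR duplicates, adapter
read-through, 3′ isoform heterogeneity of annotated piRNAs, transposon
content of clusters, and between-patient biological heterogeneity beyond NB
dispersion.  Passing tests therefore demonstrate algorithmic correctness
and statistical calibration under the stated model, not robustness to those
real-data artifacts.

## Problem sizes and verification

The bundled toy configuration (`configs/toy.yaml`) uses a ~500 kb genome
(4 × 120 kb + 16 kb mitochondrial-like), 24 genes, 60 known piRNAs, 100
decoys, 24 planted loci, 30 transcripts and the 55-sample design — sizes
chosen so a full run takes seconds while every analysis branch is
exercised.  Recovery experiments use: differential expression, 10 vs 10
samples × 200 features × 20 seeds (planted FC 4 → mean sensitivity ≈ 0.99,
false-discovery proportion ≈ 0.07; null runs give raw p ≤ 0.05 at the rank
test's attainable level ≈ 0.044); locus discovery, 40 loci on the 500 kb
genome (≥ 97% boundary-exact recovery at coverage ≥ 5 reads); clustering,
8 vs 8 samples × 10 seeds (perfect two-group recovery in ≥ 9/10).  All of
these are recomputed, not asserted, by `scripts/acceptance.py` and the
acceptance test suite.

## Known limitations

* Exact-match classification undercounts piRNAs with 3′ heterogeneity.
* The k-mer discriminant is a stand-in trained on the provided annotation;
  its scores are only as meaningful as the positive/negative sets.
* Ward-on-τ is an approximation (no Euclidean embedding is guaranteed).
* The rank-sum test's discreteness caps attainable significance for small
  groups (e.g. minimum two-sided p = 0.1 at 3 vs 3), so tiny designs can
  never reach FDR ≤ 0.05.
* FC from medians with a 0.5-RPM pseudocount compresses fold changes of
  features expressed in only one group.
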