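# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would want spelled out. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Split-anchor rearrangement calling (`breakfast`)

**Model.** A genomic rearrangement leaves two footprints in a paired-end
library: fragments *straddling* the junction align as discordant pairs
(mates interchromosomal or far apart on one chromosome), and reads
*crossing* the junction fail to align end-to-end but their two ends match
the two partner loci.

**Evidence rules.** A discordant pair requires both mates aligned, both
MAPQ strictly above 15, and mates on different chromosomes or at least
1,000,000 bp apart (separation measured between leftmost coordinates,
inclusive at exactly 1 Mb). Interchromosomal pairs count as discordant —
the intra-chromosomal distance rule cannot apply to them, and promoter-swap
partners frequently lie on different chromosomes. Unaligned mates of at
least 50 bp are split into a 25 bp prefix and a 25 bp suffix anchor; each
anchor must place *uniquely* in the reference (exact match by default; a
one-mismatch mode using edlib is available, still requiring a unique
optimum). Ambiguous anchors carry no evidence. The pair of placements must
satisfy the same discordance rule.

**Implied breakpoints.** Each anchor's junction-facing end (the prefix
anchor's 3′ end, the suffix anchor's 5′ end, swapped for minus-strand
placements) approximates the breakpoint; because the junction lies between
the two terminal anchors, the estimate is biased toward the read interior
by up to read_length − 2·anchor_length = 40 bp. Cluster breakpoint
estimates are therefore modal values (ties broken toward the smaller
coordinate, for determinism), adequate for gene-level assignment but not
base-pair precise.

**Clustering.** Single-linkage over evidence items whose canonicalized
locus pairs lie on the same chromosome pair within a join radius on *both*
sides. The radius defaults to 1,000 bp: evidence from one junction
disperses by at most the library fragment size (~300 bp here), so 1 kb is
conservative without merging distinct junctions. Evidence is canonically
sorted before clustering, making output invariant under input order.
Distinct read IDs are counted per class, so an anchor pair and a
discordant pair from the same fragment cannot double-count, and
duplicate-flagged records are excluded upstream.

**Support filter.** Keep a cluster iff (≥ 1 paired read AND ≥ 5 anchor
pairs) OR (≥ 20 anchor pairs). The filter is a pure predicate of the two
counts, hence idempotent.

**Annotation.** Breakpoints are assigned to genes by interval overlap.
The 5′ (promoter-donating) partner is taken from the anchor evidence — the
prefix anchor of a junction-spanning read lies on the 5′ side; for
pair-only clusters the androgen-regulated gene, when unambiguous, is taken
as 5′ (a documented heuristic; clusters surviving the support filter always
carry anchors). Orientation: the two anchors of one read map to the same
strand for a sense junction and opposite strands for an antisense one;
straddling-pair mates behave the opposite way (FR libraries place
concordant mates on opposite strands). Antisense juxtapositions — an
active promoter placed downstream of the target in opposite orientation —
are reported, not rejected. `coding_disrupted` is true iff a breakpoint
falls strictly inside the 3′ gene's coding region.

## Read-depth copy number (`cnv`)

**Model.** In a tumor sample of purity ρ containing a segment of copy
change c on a chromosome of germline ploidy P, expected coverage relative
to diploid controls is `[ρ(P+c) + (1−ρ)P]/P`; at ρ = 0.7, P = 2, c = −1
this is 0.65, i.e. a raw logratio of log2(0.65) ≈ −0.62. Inverting:
`raw = P·2^logratio − P`, `corrected = raw/ρ`.

**Pipeline.** Windows are 500 bp with a 250 bp step (the half-window
overlap is the minimal-grid-bias reading of "overlapping windows"; both
are overridable). Logratios use the mean of ≥ 1 benign controls per
window; zero-control windows are masked and never contribute to any
statistic. Centering: per non-excluded chromosome, a running median of
length 50 (implemented as a centered length-51 window with edge
replication — an even centered window has no natural center; an exact
trailing-50 variant is available by flag) is histogrammed and the densest
bin's center taken as that chromosome's mode; the offset subtracted from
**all** windows (excluded chromosomes included) is the median of those
modes. Chromosomes 8, 22, X and Y are excluded from the offset estimate as
frequently aberrant. Histogram bins are 0.05 log2 units over [−3, 3],
**aligned so that zero is a bin center** — with edge-aligned bins every
zero-centered sample acquires a systematic half-bin (±0.025) offset. Mode
ties resolve toward 0. Modes are computed on filtered values; the offset
is subtracted from unfiltered values, keeping window-level signal intact.

**Gene calls.** Gene logratio = median over windows overlapping the gene
span, extended symmetrically to 20 kb for shorter genes (shifted inside
chromosome bounds when the extension would cross an edge, preserving the
20 kb span). Status is amplified/deleted when |corrected| exceeds 0.5;
the comparison is strict but guarded by a 1e-9 epsilon so a change equal
to the threshold up to float rounding (e.g. −0.35/0.7) stays neutral.
Ploidy is 2 for autosomes and 1 for X/Y (male genome).

**Assumptions and limits.** The mode-of-histogram centering presumes that
most windows on most included chromosomes are copy-neutral and that
per-chromosome histograms are well populated (genome-scale window counts);
on toy genomes where a third of each chromosome is aberrant, or with only
a few hundred windows per chromosome, the mode estimator can wobble by one
bin. Tests therefore use multi-megabase chromosomes with a clear neutral
majority — the estimator's design conditions. No GC/mappability correction
and no formal segmentation (CBS/HMM) are attempted.

## RNA-seq variant heuristic (`rnavar`)

Tumor calling demands ≥ 4 alternate reads and ≥ 15% allele fraction;
benign calling ≥ 2 reads and ≥ 5%, both inclusive ("at least"). The
asymmetry is deliberate: benign samples act as a germline *filter*, so
their calling errs toward sensitivity, making benign calling strictly more
permissive than tumor calling for any pileup (a tested invariant, along
with monotonicity in both count and fraction). Tumor pileups are expected
after duplicate removal (a coordinate+strand keyed dedup is provided,
bypassable for pre-deduplicated input) and exclusion of MAPQ < 10
alignments; benign pileups use all alignments. Site identity for filtering
is (chromosome, position, ref, alt); population lists load from sites-only
VCF (via pysam) or TSV. Only substitutions are called; indels are accepted
in exclusion lists but not called. Functional annotation is reduced to
gene-overlap classification (coding / genic-noncoding / intergenic) from
the supplied gene models; external annotation databases are out of scope.

## Expression normalization and batch correction (`expr`)

Median-of-ratios: the reference profile is the per-gene geometric mean
across samples over genes with all-positive counts; a sample's size factor
is the median of its count/reference ratios. Size factors are identifiable
only up to a common scale (the reference moves with the data); the tested
equivariance is that factor *ratios* scale with the data and normalized
values change by a single common constant. Length correction divides by
total exon length in kilobases and commutes gene-wise with normalization
(tested); normalization is applied first by convention. The batch model is
fitted only on benign tissues extracted with both Trizol and Qiagen:
per-gene Trizol/Qiagen median ratio plus a two-tailed unpaired Student's
t-test (Welch by flag; Student matches the era's default), sensitivity at
p < 1e-4. Genes with zero Qiagen median or zero variance across both
groups are skipped and listed on the model. Correction divides Trizol
samples' sensitive genes by the fitted ratio.

Overexpression flags: the outlier rule is `value > 3 × max(benign
reference)` per gene (margin overridable; a z-score rule is available
behind a flag) — the exact cutoff behind published subtype matrices is
never printed, and the fold-margin rule reproduces outlier structure
without inventing a number. Benign samples are never flagged; a sample may
be flagged for several genes (mutual exclusivity is a *finding*, not a
constraint).

## Statistics (`subtype_stats`)

The two-sided Fisher test uses the probability-ordering convention — sum
the hypergeometric probabilities of all margin-fixed tables no more
probable than the observed — in exact `Fraction` arithmetic, so ties are
handled without floating-point ambiguity (the doubling convention would
differ; this is the common default). Cohort frequencies round half-up at
one decimal in the reporting layer only. The t-test delegates to
scipy's implementation behind this module's surface; zero pooled variance
returns an undefined-result flag. The ratio s.e.m. uses first-order
(delta-method) propagation with zero covariance,
`|x/y|·sqrt((sx/x)² + (sy/y)²)`, with the documented limit
`|sx/y|` when the numerator mean is zero.

## Synthetic data (`synthetic`)

**What it emulates.** A small multi-chromosome genome (uniform random
sequence) with an androgen-regulated 5′-partner gene and a SKIL-like 3′
gene on different chromosomes plus expression-subtype genes; 90 bp
paired-end reads (fragment 300 ± 30 bp); junction evidence in the two
classes the caller consumes, with configurable counts per planted
rearrangement; window counts mixing tumor and normal cells at 70% purity;
pileups with binomial allele fractions; count matrices with lognormal
baselines (σ = 0.8 across genes), lognormal size factors, multiplicative
Trizol bias on chosen genes and planted overexpression factors. Counts are
negative-binomial with dispersion 0.02 (Poisson at 0) — technical-aliquot
scale variability, appropriate because the dual-extracted benign pairs
share tissue; the default benign design is 6 tissues × 2 extractions = 12
benign libraries, a realistic cohort size at which an a priori power
calculation puts the 3× bias detection at ~99% power for p < 1e-4.

**What it does not emulate.** Sequencing errors and quality scores,
transcript splicing (junction reads are genomic, junction-local),
GC/mappability bias, subclonal heterogeneity, per-patient biological
expression variation, and strand-specific library artifacts. Passing tests
therefore demonstrate correctness of the *computational* chain under its
stated model, not robustness to every artifact of real libraries.

**Determinism.** Every simulator is a pure function of (inputs, seed) via
`numpy.random.default_rng`; truth sidecars are sufficient to compute every
expected downstream output, and tests verify sidecar counts against
brute-force scans of the emitted records.

## Pipeline

Stages are independently runnable and communicate through SAM/TSV
contracts; the orchestrator adds nothing computational. Configs are YAML
with unknown keys rejected before any compute; every default is resolved
into the config, whose SHA-256 hash is recorded in each report. Reports
are byte-identical under re-run with the same config and seed (fixed float
formatting, sorted serialization).

## Problem sizes used in tests

Unit fixtures use 300 kb chromosomes (anchor uniqueness in uniform random
sequence is near-certain at 25 bp); the copy-number recovery checks use
3 × 2 Mb chromosomes at 100 pairs/window over 10 seeds; batch-correction
checks use ~1,100 genes × 18 samples; the Fisher test is compared with
enumeration exhaustively over all 2×2 tables with margins ≤ 30 in the
suite (≤ 20 in the acceptance script). These sizes were chosen as the
smallest at which each estimator operates under its stated assumptions.

## Known limitations

* Breakpoint estimates are gene-level, not base-pair precise (no gapped
  realignment of whole reads).
* The 5′-partner heuristic for anchor-free clusters depends on the
  androgen-regulation flag of exactly one partner.
* The histogram-mode offset inherits bin-width quantization (±0.025 at
  defaults); at whole-genome window counts this is negligible, on tiny
  genomes it is the dominant error term.
* Only substitutions are called by the variant heuristic.
* The overexpression cutoff is a package convention (3× benign maximum),
  not a published constant.
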