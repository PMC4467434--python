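# oncopipe

Computational discovery of promoter-swap gene fusions and their genomic
context in prostate cancer sequencing cohorts.

Roughly 60% of prostate cancers carry fusions that place an ETS-family
transcription factor under an androgen-regulated promoter (TMPRSS2-ERG
being the canonical case). A rarer subtype instead juxtaposes such
promoters with the SMAD inhibitor *SKIL* (SnoN), activating it without
touching its coding sequence. Detecting these events — and placing them in
context with copy-number changes, somatic mutations and expression
subtypes — requires a chain of methods that this package implements as a
tested, reusable library:

* **`oncopipe.breakfast`** — a split-anchor rearrangement caller for
  paired-end alignments. Evidence classes: *discordant read pairs* (both
  mates aligned, MAPQ > 15, interchromosomal or ≥ 1 Mb apart) and *anchor
  pairs* (each unaligned 90 bp mate split into two terminal 25 bp anchors,
  realigned independently; a discordant anchor placement marks a
  junction-spanning read). Evidence is clustered by single linkage on both
  loci and a cluster is reported when supported by ≥ 1 paired read and
  ≥ 5 anchor pairs, or by ≥ 20 anchor pairs. Calls are annotated against
  gene models: 5′/3′ partners, androgen-regulated promoter class,
  sense/antisense juxtaposition, and whether the 3′ coding sequence is
  disrupted.
* **`oncopipe.cnv`** — read-depth copy number in overlapping 500 bp
  windows: `logratio(w) = log2(tumor(w) / mean of benign controls(w))`,
  centred by subtracting the median of per-chromosome histogram modes of
  median-filtered logratios (chromosomes 8, 22, X, Y excluded from the
  estimate), summarized per gene with a 20 kb minimum span, and converted
  to calls via `raw = ploidy·2^logratio − ploidy`, `corrected = raw / 0.7`
  (70% tumor purity), with |corrected| > 0.5 marking amplification/deletion.
* **`oncopipe.rnavar`** — RNA-seq variant heuristic: a tumor site is
  called at ≥ 4 alternate reads and ≥ 15% allele fraction; benign (BPH)
  samples are called permissively (≥ 2 reads, ≥ 5%) and anything seen
  there, or in user-supplied population site lists, is filtered out as
  germline. The survivors are candidate somatic mutations.
* **`oncopipe.expr`** — median-of-ratios size-factor normalization,
  exon-length correction (per kb of exon), and RNA-isolation batch
  correction: on benign tissues extracted with both Trizol and Qiagen
  chemistry, genes differing at p < 1e-4 (unpaired t-test) are corrected
  by their Trizol/Qiagen median ratio. Subtype overexpression (ERG, ETV1,
  ETV4, SPINK1, SKIL) is flagged per sample against the benign reference.
* **`oncopipe.subtype_stats`** — exact-enumeration two-sided Fisher test
  for mutual exclusivity, cohort frequencies, unpaired t-tests, and
  first-order (delta-method) s.e.m. propagation for assay ratios.
* **`oncopipe.synthetic`** — simulators for every input the pipeline
  consumes (reference + gene models, alignments with planted junctions,
  coverage with planted copy segments at 70% purity, pileups with planted
  somatic/germline variants, count matrices with planted batch bias and
  overexpression), each emitting a machine-readable truth sidecar.
* **`oncopipe.pipeline`** — YAML-configured orchestration of the stages
  over SAM/TSV file contracts, with per-sample reports and a cohort
  alteration matrix.

## Worked example

`examples/` holds one short script per capability. Calling a planted
promoter-swap (`python examples/01_fusion_calling.py`):

```
planted junction: TMPRSS2L -> SKIL at chr1:35800 / chr2:45150
called: TMPRSS2L-SKIL  orientation=sense  promoter=androgen_regulated  coding_disrupted=False
  evidence: 2 discordant pair(s), 8 anchor pair(s); breakpoints ~35765 / ~45155
```

The caller recovers the planted partners from 2 straddling pairs plus 8
junction-spanning reads; `coding_disrupted=False` is the signature of an
activating promoter swap. Copy number
(`python examples/02_copy_number.py`):

```
normalization offset subtracted: -0.000
expected raw logratio in the deletion: -0.621
PTENL    logratio=-0.626 raw=-0.704 corrected=-1.006 -> deleted
NEUTRAL  logratio=-0.034 raw=-0.047 corrected=-0.067 -> neutral
```

A one-copy loss diluted to 70% purity shows up at log2(0.65) ≈ −0.62; the
purity correction restores the integer change −1.

The same stages are scriptable from the shell (`oncopipe simulate bundle`,
`oncopipe breakfast call`, `oncopipe cnv call`, `oncopipe rnavar somatic`,
`oncopipe expr normalize|batch-fit|batch-apply|flag`, `oncopipe stats
fisher|freq`, `oncopipe pipeline run --config run.yaml`).

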