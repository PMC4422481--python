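# Methods

`perimeso` re-creates, as a tested pipeline, the somatic-landscape analysis
used for small tumor cohorts assayed by SNP array and paired tumor–normal
sequencing: copy-number segmentation and recurrence scoring from probe-level
LogR/BAF, a staged somatic variant classifier and filter cascade, and the
integration of both evidence types into a per-sample gene-alteration status
table. Every stage is exercised end-to-end on synthetic cohorts with planted
truth; no external data is downloaded or required.

## Signal model for the array simulator

A tumor specimen of purity *p* (fraction of tumor cells) carrying a segmental
event of integer copy number *c* in a fraction *f* of its tumor cells has an
average of `2 + p·f·(c − 2)` copies per cell over the event, so the expected
LogR is

    LogR = log2( (2 + p·f·(c − 2)) / 2 )

For a clonal one-copy loss this is `log2(1 − p/2)`: −1 at purity 1 and
−0.6215 at purity 0.7. With the noise parameter at 0 the simulator emits
these values exactly, which is what the closed-form tests assert.

Heterozygous probes carry one A and one B allele; under a one-copy loss the
B-allele frequency becomes `((1−q) + q·b) / (2−q)` with `q = p·f` and
`b ∈ {0,1}` depending on which haplotype was lost (drawn per probe). At
purity 0.7 this puts heterozygous probes at 0.231/0.769, i.e. a mirrored BAF
of 0.769. Homozygous probes stay at 0/1. Gaussian noise of configurable
standard deviation (default 0.05, a typical array residual) is added to both
channels; BAF is clipped to [0, 1].

The count simulator draws per-site depths from Poisson(mean depth) and alt
reads from Binomial(depth, AF), with AF = 0.5 (germline heterozygous),
≈1 (homozygous), `target_af · p` (somatic) or the per-base error rate
(reference sites, default 10⁻³). A per-variant *detection efficiency* < 1
removes that fraction of alt reads together with their depth contribution,
reproducing the allelic-fraction underestimation seen when long indels
prevent reads from aligning — without simulating reads. Read-level quality
summaries (mean base quality, strand split, read position, distance to the
3′ end, mapping-quality difference, homopolymer length) are drawn from
well-behaved distributions so that the false-positive filter stage is
exercisable; artifact-like sites for negative tests are constructed
explicitly in the test suite.

## Segmentation

Per chromosome, the probe LogR sequence is partitioned by minimizing

    Σ_segments SSE(segment) + penalty × (number of breakpoints)

solved exactly by dynamic programming (O(n²), vectorized inner loop), rather
than by a heuristic. The default penalty is `γ·σ²·log n` (γ = 40) with σ
estimated robustly from the median absolute first difference — insensitive
to the true jumps it is meant to detect. Segment boundaries fall at midpoints
between flanking probes, so segments tile the probed span, probe counts are
conserved, and the segment count is non-increasing in the penalty. On
noiseless profiles the optimum is checked against exhaustive enumeration of
breakpoint placements in the test suite. Ties in the DP are broken toward
the earliest candidate breakpoint index, which is immaterial for profiles
whose optimum is unique.

Before segmentation, probes with a missing LogR in any sample are dropped
cohort-wide (so all samples share one grid), and each sample's LogR is
median-centered using only chromosomes whose mirrored BAF shows no allelic
imbalance. Centering on balanced chromosomes keeps whole-chromosome
aneuploidy visible — a global median would drag an aneuploid genome back to
LogR 0, the normalization artifact that historically forced manual review of
such samples.

## Calling thresholds

* amplified: mean LogR > 0.25 (strict); deleted: mean LogR < −0.25 (strict);
* LOH: mean mirrored BAF > 0.55 (strict), averaged over heterozygous-
  informative probes, i.e. probes whose raw BAF lies in (0.15, 0.85) —
  mirroring folds the symmetric split around 0.5 into one tail; a one-sided
  reading of raw BAF would miss half the signal;
* sample burden: cumulative bp lost/gained over segments longer than 1 Mb;
* cytoband status: deleted (amplified) when more than 75% of the band's
  physical length — length, not probe count — lies in segments of that
  status; recurrence additionally counts bands with ≥75% of their length in
  LOH-flagged segments, and reports bands supported by ≥3 samples;
* gene scores: per gene, the sum across samples of the containing segment's
  mean LogR (net LogR) and mean mirrored BAF (net BAF); a gene is assigned
  to the segment containing its midpoint, and an uncovered sample
  contributes 0 and the neutral 0.5 respectively. Net BAF as a *sum* with a
  0.5 neutral baseline is a declared convention; genes sharing a segment
  share scores by construction.

## Variant classification and cascade

Classification operates on the 2×2 table `[[n_ref, n_alt], [t_ref, t_alt]]`.
The somatic p-value is the one-sided Fisher exact tail for tumor-alt
enrichment (the direction of the biological question); LOH uses the
two-sided p. Genotype bands are heterozygous [0.15, 0.85] and
homozygous-alt above — conventional, configurable bounds. The exact test is
delegated to scipy; an independent integer-arithmetic hypergeometric
enumeration in the test suite confirms agreement to 10⁻⁹ across random
tables with margins ≤ 60.

Stages, in order, each recording the first failed rule; a site removed at
stage *k* is not re-tested downstream:

0. **basic** — tumor and normal depth ≥ 10× each, tumor VAF ≥ 0.10, mean
   variant base quality ≥ 17 (applied to variant-supporting bases);
1. **indel quality** — somatic indels need ≥ 10× coverage, ≥ 3 supporting
   reads, and germline frequency not above 5% (strictly-more-than removes);
2. **proximity/cluster** — SNVs within 3 bp of a retained indel, and SNVs in
   runs of ≥ 3 SNVs spanning ≤ 10 bp;
3. **somatic quality** — a somatic call is retained iff its Fisher p < 0.05
   *and* the normal is clean (≤ 5% alt for SNVs, zero alt reads for
   indels). The source description of this step reads as if significant
   calls were the ones removed, which would discard exactly the calls the
   test exists to find; the retain-if-significant reading is implemented;
4. **false-positive filter** — applied to germline and somatic calls:
   ≥ 4 variant reads, variant frequency ≥ 0.05, mean read position in
   [0.1, 0.9], distance to 3′ ≥ 0.1, two-sided exact binomial strand-bias
   p ≥ 0.01 (tested at ≥ 10 variant reads), homopolymer run < 5 bp, and
   mapping-quality difference ≥ −10. The named criteria are from the
   standard false-positive filter; the numeric defaults are declared here
   and all configurable. Read-length and mismatch-quality-sum deltas are
   folded into a single optional quality-delta test, off by default because
   the count simulator does not model per-read mismatch sums.

Every stage conserves sites (in = retained + removed, one conservation line
per stage in the log). Consequences come from a toy codon model over the
synthetic genes (Biopython codon table): substitutions are
silent/missense/nonsense; coding indels are frameshift iff their length is
not a multiple of 3, else in-frame. A 42-bp deletion is therefore annotated
`inframe_indel` even though such events are sometimes reported as
frameshifts; the arithmetic is followed and the discrepancy surfaced rather
than special-cased. Mutation rates are mutations per callable bp with the
cohort median taken as the lower middle value for even cohorts; recurrently
mutated genes count each gene once per sample over passed non-silent somatic
calls.

## Evidence integration

Per sample and target gene, evidence is gated by the declared assays
(array/exome/targeted): loss requires the array (or exome) assay; a sample
without an assay renders `NA` in the corresponding column, while an assayed
sample with no finding renders blank. A deleted segment containing the gene
midpoint records a loss with its size; the whole-chromosome marker is set
when the segment covers ≥ 95% of the chromosome's probed span (robust to
edge probes). Subclonality is flagged when a somatic allelic fraction is
below half the clonal-heterozygous expectation `p/2`, or when the deleted
segment's |mean LogR| is below half the clonal one-copy expectation
`|log2(1 − p/2)|` — both factors configurable, with purity assumed 0.7 as
in the emulated cohort design.

Categories partition the cohort: `both` iff loss and ≥ 1 somatic mutation,
else `mutation_only` / `loss_only` / `none`. A germline loss-of-function
variant is reported but does not by itself make a sample altered — this is
what makes the published 3 + 3 + 2 decomposition reproducible, since the
germline-variant carrier is counted under loss only. The altered percentage
is printed as the truncated integer (8/12 → 66), matching the convention of
the reported figure. The rendered table round-trips: parsing a rendered
table and re-rendering reproduces identical statuses.

## Synthetic study design (the default cohort)

The default `CohortConfig` is the emulated study: 12 samples — 3
mutation-only, 3 loss-only, 2 both, 4 none — at purity 0.7, sequencing depth
100×, array noise 0.05, probes every 50 kb on a 3-chromosome, 180 Mb
genome. The recurrently deleted region is a nominally 15 Mb one-copy loss
around the target gene (widened, if needed, to cover the gene's full
cytoband, since the emulated condition is a recurrently deleted band); one
loss sample instead loses the whole chromosome and additionally carries a
germline nonsense in the gene; one "both" sample carries a 42-bp in-frame
coding deletion with detection efficiency 0.6 (the aligner-dropout analog);
the other "both" sample has the loss and a nonsense mutation at cell
fraction 0.5 (subclonal). Passenger somatic variants are planted genome-wide
at 1.3 × 10⁻⁶ per bp — the emulated cohort's median rate — plus 30 germline
heterozygous variants per sample. Problem sizes (180 Mb genome, 3.6 k probes
and ~250 planted variants per sample) keep a full 12-sample analysis at a
few seconds while leaving every decision boundary (thresholds, LOH band,
cluster windows) well exercised.

What the simulator does *not* model — and what passing tests therefore do
not demonstrate about real data: probe density variation and capture bias,
GC waves, correlated LogR noise, realignment artifacts around indels,
population haplotype structure, contamination of the matched normal, and
multi-clone architectures beyond a single cell fraction per event.

## Numerical and degenerate-input choices

* Fisher p-values computed by scipy's exact routine; enumeration oracle in
  the tests only.
* SSE terms are clipped at 0 against floating-point cancellation in prefix
  sums; the auto-penalty floor is 10⁻⁶ so noiseless profiles are not split
  probe-by-probe.
* A copy-0 event at purity 1 would have LogR −∞; total copies are floored
  at 10⁻³ before the log.
* Segments with no heterozygous-informative probe carry a missing mirrored
  BAF and can never be LOH-flagged; in gene scores they contribute the
  neutral 0.5.
* Band ties in recurrence sorting are broken lexicographically; cascade
  stage order is fixed and a removed site keeps only its first failing
  label (stage 2 may attach both the proximity and the cluster flag).
* Empty inputs: an empty cohort summary and a zero callable length are
  errors; an empty call set yields an empty recurrence report.

## Known limitations

Purity is a known simulation parameter, not estimated; allele-specific
integer copy numbers are not inferred; tumor-only calling for targeted-only
samples is out of scope (their mutations enter integration as external
records); population-database annotation (dbSNP-style lookup) is not
performed. The two-sided Fisher branch trusts scipy's tie handling at
equal-probability tables, which can differ from naive enumeration at float
precision.
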