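# Methods

## Data model

The pipeline starts downstream of alignment: its input is a per-sample
table of read counts per (position, base, strand) on rCRS coordinates
(1-based, 1…16,569), with the position-in-read distribution of each
(position, base, strand) cell summarized as a (mean, sd) pair.  Carrying
summaries instead of raw per-read offsets keeps the format compact and is
sufficient for the approximate location test used by the read-position
filter; it cannot support rank-based or exact tests, which is a deliberate
trade-off.  Depth at a position is the sum of counts over bases and
strands.  Alignment, deduplication and base-quality recalibration are out
of scope; so is any remote data access.

## Heteroplasmy calling

A site is a high-confidence heteroplasmy in a sample when all six criteria
hold.  Thresholds live in `CallerConfig`; defaults in parentheses.

1. **Depth** ≥ `min_depth` (1000 reads).
2. **MAF** ≥ `min_maf` (0.01, inclusive).  The minor allele is the
   second-most-frequent base by strand-summed count; ties resolve toward
   the reference base, then alphabetically.  Indels and third alleles are
   not modelled.
3. **Strand balance**: the minor allele must appear on both strands
   (`strand_min_count` = 1 per strand) and its per-strand frequencies must
   agree within a ratio of `strand_ratio_max` (3.0).  A ratio rule was
   chosen over an exact test because at ~47,000× depth exact tests reject
   biologically real sites for trivial imbalances; the ratio is
   configurable.
4. **Region**: the site must lie outside 303–311, 3107, 16185–16193
   (hypervariable homopolymer tracts and the rCRS spacer) and 14800–15200
   (coverage collapse around the PCR primer sites used for mtDNA
   enrichment).
5. **Read-position balance**: a Welch-style two-sample test on the stored
   (mean, sd, n) read-offset summaries of minor vs major reads, two-sided,
   passing at p ≥ `readpos_alpha` (0.01).  Singleton minor support fails
   closed (one read gives no spread estimate).
6. **Poisson error test**: the minor count k must be improbable under the
   position's error rate: p = P(X ≥ k), X ~ Poisson(depth × rate),
   significant at `poisson_alpha` (0.01).  No multiple-testing correction
   is applied: the published per-site p-values include values as large as
   1 × 10⁻³, which a genome-wide Bonferroni (~3 × 10⁻⁶) would reject, so a
   plain per-site α is the only threshold consistent with the source
   analysis.

The error rate at a position, for a given allele, is estimated from the
other samples of the batch as (Σ allele counts + 1) / (Σ depths + 1).  The
+1 pseudocount keeps λ > 0 when no other sample shows the allele.  By
default the focal sample's **maternal relatives are excluded** from the
estimate: a germline heteroplasmy segregating in the family would
otherwise count as "error" and mask itself; `exclude_relatives=False`
restores the strict all-other-samples behaviour.  If no eligible sample
covers the position the criterion fails closed.  Known limitation: for an
allele that is the *major* allele of unrelated samples (a haplogroup
variant), the estimate approaches 1 and the site cannot be called; this is
inherent to the batch-error design, and is why ~50% heteroplasmies whose
minor allele matches the cohort consensus are systematically uncallable.

## Annotation

The gene model is the standard NC_012920 annotation (13 proteins, 22
tRNAs, 2 rRNAs); the D-loop is defined by coordinates (16024–16569 and
1–576), not a gene record.  Codon effects use the vertebrate
mitochondrial code; ND6 (the only light-strand protein gene) is
complemented before translation and numbered along its coding strand.
Genes overlapping in different frames (ATP8/ATP6, ND4L/ND4) are resolved
to the first gene in genomic order; no packaged variant falls in an
overlap, so this is a convention, not a result.  Incomplete terminal stop
codons are completed with A's, mirroring polyadenylation.

The packaged reference **sequence is synthetic**: the true NC_012920
sequence is not redistributed here, so `build_synthetic_rcrs()` generates
a deterministic stand-in with the true gene coordinates, open reading
frames under the mitochondrial code, and the real reference bases and
codon contexts at every position the packaged variant table touches.
Annotation is therefore exact at all analyzed sites and structurally
plausible elsewhere; consensus sequences and pairwise distances computed
against positions outside the analyzed set do not correspond to real
human mtDNA.

## Pairs, ΔNS, transmissions

Concordance is computed per domain (cardiac, palatal) from explicit
vocabularies mapping clinical terms to anomaly status (e.g. TOF, VSD,
MVP → anomaly; a murmur alone → none; combination terms like "VPI/BU"
count as an anomaly if any component is one).  Unknown terms raise —
nothing is inferred from strings.  Pairs with unequal deletion sizes are
excluded before any statistics because inheritance of the deletion cannot
be assumed.

ΔNS = (# high-confidence sites in child) − (# in mother).  A mother
shared by two pairs contributes the same count to both; pairs sharing a
mother are treated as independent throughout, matching the per-variant
accounting of the source analysis.

A transmission anchors on a site that is high-confidence in either
member — the rule is applied symmetrically, because mother-only
high-confidence sites exist and could never transmit under a child-only
rule — and tracks the anchor's minor allele (the child's when both
members are high-confidence, a single tracked allele per site).  The
partner must carry ≥ `min_partner_reads` (10) reads of the tracked
allele.  ΔAF = AF_child − AF_mother of the tracked allele, positive when
the child's frequency is higher.

## Statistics

Group comparisons use the Mann–Whitney U (pair count with 0.5 per tie)
and a Monte-Carlo permutation null: pooled values, labels redrawn
preserving group sizes, add-one estimator
p = (1 + #extreme) / (n_permutations + 1), which can never return 0 and
is reproducible given the seed.  `permutation_pvalue` defaults to
two-sided extremeness |U − n₁n₂/2|; the concordance comparison defaults
to the one-sided, concordant-greater alternative, which is the direction
under which the published pair-level group tests are consistent with full
enumeration of the label assignments (enumeration on the packaged ΔNS
values gives one-sided p = 0.020 cardiac / 0.067 palate, against two-sided
0.029 / 0.129).  Sidedness is a config switch.  ΔAF comparisons use
variants as units, matching the published group sizes; variants within a
pair are not independent, which is a documented caveat, and a pair-level
aggregation is available but off by default.  The Shapiro–Wilk check is
advisory only and never gates the permutation test.

## Synthetic cohorts

The generator emulates the study's data-generating process, not any real
genome:

- `het_rate` (1.0): Poisson mean of true heteroplasmies per mother;
  frequencies log-uniform on [`maf_min`, `maf_max`] = [0.01, 0.5].
- `bottleneck_n` (30): child AF = k/N, k ~ Binomial(N, AF_mother) — a
  single binomial bottleneck rather than a Kimura distribution, chosen for
  closed-form moments (E[AF_child] = AF_mother, Var = AF(1−AF)/N) that
  parameter-recovery tests can check; an optional second, smaller binomial
  stage models somatic drift and is off by default.  N = 30 sits in the
  range reported for human germline segregating units and produces
  realistic mother-to-child frequency swings.
- depths log-normal with median 47,000× (`depth_sigma` = 0.3, a modest
  spread consistent with a uniform deep-capture protocol); error rates
  Beta with mean 2 × 10⁻⁴ per (position, allele), drawn once and **shared
  across samples** — which is exactly what makes the cross-sample Poisson
  test informative; read-position summaries are those of uniform placement
  in 100-bp reads, with sampling jitter of the mean.
- `artifact_rate` (1.0 per sample): injected sites at callable MAF/depth
  that are strand-restricted or read-end-clustered, as negative controls
  for filters 3 and 5.
- phenotypes: P(discordant) = logistic(β0 + β1·max|ΔAF| of the pair);
  β0 defaults to logit(11/16), the observed cardiac split, and β1 = 0
  gives the null.  β1 values in tests are chosen for statistical power
  only and make no biological claim.

All randomness descends from one seed through named substreams (sites,
bottleneck, reads, artifacts, phenotypes).  The generator emits counts
for every simulated position in every sample, so batch error rates are
estimable everywhere.  What it does **not** emulate: read-level errors
(FASTQ/BAM), alignment artifacts, NUMT contamination beyond the excluded
regions, linked sites, haplogroup structure, or multi-generation mutation
accumulation — so passing recovery tests demonstrate the pipeline's
statistical behaviour under its own assumptions, not robustness to real
alignment pathology.

The bottleneck estimator is moment matching, N̂ = mean[AF(1−AF)] /
Var(ΔAF), with a percentile bootstrap interval; zero observed drift is
reported as "no drift detected" rather than a division error, and fewer
than 10 transmissions is an error.

## Problem sizes and numerical choices

The calibration and recovery tests run at sizes chosen to make their
Monte-Carlo error small relative to the asserted bounds: ~10⁵ draws for
the bottleneck variance (5% tolerance), 500 transmissions for N̂
recovery ([24, 36] at N = 30), a 50-pair cohort for the ≥95%/≥90%
recovery/rejection rates, and ~120 null-pipeline replicates (199
permutations each, 30 background positions) for the type-I check, which
asserts the rate within three binomial standard errors of the nominal
level.  Fixture-based checks are exact and deterministic.

Degenerate inputs are handled explicitly: zero coverage yields a no-data
result rather than an exception; a single observed base has MAF 0;
consensus construction is total (reference base at zero-coverage
positions, reference-then-alphabetical tie-break); empty groups,
constant vectors (Shapiro–Wilk), and unknown clinical terms raise with
the offending value named.

## Known limitations

- The 18 published transmission events are not reproducible from the
  packaged tables alone: 14 of them hinge on partner allele frequencies
  below the calling threshold, which exist only in the deposited raw
  reads.  The reconstruction recovers exactly the four both-member
  transmissions the printed table determines.
- Whether the published Poisson test was one-sided upper-tail, and which
  exact strand/read-position tests the upstream pipeline used, are not
  restated in the source; the defaults here are reimplementation choices,
  all configurable.
- The batch error model conflates haplogroup variation with error when
  relatives are not excluded (see above).
- The synthetic reference sequence is a stand-in; see Annotation.
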