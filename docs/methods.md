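# Methods

This note documents the models, defaults, and numerical choices behind
sigkit, and what the synthetic cohorts do and do not establish.

## Context classification

Coordinates are 1-based inclusive with the VCF anchor-base convention for
indels; indels must arrive left-aligned and trimmed, and classification
raises a normalization error when a one-base left shift would preserve the
allele.

- **SBS-96 / SBS-288.** Substitutions are reported in the pyrimidine
  representation; purine-reference events are reverse-complemented with
  flanks swapped and complemented. The SBS-288 prefix is `T:` when the
  pyrimidine lies on the transcribed (template) strand of the overlapping
  gene, `U:` on the untranscribed strand, `N:` outside genes. Loci under
  genes on both strands resolve to the longest overlapping interval, ties
  by lexicographic gene id — SBS-288 has no bidirectional class and the
  assignment must be deterministic.
- **DBS-78.** Ten canonical reference doublets; non-canonical doublets and
  (for the four palindromic references) non-canonical alternate alleles
  are reverse-complemented onto the published 78-label set. The tests
  verify, exhaustively over all 144 doublet substitutions, that the
  classifier induces exactly the 78 reverse-complement equivalence
  classes.
- **ID-83.** 1-bp events are keyed by the pyrimidine of the affected base
  and the homopolymer run length (deletions report run − 1, insertions
  the count of pre-existing copies, capped at 5); longer events by length
  bin (2, 3, 4, 5+) and tandem-repeat copy number scanned downstream
  (upstream copies cannot exist in left-aligned records; the test oracle
  scans both directions precisely to check this). Deletions in no repeat
  context are checked for microhomology on both flanks — longest deleted
  prefix matching the downstream flank or deleted suffix matching the
  upstream flank, maximum taken, capped at length − 1 and 5.
- **CN and SV schemas.** The exact published bin boundaries for the
  68-category CN and 38-category SV contexts are not public; the shipped
  defaults are reconstructions that honor the stated category counts and
  the short-event refinements, and both schemas are parameter objects that
  callers can replace wholesale. CN: homozygous deletion × 5 length bins,
  LOH × total-CN {1, 2, 3–4, 5–8, 9+} × 7 length bins, heterozygous ×
  {2, 3–4, 5–8, 9+} × 7 length bins, with ≤10 kb and 10–100 kb bins in
  every state (5 + 35 + 28 = 68). SV: {clustered, non-clustered} ×
  ({DEL, DUP, INV} × 6 size bins including <1 kb, plus TRA) = 38.
  Clustered status is consumed as an input flag; no clustering algorithm
  is implied.
- **Genome aberration fraction** is the covered-genome fraction whose
  (total, minor) copy state differs from (2, 1). The denominator is the
  genome covered by segments, which keeps the statistic agnostic to the
  upstream segmentation's coverage.

## De novo extraction

KL-NMF with multiplicative updates; entries are floored at machine epsilon
(flooring avoids divide-by-zero without materially moving optima, and the
divergence is still non-increasing to ~1e−10 relative tolerance, which the
tests assert per iteration). Initialization is uniform random scaled by
√(mean(V)/k), seeded per replicate as base seed + replicate index.
Convergence: relative divergence change < 1e−9 (default) or 10,000
iterations.

Hypermutator normalization rescales any column above the cap (default
10,000 mutations) down to the cap before factorization; consensus
activities are refit on the raw catalog, so reported activities are
mutation counts.

**Rank stability.** Pooled replicate signatures are clustered by
replicate-matched consensus clustering: every replicate contributes
exactly one signature per cluster, via Hungarian matching of its k columns
to the running centroids under cosine distance, iterated to a fixed
point. Plain (unconstrained) medoid clustering is unsuitable here: at
ranks above the true one it can split a tight cluster into two tight
subclusters and score silhouette ≈ 0.9 for an overfit rank, defeating
rank selection. Under the matched constraint the spurious extra signature
must form its own cluster, which is visibly diffuse (on planted rank-4
catalogs, stability falls from ≈0.99 at k=4 to ≈0.67 at k=5). Stability is
the mean silhouette of the pooled signatures under cosine distance.

**Rank selection** returns the largest rank with stability ≥ 0.8 whose
mean replicate divergence is within 5% of the best divergence among
qualifying ranks; if nothing qualifies, the most stable rank is returned
with a logged warning. Both thresholds are configurable.

Exact NMF is not identifiable in general: when no sample is dominated by a
single process, activity mass can shift between factors along WH = V. The
recovery tests therefore use sparse, well-separated profiles with
signature-dominant samples, which is also the regime where signature
analysis is scientifically interpretable.

## Sparse assignment

Forward phase: greedily add the candidate with the largest cosine-similarity
gain while the gain exceeds the addition penalty (ties: larger gain, then
lexicographic name). Backward phase: repeatedly drop the cheapest
signature while the loss is at most the removal penalty. The two phases
alternate to a joint fixed point (with cycle protection), so the reported
support satisfies both conditions simultaneously — which is exactly what
the exhaustive-enumeration oracle in the tests verifies on ≤6-candidate
instances. Activities are the NNLS solution on the final support, exact
zeros elsewhere, unrounded.

Defaults are add 0.05 / remove 0.01. The removal penalty must not exceed
the operative addition penalty: a removal gate looser than the addition
gate immediately prunes barely-admitted signatures, and relaxing the
addition penalty would then *lower* sensitivity. The relaxed
configuration (addition 0.01, used by the power study) caps the removal
penalty at the relaxed addition penalty for the same reason.

A consequence of cosine gating worth knowing: a component contributing a
fraction f of a profile improves reconstruction cosine by roughly f²/2,
so the 0.05 addition gate admits only components contributing ≳30% and
the 0.01 gate ≳15%. Recovery benchmarks therefore run at the relaxed
penalty; at the default penalty they would measure the sparsity gate, not
the fit.

Candidate rules are data: a reference set carries global exclusions
(SBS23, SBS32 by default), indel-triggered rescues (ID6 → SBS3,
ID3 → SBS92), and the MSI rescue set (SBS33 plus SBS6/14/15/20/21/26/44).
The MSI flag is an input boolean — upstream callers may derive it from low
reconstruction similarity plus ID2 enrichment; confirming MSI biology is
out of scope.

Per-mutation attribution follows Bayes' rule on the reconstructed
profile; contexts with zero reconstructed count are flagged undefined
rather than given probabilities. Driver attribution is confident only when
the best probability strictly exceeds the threshold (default 0.5 — a
probability of exactly one half is not "above 50%").

## Injection power study

Per sample and replicate: n = round(level × total) mutations are removed
as a multivariate hypergeometric draw (equivalent to removing uniformly
without replacement, hence never negative), n are injected as multinomial
draws from the target profile (pre-noise totals are conserved exactly),
then each category count receives zero-mean Gaussian noise with standard
deviation = noise_fraction × count, rounded and floored at zero. The noise
operator is the most local reading of "10% Gaussian noise" and is
config-swappable. Detection is strictly positive assigned activity of the
target under the relaxed penalty; an optional minimum-activity floor is
available. The level grid (1, 2, 5, 10, 15, 20%), 100 replicates per
level, and 10% noise are the defaults; the test suite and acceptance
script run a scaled 50-sample × 20-replicate design with a level-0 control
arm to keep runtimes in minutes.

Every input sample must lack the target under baseline assignment with
the target offered as a candidate; offending samples are listed in the
error.

## Exposure and association models

- PM2.5 per subject: mean of annual region values from the diagnosis year
  back to the series start; diagnoses before the series (or with unknown
  year) take the earliest year's value; diagnosis years beyond coverage
  truncate with a warning. Unknown region → missing, excluding the subject
  from pollution models. The 20 µg/m³ dichotomization is boundary-
  inclusive on the high side (documented choice; the convention is not
  standardized).
- Binary exposures encode high/exposed/yes as the indicator level, so
  reported effects read "exposed vs unexposed".
- Logistic presence models use Wald inference; complete separation or
  non-convergence falls back to an L2-penalized fit flagged
  `separation_penalized` with the point estimate only. Continuous PM2.5
  odds ratios are rescaled to 10 µg/m³.
- Linear models run on log10 (burdens, signature mutations) or log2
  (telomere ratios); percent change per unit = base^β − 1, CI transformed
  likewise. Dose-response models for a signature should be restricted by
  the caller to samples where the signature is present; non-positive
  outcomes are excluded with a logged count.
- BH FDR is applied within one analysis family (one variant class per
  analysis); driver models filter genes at prevalence > 2% and correct
  jointly.
- Fisher exact tests are two-sided; the sample odds ratio uses a Haldane
  0.5 correction (flagged) when a single cell is zero and is flagged
  infinite/undefined for degenerate margins. Rank-sum tests enumerate all
  group assignments with midranks for combined n ≤ 10 (ties handled
  exactly) and use the tie-corrected normal approximation above that;
  identical samples return p = 1 with an `all_tied` flag.

## Synthetic cohorts

The generator emulates, at catalog level, a large international
never-smoker lung-cancer cohort: ~79% female, mean age 64, mostly
adenocarcinoma, 28 recruitment regions whose annual PM2.5 series span
5–40 µg/m³. Per-sample activities are log-normal (default median 800
mutations per signature, log-sd 0.5, so six signatures give total burdens
of a few thousand) with optional log-linear PM2.5 slopes; a 3%
hypermutator tail multiplies all activities by 8; passive smoking
multiplies total burden (default ×1.083) without touching the signature
mix; telomere log2 ratios decline with PM2.5 (default −0.005 per µg/m³,
noise sd 0.3); driver indicators follow per-gene logistic models.
Catalogs are integer multinomial draws from the activity-weighted profile
mixture, separating biological intensity from sampling noise. All
randomness flows from one root seed through named child streams, so
adding draws to one stage never shifts another.

Scenario presets: `null` (no effects), `pollution` (slopes +12%, +2.3%,
+6% per µg/m³ on tobacco-like, clock-like and indel-like signatures, plus
the telomere slope), `passive-smoking` (burden-only effect), `msi` (one
indel-heavy outlier flagged for the rescue rule).

Ancestry is generated with a graded trend (EAS probability 0.25 → 0.65
across the region gradient) rather than a deterministic region split:
confounding between ancestry and exposure is retained for the covariate
adjustment to absorb, but a near-deterministic split makes the ancestry
label collinear with region-level PM2.5 and roughly doubles the standard
error of adjusted dose-response slopes, which mis-measures the models
rather than the data.

**What passing tests show — and don't.** The cohorts reproduce the
statistical structure the methods assume (mixture catalogs, log-normal
activities, log-linear exposure effects, burden-only passive-smoking
shifts), so the tests establish correctness of the algorithms and
calibration of the inference under that structure. They do not establish
robustness to real-data phenomena the generator omits: signature profiles
correlated the way true biological processes are, region-specific
signature sets, measurement error in exposure assignment, covariate-
dependent activity distributions, or mutation-calling artifacts.

## Problem sizes

Defaults used by the test suite and acceptance script, chosen to keep a
full run in minutes on one CPU while preserving the statistical behavior
of interest: extraction recovery on 150-sample catalogs with 10 replicates
per rank over ranks 2–6 and 10 cohort seeds; assignment recovery on 150
samples; the power study at 50 samples × 20 replicates × 7 levels;
exposure recovery at n=800 over 20–50 replicates; null calibration at 200
replicates per procedure. All sizes are configurable upward.
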