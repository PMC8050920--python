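# Methods

## Scope and model

`chromsig` implements the downstream statistics of a case/control ATAC-seq
study design: raw fragment counts over a merged peak list are normalized to
a common distribution, log2-transformed, tested for differential
accessibility between donor groups, clustered into condition signatures,
and summarized per sample as a signature score that can be related to
clinical covariates. Upstream read processing (trimming, alignment, Tn5
+4/−5 shifting, peak calling) is out of scope; the package starts from a
peak × sample count matrix and, for footprinting, from per-base insertion
tracks that are assumed to be already shifted.

All genomic coordinates are 0-based half-open throughout (BED-native);
1-based external conventions are converted at the I/O boundary only. Gene
symbols are upper-cased on ingest so GMT, TSS and association tables join
case-insensitively. Missing clinical values are carried as NaN and handled
by pairwise-complete deletion, never imputed.

## Normalization

Quantile normalization forces every sample onto the reference distribution
defined by the row means of the column-sorted matrix. Ties within a column
receive the mean of the reference values over their tied ranks, so ties
stay tied and column totals are preserved. Two consequences worth knowing:
for tie-free (continuous) data the normalized columns are identical as
multisets and the operation is exactly idempotent; with heavy integer ties
the column distributions agree only up to tie-structure and idempotence is
approximate. Counts are then transformed as log2(count + 1); the
pseudocount of 1 keeps zero counts at zero intensity. Peaks on chrY are
removed before normalization, and peaks with mean log2 intensity ≤ 3
across all samples are dropped (both configurable).

## Differential accessibility

Per-region two-sample Student's t-tests (equal-variance by default; Welch
behind a flag) with two-sided p, BH step-up FDR computed within each
contrast separately. log2 fold change is the difference of group means of
log2 intensities. Degenerate regions resolve deterministically: zero
spread with zero mean difference → p = 1; zero spread with a nonzero
difference → p = 0. Three threshold families are provided, all strict
comparisons:

| family | test | thresholds |
|---|---|---|
| disease-specific | unpaired t | \|log2FC\| > 1, p < 0.001, FDR < 0.1 |
| cell-type-specific (one-vs-rest) | unpaired t | \|log2FC\| > 4, p < 0.001, FDR < 0.01, mean log2 > 3 |
| stimulation (paired) | paired t | linear fold change 2^log2FC > 1.5, p < 0.01 (no FDR) |

The stimulation family's fold change is evaluated on the linear scale
against 1.5 because the threshold is stated as a fold change, while the
matrix is log2; survivors split by direction into up/down sets. The
matching RNA filter keeps genes with fold change > 1.5, p < 0.05 and total
counts > 5.

## Signature clusters and RAAS

The union of survivors over all pairwise disease contrasts is clustered
with k-means (k = 3, k-means++ initialization, 10 restarts, fixed seed,
Lloyd iterations to tol 1e-6). Rows are z-scored across samples first so
high-intensity peaks cannot dominate the Euclidean metric (a
`standardize=False` flag clusters raw intensities). Cluster semantics are
assigned from the centroids' group means: C3 maximizes RA − max(HD, OA),
C1 maximizes HD − max(OA, RA), C2 maximizes min(OA, RA) − HD, resolved in
the order C3, C1, C2 over distinct clusters; exact ties fall back to
cluster-index order with a logged warning.

The cluster score of sample *s* is
`100 · Σ_{r∈cluster} v[r,s] / Σ_{r} v[r,s]` over log2 intensities of all
retained peaks; the C3 score is the RA-associated ATAC-seq score (RAAS).
The denominator is total intensity (not peak count): this keeps the score
a dimensionless percentage, invariant to per-sample intensity scaling,
with scores over any partition of the peaks summing to exactly 100.

Sample-level PCA z-scores regions, projects samples onto the principal
axes, and fixes signs so each axis's largest-magnitude loading is
positive. A matrix of identical samples maps every sample to the origin; a
fully constant matrix is an error.

## Clinical statistics

RAAS is regressed on each covariate by OLS (statsmodels), reporting slope,
intercept, R² = 1 − SSres/SStot, and the slope's two-sided t-test p with
n − 2 df; fits use the samples where the covariate is present and require
n ≥ 3 and a non-constant covariate. No correction is applied across the
eight covariates by default (each is reported against the 0.05 bar); a BH
flag is available. Group comparisons of scores reuse the t-test machinery
(paired for stimulation designs, matched through pair ids). qPCR
quantification follows 2^(−ΔΔCT) with
ΔΔCT = (Ct_target − Ct_ref)_condition − (Ct_target − Ct_ref)_control.

## Region→gene association and set tests

Each gene's regulatory domain is its basal window (5 kb upstream, 1 kb
downstream of the TSS, strand-aware) extended on both sides up to 1 Mb but
stopping at the nearest neighboring gene's basal domain; the basal window
is always contained and coordinates clip at 0. A peak is associated with
every gene whose domain it overlaps by ≥ 1 bp. Gene-set overlap is tested
with a one-sided (enrichment) Fisher exact test — the hypergeometric upper
tail — within a stated gene universe. Chromatin-state composition
intersects peaks with a segmentation BED; a peak overlapping several
states counts once per state.

## Motif scanning and enrichment

PFMs become log-odds PWMs via
`w[b,j] = log2((counts[b,j]+pc)/Σ_b(counts[·,j]+pc)) − log2(background[b])`
with pseudocount 0.25 per cell and uniform background by default. Both
strands are scanned; a hit requires score ≥ 0.8 × the maximum attainable
score (flag-adjustable); N bases contribute the minimum column weight;
minus-strand hits are reported at the forward-strand offset of the match
start. Enrichment of a motif in a target region set versus a background
set is a one-sided hypergeometric test on region presence/absence over the
union universe, BH-corrected across motifs; the motif × set significance
matrix holds −log10 p capped at 300. This presence/absence hypergeometric
is a deliberate, transparent statistic; it is not a re-implementation of
any specific motif tool's internal background model, so absolute p-values
on real data will differ from such tools even where rankings agree.

## Pre-ranked GSEA

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum over the descending-ranked statistic: hits increment by
|stat|^weight / N_R, misses decrement by 1/(N − N_hits); ES is the signed
value at the maximal absolute deviation. Ties between positive and
negative extremes of equal magnitude (possible for symmetric rankings) are
broken toward the earliest position, judged with a 1e-9 tolerance so the
choice is stable under floating-point rounding; the miss ladder is
computed as exact integer ratios for the same reason. The p-value is a
gene-sampling permutation test: null sets of equal size drawn without
replacement, p = (1 + #{|ES_null| ≥ |ES_obs|}) / (1 + n_perm), seeded.
Weight 1 is the default; weight 0 gives the unweighted KS statistic.

## Footprinting

Per-base cleavage counts are extracted at center − flank … center + flank
(default flank 100 → 201 offsets) for every motif site, minus-strand
windows reversed, and averaged over sites. The motif center of a width-W
match is floor((W−1)/2) from the match start — stated explicitly so even
widths never drift by a base. Peak-center profiles use the interval
midpoint with no strand flip. Group comparisons average each sample's
profile within ±10 bp of center and apply an unpaired t-test. No
naked-DNA (Tn5 sequence bias) correction is applied; profiles are raw
cleavage averages.

## Synthetic study conditions

The generator defaults encode the emulated study design and are not meant
to be tuned per run:

* **Cohort**: 20,000 autosomal peaks (plus 100 chrY peaks to exercise the
  chrY filter), arms HD/OA/RA = 14/23/26, baseline log2 intensity
  N(5, 1.5) per peak, sample noise sd 0.5, three planted 500-peak clusters
  with effect size 1.5 log2 units (C1 up in HD, C2 up in OA and RA, C3 up
  in RA). Each RA sample carries a severity multiplier s ~ N(1, 0.3)
  (clipped at 0.1) scaling its C3 effect — the disease-heterogeneity term
  that makes a per-sample clinical coupling meaningful. CRP (mg/L) for RA
  is 4 + 12 · (1.5 · s) + N(0, 3), clipped at 0.1, giving RA values around
  22 ± 6 against a low OA/HD baseline (≈3 ± 2) — realistic for active,
  treatment-naive RA versus OA. An ESR covariate is drawn independently of
  everything as a negative control. Counts are emitted as
  round(2^log2 − 1) so the pipeline's own normalization path is exercised.
* **Stimulation pairs**: 5 donor pairs (control/CRPstim) sharing per-donor
  baselines (donor sd 0.3), C3-truth peaks shifted +1.0 log2 in the
  stimulated arm.
* **Motifs**: 100 target and 400 background sequences of 200 bp, an 8-bp
  consensus planted in 90% of targets and 10% of background (random offset
  and strand), plus 5 decoy motifs planted nowhere.
* **Insertion tracks**: ≥50 sites (default 200) spaced 1 kb; Poisson
  counts at rate λ = 10 genome-wide, λ·f inside the accessible peak around
  each site (f = 2 control, 3 stimulated), with a footprint at the center:
  the rate is suppressed by d·(1 − |offset|/halfwidth) with depth d = 0.6
  and half-width 10 bp, i.e. a depletion that is maximal exactly at the
  site center and tapers linearly to the edges. The tapered (rather than
  flat-bottomed) dip reflects how averaged footprints look and guarantees
  the aggregate minimum sits at the center in expectation. The enriched
  zone spans the whole ±100 bp aggregation window (flank_extent 120),
  because motif sites live inside called peaks that are wider than the
  window.
* **Gene context**: 300 genes; a 40-gene planted set whose TSSs sit at C3
  peak midpoints (so region→gene association recovers it), random decoy
  sets, and a ranked DE statistic with the planted genes shifted +2.

What the generators deliberately do not model: fragment-length structure,
GC or Tn5 sequence bias, batch effects between cohort sources, peak-width
variation, count overdispersion beyond the log-normal intensity model, and
correlated peaks (regions are independent given group and sample). Passing
recovery tests therefore demonstrates the correctness and calibration of
the statistics under the declared generative model, not robustness to
these real-data complications.

## Numerical conventions and edge cases

* All threshold comparisons strict, as written above.
* BH q-values computed by the standard step-up, input order preserved.
* Zero-variance t-tests resolve to p ∈ {0, 1} as described; paired tests
  require equal sizes ≥ 2.
* Quantile normalization rejects non-finite input; log2 transform refuses
  to run twice.
* k-means discards empty-cluster restarts (scikit-learn handles this
  internally); identical seeds give identical assignments.
* Cluster scores error on a zero denominator; an empty cluster scores 0.
* Fisher/hypergeometric p capped at 1; −log10 p capped at 300.
* The pipeline orchestrator validates all input paths before any
  computation, logs per-stage timings to stderr, aborts with a
  stage-named error, and writes a manifest (config hash, seed, version,
  per-stage row counts). With no differential structure (e.g. a null
  cohort) labelling is skipped and the run still completes.

## Problem sizes used in validation

The test suite and the acceptance script run the full default cohort
(20,000 peaks, 63 samples) for single-seed recovery checks, and reduced
cohorts (2,000 peaks, 150-peak clusters) where only the planted structure
matters. Calibration checks use 50–100 generator seeds per property and
1,000 random instances per statistical primitive against brute-force
oracles. These sizes make the whole suite run in about two minutes on one
CPU while leaving every recovery margin wide (cluster Jaccards ≥ 0.93 at
defaults against an acceptance bar of 0.9).

## Known limitations

* Student's t on log2 intensities is the study's statistic; it is not a
  count-model DE test (no dispersion shrinkage), and small-group contrasts
  inherit its assumptions.
* The motif enrichment background is user-supplied; no GC- or
  length-matched background construction is provided.
* Regulatory-domain association ignores TAD structure and enhancer–gene
  maps; it is a distance rule.
* GSEA uses gene-sampling permutations, which test a competitive null and
  can be liberal relative to phenotype permutation when genes are
  correlated.
* The RAAS denominator uses total intensity by default because it keeps
  the score a bounded, scale-invariant percentage; the alternative reading
  (dividing by the number of peaks) is exposed as
  ``cluster_score(..., denominator="count")``.
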