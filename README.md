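# chromsig

Condition-specific chromatin accessibility signatures from ATAC-seq count
matrices.

`chromsig` is for epigenomics groups comparing open-chromatin profiles
across patient groups — the motivating design is immune-cell ATAC-seq from
rheumatoid arthritis (RA) patients, osteoarthritis (OA) patients and
healthy donors (HD). It takes a peak × sample count matrix and sample
metadata through the full downstream analysis:

1. **Normalization** — quantile normalization of raw counts (chrY removed),
   log2 peak intensities, and a mean-intensity filter
   (mean log2 count > 3).
2. **Differential accessibility** — per-region Student's t-tests with
   Benjamini–Hochberg FDR. Disease-specific peaks:
   |log2FC| > 1, p < 0.001, FDR < 0.1 over all pairwise group contrasts;
   cell-type-specific peaks: |log2FC| > 4, p < 0.001, FDR < 0.01, mean > 3
   (one-vs-rest); paired stimulation contrast: fold change > 1.5, p < 0.01.
3. **Signature clusters** — k-means (k = 3, seeded k-means++, row z-scores)
   over the differential peaks, labelled C1 (high in HD), C2 (high in OA
   and RA) and C3 (high in RA only).
4. **Scoring** — per-sample cluster score
   `100 · Σ_{r∈cluster} v[r,s] / Σ_{r} v[r,s]`
   over log2 intensities; the C3 score is the **RA-associated ATAC-seq
   score (RAAS)**.
5. **Clinical correlation** — OLS of RAAS on clinical covariates (CRP,
   DAS28-CRP, DAS28-ESR, ESR, joint counts, RF, anti-CCP) with R² and the
   slope's t-test p.
6. **Annotation** — region→gene maps via basal-plus-extension regulatory
   domains (5 kb up / 1 kb down, ≤1 Mb extension to the nearest neighbour's
   basal domain), one-sided Fisher exact gene-set overlap tests, and
   chromatin-state composition against a segmentation BED.
7. **Motif enrichment** — log-odds PWM scanning of peak sequences (both
   strands) and hypergeometric enrichment of target vs background peaks,
   plus the motif × sample −log10 p matrix.
8. **GSEA** — pre-ranked enrichment scores (weighted Kolmogorov–Smirnov
   running sum) with a gene-sampling permutation p.
9. **Footprinting** — per-base Tn5 cleavage aggregated over motif centers
   (−100..+100 bp, strand-aware) and peak-center metaprofiles, with
   central-signal group comparisons.

A first-class synthetic-cohort module (`chromsig.synthetic_data`) generates
every input with known ground truth — planted C1/C2/C3 clusters, a CRP
covariate coupled to each RA sample's C3 elevation, paired
control/stimulation samples, planted motif instances and insertion tracks
with footprint-shaped depletion — so every stage of the pipeline can be
validated by parameter recovery.

## Worked example

```python
import numpy as np
from chromsig import synthetic_data as sd, normalization as nz
from chromsig import differential as diff, signature as sig, clinical_stats as cs

matrix, metadata, regions, truth = sd.generate_cohort(sd.CohortConfig(seed=17))
norm = nz.normalize_pipeline(matrix)                      # QN + log2, drop chrY, mean > 3
diff_regions = diff.disease_differential_regions(norm, metadata)
clusters = sig.label_clusters(
    sig.kmeans_regions(norm.subset_regions(sorted(diff_regions))), metadata)
scores = sig.raas_scores(norm, clusters)                  # RAAS = C3 score per sample

print(f"differential regions: {len(diff_regions)}")
for label in ("C1", "C2", "C3"):
    pred, true = clusters.regions_of(label), truth.cluster_regions(label)
    print(f"{label}: {len(pred)} regions, Jaccard vs truth "
          f"{len(pred & true) / len(pred | true):.3f}")
by_group = sig.scores_by_group(scores, metadata)
print("RAAS means:", {g: round(float(np.mean(v)), 2) for g, v in by_group.items()})
t, p, _ = cs.compare_scores(scores, metadata, "RA", "OA")
print(f"RAAS RA vs OA: t = {t:.1f}, p = {p:.2e}")
ra = [s for s in metadata if s.group == "RA"]
ra_scores = [s for s in scores if truth.sample_groups[s.sample_id] == "RA"]
for f in cs.score_vs_clinical(ra_scores, ra, ["CRP", "ESR"]):
    print(f"RAAS ~ {f.covariate}: slope = {f.slope:.4f}, "
          f"R^2 = {f.r_squared:.3f}, p = {f.p_slope:.2e}")
```

Output:

```
differential regions: 1441
C1: 464 regions, Jaccard vs truth 0.928
C2: 496 regions, Jaccard vs truth 0.992
C3: 481 regions, Jaccard vs truth 0.962
RAAS means: {'HD': 2.57, 'OA': 2.57, 'RA': 3.26}
RAAS RA vs OA: t = 14.9, p = 2.10e-19
RAAS ~ CRP: slope = 0.0307, R^2 = 0.823, p = 1.66e-10
RAAS ~ ESR: slope = -0.0023, R^2 = 0.013, p = 5.79e-01
```

The pipeline recovers each planted 500-peak cluster almost exactly
(Jaccard ≥ 0.93), RAAS is elevated specifically in the RA arm, the
regression recovers the planted positive CRP–RAAS coupling, and the
deliberately decoupled ESR covariate stays non-significant.

The same analysis runs from the shell:

```sh
chromsig simulate cohort --seed 17 --outdir sim/
chromsig normalize --matrix sim/counts.tsv --out norm.tsv
chromsig diff --matrix norm.tsv --meta sim/metadata.tsv --contrast RA:OA --out diff.tsv
chromsig run --config run.yaml          # full pipeline with a manifest
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generators and their defaults, numerical conventions (tie handling,
degenerate tests, ES tie-breaks) and known limitations.
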