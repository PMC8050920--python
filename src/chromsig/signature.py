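"""Chromatin signature construction: k-means clustering of differential
peaks into condition signatures (C1 high in healthy donors, C2 high in both
patient groups, C3 high in RA only), per-sample cluster scores, and PCA of
samples on a signature's peaks.

The C3 score — the percentage of a sample's total peak intensity that falls
in the RA-specific cluster — is the RA-associated ATAC-seq score (RAAS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import LOG2_INTENSITY, AccessibilityMatrix, SampleRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 3
DEFAULT_SEED = 17
DEFAULT_RESTARTS = 10

C1, C2, C3 = "C1", "C2", "C3"


@dataclass
class SignatureClusters:
    k: int
    assignment: dict[str, int]  # region_id -> cluster index
    centroids: np.ndarray       # k x n_samples, in z-score units
    samples: list[str]
    semantics: dict[int, str] = field(default_factory=dict)  # index -> label

    def regions_of(self, cluster: int | str) -> set[str]:
        if isinstance(cluster, str):
            matches = [i for i, lab in self.semantics.items() if lab == cluster]
            if not matches:
                raise KeyError(f"no cluster labelled {cluster!r}")
            cluster = matches[0]
        return {rid for rid, c in self.assignment.items() if c == cluster}

    @property
    def labelled(self) -> dict[str, set[str]]:
        return {lab: self.regions_of(i) for i, lab in self.semantics.items()}


@dataclass
class SampleScore:
    sample_id: str
    cluster_label: str
    score: float


def zscore_rows(values: np.ndarray) -> np.ndarray:
    """Standardize each region across samples; constant rows map to zero."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


def kmeans_regions(
    matrix_subset: AccessibilityMatrix,
    k: int = DEFAULT_K,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
    standardize: bool = True,
) -> SignatureClusters:
    """Cluster differential regions with seeded k-means++.

    Rows are z-scored across samples first (``standardize=False`` clusters
    raw intensities) so high-intensity peaks cannot dominate the Euclidean
    metric.  Best of ``restarts`` initializations by within-cluster sum of
    squares; deterministic given ``seed``.
    """
    n = len(matrix_subset.regions)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of regions ({n})")
    z = zscore_rows(matrix_subset.values) if standardize else matrix_subset.values
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts,
        max_iter=300, tol=1e-6, random_state=seed,
    ).fit(z)
    assignment = {
        rid: int(lab) for rid, lab in zip(matrix_subset.region_ids, km.labels_)
    }
    return SignatureClusters(
        k=k, assignment=assignment, centroids=km.cluster_centers_,
        samples=list(matrix_subset.samples),
    )


def label_clusters(
    clusters: SignatureClusters,
    metadata: list[SampleRecord],
    groups: tuple[str, str, str] = ("HD", "OA", "RA"),
) -> SignatureClusters:
    """Attach C1/C2/C3 semantics from the centroids' group means.

    C3 maximizes RA − max(HD, OA); C1 maximizes HD − max(OA, RA); C2
    maximizes min(OA, RA) − HD.  Labels are assigned in order C3, C1, C2 to
    distinct argmax clusters; anything left is unlabelled.
    """
    hd, oa, ra = groups
    if clusters.k < 3:
        raise ValueError("need >= 3 clusters to assign C1/C2/C3 labels")
    group_cols: dict[str, list[int]] = {g: [] for g in groups}
    for j, sid in enumerate(clusters.samples):
        rec = next((s for s in metadata if s.sample_id == sid), None)
        if rec is not None and rec.group in group_cols:
            group_cols[rec.group].append(j)
    for g, cols in group_cols.items():
        if not cols:
            raise ValueError(f"group {g!r} has no samples in the matrix")
    gm = {g: clusters.centroids[:, cols].mean(axis=1) for g, cols in group_cols.items()}
    criteria = {
        C3: gm[ra] - np.maximum(gm[hd], gm[oa]),
        C1: gm[hd] - np.maximum(gm[oa], gm[ra]),
        C2: np.minimum(gm[oa], gm[ra]) - gm[hd],
    }
    if all(np.allclose(c, c[0]) for c in criteria.values()):
        logger.warning("degenerate centroids: all label criteria tied; "
                       "labels assigned by cluster index order")
    semantics: dict[int, str] = {}
    for label in (C3, C1, C2):
        order = np.argsort(-criteria[label], kind="stable")
        for idx in order:
            if int(idx) not in semantics:
                semantics[int(idx)] = label
                break
    clusters.semantics = semantics
    return clusters


def cluster_score(
    matrix_full: AccessibilityMatrix,
    cluster_regions: set[str],
    sample_id: str,
    denominator: str = "intensity",
) -> float:
    """Percentage of a sample's total peak intensity inside the cluster:
    ``100 * sum(cluster intensities) / sum(all intensities)``.

    ``denominator="count"`` divides by the number of peaks instead — a mean
    intensity per peak times 100 rather than a bounded percentage.
    """
    if matrix_full.scale != LOG2_INTENSITY:
        raise ValueError("cluster_score expects a log2 intensity matrix")
    all_ids = set(matrix_full.region_ids)
    stray = set(cluster_regions) - all_ids
    if stray:
        raise KeyError(f"cluster regions not in matrix: {sorted(stray)[:5]}")
    j = matrix_full.sample_index(sample_id)
    col = matrix_full.values[:, j]
    if denominator == "intensity":
        total = float(col.sum())
    elif denominator == "count":
        total = float(len(col))
    else:
        raise ValueError("denominator must be 'intensity' or 'count'")
    if total == 0:
        raise ZeroDivisionError(f"sample {sample_id!r} has zero total intensity")
    mask = np.array([rid in cluster_regions for rid in matrix_full.region_ids])
    return 100.0 * float(col[mask].sum()) / total


def raas_scores(
    matrix_full: AccessibilityMatrix,
    clusters: SignatureClusters,
    label: str = C3,
) -> list[SampleScore]:
    """RAAS per sample: the C3 cluster score (or any other label's)."""
    regions = clusters.regions_of(label)
    return [
        SampleScore(sid, label, cluster_score(matrix_full, regions, sid))
        for sid in matrix_full.samples
    ]


def scores_by_group(scores: list[SampleScore], metadata: list[SampleRecord]):
    group_of = {s.sample_id: s.group for s in metadata}
    out: dict[str, list[float]] = {}
    for sc in scores:
        out.setdefault(group_of[sc.sample_id], []).append(sc.score)
    return out


def pca_samples(matrix_subset: AccessibilityMatrix, n_components: int | None = None):
    """Project samples onto the principal axes of the region-z-scored matrix.

    Returns ``(coordinates, variance_explained)`` where coordinates is
    n_samples x n_components and variance-explained fractions sum to 1 over
    the full decomposition.  Sign convention: the largest-magnitude loading
    of each axis is positive.
    """
    n_regions, n_samples = matrix_subset.shape
    if n_samples < 2 or n_regions < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 regions")
    v = matrix_subset.values
    if np.all(v == v.flat[0]):
        raise ValueError("constant matrix: no variance to decompose")
    z = zscore_rows(v)
    max_comp = min(n_samples, n_regions)
    if np.allclose(z, 0):
        # identical samples: every projection collapses to the origin
        coords = np.zeros((n_samples, max_comp))
        var = np.zeros(max_comp)
        if n_components is not None:
            coords, var = coords[:, :n_components], var[:n_components]
        return coords, var
    x = z.T  # samples x regions
    pca = PCA(n_components=max_comp, svd_solver="full").fit(x)
    coords = pca.transform(x)
    # fix signs so the largest-|loading| of each component is positive
    for c in range(coords.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    var = pca.explained_variance_ratio_
    if n_components is not None:
        coords, var = coords[:, :n_components], var[:n_components]
    return coords, var
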