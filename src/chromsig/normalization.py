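"""Raw-count normalization: chromosome filtering, quantile normalization,
log2 intensity transform, and the minimum-mean-intensity peak filter.

Every downstream statistic in this package runs on quantile-normalized log2
intensities, so this module is the single entry point from raw counts to the
analysis-ready matrix.
"""

from __future__ import annotations

import numpy as np

from .io_formats import LOG2_INTENSITY, RAW_COUNTS, AccessibilityMatrix


def drop_chromosomes(matrix: AccessibilityMatrix, chroms) -> AccessibilityMatrix:
    """Remove all peaks on the given chromosomes (e.g. chrY before
    normalization), preserving the order of the remaining rows."""
    chroms = set(chroms)
    if not chroms:
        raise ValueError("no chromosomes given")
    keep = [i for i, r in enumerate(matrix.regions) if r.chrom not in chroms]
    if not keep:
        raise ValueError("dropping chromosomes removed every region")
    return AccessibilityMatrix(
        [matrix.regions[i] for i in keep], list(matrix.samples),
        matrix.values[keep, :], matrix.scale,
    )


def quantile_normalize(matrix: AccessibilityMatrix) -> AccessibilityMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the vector of row means of the column-sorted matrix.
    Each column's values are replaced by the reference value at their rank;
    tied values within a column receive the mean of the reference values
    over their tied ranks, so ties stay tied.
    """
    v = matrix.values
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v, dtype=float)
    for j in range(v.shape[1]):
        col = v[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = reference.copy()
        # average reference values over runs of tied input values
        i = 0
        n = len(sorted_col)
        while i < n:
            k = i + 1
            while k < n and sorted_col[k] == sorted_col[i]:
                k += 1
            if k - i > 1:
                assigned[i:k] = reference[i:k].mean()
            i = k
        out[order, j] = assigned
    return AccessibilityMatrix(list(matrix.regions), list(matrix.samples), out, matrix.scale)


def log2_intensity(matrix: AccessibilityMatrix, pseudocount: float = 1.0) -> AccessibilityMatrix:
    """log2(count + pseudocount); flips the scale flag to log2_intensity."""
    if matrix.scale == LOG2_INTENSITY:
        raise ValueError("matrix is already on the log2 intensity scale")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return AccessibilityMatrix(
        list(matrix.regions), list(matrix.samples),
        np.log2(matrix.values + pseudocount), LOG2_INTENSITY,
    )


def filter_min_mean(matrix: AccessibilityMatrix, threshold: float) -> AccessibilityMatrix:
    """Keep peaks whose mean log2 intensity across all samples exceeds
    ``threshold`` (strict >)."""
    means = matrix.values.mean(axis=1)
    keep = np.flatnonzero(means > threshold)
    return AccessibilityMatrix(
        [matrix.regions[i] for i in keep], list(matrix.samples),
        matrix.values[keep, :], matrix.scale,
    )


def normalize_pipeline(
    matrix: AccessibilityMatrix,
    drop_chroms=("chrY",),
    pseudocount: float = 1.0,
    min_mean: float | None = 3.0,
) -> AccessibilityMatrix:
    """Raw counts -> analysis-ready matrix: drop chromosomes, quantile
    normalize, log2 transform, then apply the mean-intensity filter."""
    if matrix.scale != RAW_COUNTS:
        raise ValueError("normalize_pipeline expects raw counts")
    out = matrix
    drop = [c for c in drop_chroms if any(r.chrom == c for r in out.regions)]
    if drop:
        out = drop_chromosomes(out, drop)
    out = quantile_normalize(out)
    out = log2_intensity(out, pseudocount)
    if min_mean is not None:
        out = filter_min_mean(out, min_mean)
    return out
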