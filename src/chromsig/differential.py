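"""Differential accessibility: per-region two-sample t-tests, BH FDR,
the threshold families used to call cell-type-specific, disease-specific and
stimulation-responsive peaks, and the matching RNA DE filter.

Conventions:

* log2 fold change = difference of group means of log2 intensities
  (the matrices are already log2-scale), oriented a - b.
* All threshold comparisons are strict (``>`` for \\|log2FC| and mean
  intensity, ``<`` for p and FDR).
* The FDR family is one pairwise comparison: BH is applied within each call
  to :func:`differential_table`, never pooled across contrasts.
* Zero-variance degeneracies resolve to p = 1 when the mean difference is
  also zero (no evidence of a difference) and p = 0 otherwise (a
  deterministic difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import LOG2_INTENSITY, AccessibilityMatrix, SampleRecord

# ---------------------------------------------------------------------------
# Threshold families (defaults as used for the three contrast kinds)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdFamily:
    min_abs_log2fc: float | None = None
    max_p: float | None = None
    max_fdr: float | None = None
    min_mean: float | None = None
    paired: bool = False

    def survives(self, log2fc: float, p: float, fdr: float, mean_all: float) -> bool:
        if self.min_abs_log2fc is not None and not abs(log2fc) > self.min_abs_log2fc:
            return False
        if self.max_p is not None and not p < self.max_p:
            return False
        if self.max_fdr is not None and not fdr < self.max_fdr:
            return False
        if self.min_mean is not None and not mean_all > self.min_mean:
            return False
        return True


#: disease-specific peaks: |log2FC| > 1, p < 0.001, FDR < 0.1
DISEASE_FAMILY = ThresholdFamily(min_abs_log2fc=1.0, max_p=0.001, max_fdr=0.1)
#: cell-type-specific peaks: |log2FC| > 4, p < 0.001, FDR < 0.01, mean > 3
CELLTYPE_FAMILY = ThresholdFamily(min_abs_log2fc=4.0, max_p=0.001, max_fdr=0.01, min_mean=3.0)
#: CRP-stimulation contrast: linear fold change > 1.5, p < 0.01, paired t
STIM_FOLD_CHANGE = 1.5
STIM_MAX_P = 0.01


@dataclass
class DifferentialRecord:
    region_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p: float
    fdr: float


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------


def t_test_two_sample(a, b, paired: bool = False, equal_variance: bool = True):
    """Two-sided two-sample t-test returning ``(t, p)``.

    Unpaired defaults to Student's equal-variance t; ``equal_variance=False``
    switches to Welch.  Paired requires equal lengths and tests the mean of
    the pairwise differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length samples")
        if len(a) < 2:
            raise ValueError("paired test requires >= 2 pairs")
        t, p = _paired_rows(a[None, :], b[None, :])
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 samples")
        t, p = _unpaired_rows(a[None, :], b[None, :], equal_variance)
    return float(t[0]), float(p[0])


def _unpaired_rows(a: np.ndarray, b: np.ndarray, equal_variance: bool = True):
    """Vectorized unpaired t over rows of two (m x n) arrays."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    if equal_variance:
        df = np.full(a.shape[0], n1 + n2 - 2, dtype=float)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = np.sqrt(se2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return _resolve_degenerate(t, p, diff, se)


def _paired_rows(a: np.ndarray, b: np.ndarray):
    """Vectorized paired t over rows of two (m x n) arrays."""
    d = a - b
    n = d.shape[1]
    m = d.mean(axis=1)
    s = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return _resolve_degenerate(t, p, m, s)


def _resolve_degenerate(t, p, diff, spread):
    zero_spread = spread == 0
    zero_diff = zero_spread & (diff == 0)
    det_diff = zero_spread & (diff != 0)
    t = np.where(zero_diff, 0.0, t)
    p = np.where(zero_diff, 1.0, p)
    t = np.where(det_diff, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(det_diff, 0.0, p)
    return t, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Contrast drivers
# ---------------------------------------------------------------------------


def _group_samples(metadata: list[SampleRecord], group: str) -> list[str]:
    return [s.sample_id for s in metadata if s.group == group]


def differential_table(
    matrix: AccessibilityMatrix,
    metadata: list[SampleRecord],
    group_a: str,
    group_b: str,
    family: ThresholdFamily = DISEASE_FAMILY,
    equal_variance: bool = True,
    samples_a: list[str] | None = None,
    samples_b: list[str] | None = None,
):
    """Per-region differential test of group_a vs group_b.

    Returns ``(records, survivors)`` where survivors is the set of region
    ids passing every bound in ``family``.  ``samples_a``/``samples_b``
    override the metadata group lookup (used for one-vs-rest contrasts).
    """
    if matrix.scale != LOG2_INTENSITY and not family.paired:
        raise ValueError("differential_table expects a log2 intensity matrix")
    ids_a = samples_a if samples_a is not None else _group_samples(metadata, group_a)
    ids_b = samples_b if samples_b is not None else _group_samples(metadata, group_b)
    if not ids_a:
        raise ValueError(f"group {group_a!r} absent from metadata")
    if not ids_b:
        raise ValueError(f"group {group_b!r} absent from metadata")
    a = matrix.subset_samples(ids_a).values
    b = matrix.subset_samples(ids_b).values
    if family.paired:
        if a.shape[1] != b.shape[1] or a.shape[1] < 2:
            raise ValueError("paired contrast requires >= 2 resolvable pairs")
        t, p = _paired_rows(a, b)
    else:
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("each group needs >= 2 samples")
        t, p = _unpaired_rows(a, b, equal_variance)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b
    fdr = bh_fdr(p)
    mean_all = matrix.values.mean(axis=1)
    records = [
        DifferentialRecord(rid, float(ma), float(mb), float(fc), float(pv), float(q))
        for rid, ma, mb, fc, pv, q in zip(
            matrix.region_ids, mean_a, mean_b, log2fc, p, fdr
        )
    ]
    survivors = {
        r.region_id
        for r, m in zip(records, mean_all)
        if family.survives(r.log2fc, r.p, r.fdr, float(m))
    }
    return records, survivors


def disease_differential_regions(
    matrix: AccessibilityMatrix,
    metadata: list[SampleRecord],
    groups: tuple[str, ...] = ("HD", "OA", "RA"),
    family: ThresholdFamily = DISEASE_FAMILY,
) -> set[str]:
    """Union of survivors over all pairwise group contrasts — the
    differential-region set that feeds signature clustering."""
    survivors: set[str] = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            _, surv = differential_table(matrix, metadata, groups[i], groups[j], family)
            survivors |= surv
    return survivors


def celltype_specific_peaks(
    matrix: AccessibilityMatrix,
    metadata: list[SampleRecord],
    family: ThresholdFamily = CELLTYPE_FAMILY,
) -> dict[str, set[str]]:
    """One-vs-rest contrast per cell type; returns the peaks MORE accessible
    in each cell type than in the rest (up-in-type survivors)."""
    by_type: dict[str, list[str]] = {}
    for s in metadata:
        by_type.setdefault(s.cell_type, []).append(s.sample_id)
    if len(by_type) < 2:
        raise ValueError("need >= 2 cell types")
    for ct, ids in by_type.items():
        if len(ids) < 2:
            raise ValueError(f"cell type {ct!r} has < 2 samples")
    out: dict[str, set[str]] = {}
    for ct, ids in by_type.items():
        rest = [s.sample_id for s in metadata if s.cell_type != ct]
        records, surv = differential_table(
            matrix, metadata, ct, "rest", family, samples_a=ids, samples_b=rest
        )
        up = {r.region_id for r in records if r.log2fc > 0}
        out[ct] = surv & up
    return out


def resolve_pairs(metadata: list[SampleRecord], group_a: str = "CRPstim",
                  group_b: str = "control") -> tuple[list[str], list[str]]:
    """Match stimulation/control samples through pair_id, in pair order."""
    a_by_pair = {s.pair_id: s.sample_id for s in metadata if s.group == group_a and s.pair_id}
    b_by_pair = {s.pair_id: s.sample_id for s in metadata if s.group == group_b and s.pair_id}
    unpaired = set(a_by_pair) ^ set(b_by_pair)
    if unpaired:
        raise ValueError(f"unpaired samples for pair ids {sorted(unpaired)}")
    n_a = sum(1 for s in metadata if s.group == group_a)
    if n_a != len(a_by_pair):
        raise ValueError(f"samples in group {group_a!r} without pair_id")
    pairs = sorted(a_by_pair)
    return [a_by_pair[p] for p in pairs], [b_by_pair[p] for p in pairs]


def stim_contrast(
    matrix: AccessibilityMatrix,
    metadata: list[SampleRecord],
    fold_change: float = STIM_FOLD_CHANGE,
    max_p: float = STIM_MAX_P,
):
    """Paired stimulation-vs-control contrast per region.

    Fold change is evaluated on the linear scale as 2**log2fc; survivors
    split into up (fc > 1.5) and down (fc < 1/1.5), both at p < 0.01.
    Returns ``(records, up, down)``.
    """
    stim_ids, ctrl_ids = resolve_pairs(metadata)
    if len(stim_ids) < 2:
        raise ValueError("need >= 2 control/stimulation pairs")
    family = ThresholdFamily(paired=True)
    records, _ = differential_table(
        matrix, metadata, "CRPstim", "control", family,
        samples_a=stim_ids, samples_b=ctrl_ids,
    )
    log2_threshold = np.log2(fold_change)
    up = {r.region_id for r in records if r.p < max_p and r.log2fc > log2_threshold}
    down = {r.region_id for r in records if r.p < max_p and r.log2fc < -log2_threshold}
    return records, up, down


def rna_de_filter(
    gene_table: pd.DataFrame,
    fold_change: float = 1.5,
    max_p: float = 0.05,
    min_total_counts: float = 5.0,
) -> set[str]:
    """Differential-expression filter: linear fold change > 1.5, p < 0.05,
    and summed counts across samples > 5 (all strict).

    ``gene_table`` columns: gene, log2fc, p, total_counts.
    """
    if gene_table.empty:
        return set()
    for col in ("gene", "log2fc", "p", "total_counts"):
        if col not in gene_table.columns:
            raise ValueError(f"gene table missing column {col!r}")
    fc = 2.0 ** gene_table["log2fc"].to_numpy(dtype=float)
    keep = (
        (fc > fold_change)
        & (gene_table["p"].to_numpy(dtype=float) < max_p)
        & (gene_table["total_counts"].to_numpy(dtype=float) > min_total_counts)
    )
    return set(gene_table.loc[keep, "gene"].astype(str))


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"region_id": r.region_id, "mean_a": r.mean_a, "mean_b": r.mean_b,
             "log2fc": r.log2fc, "p": r.p, "fdr": r.fdr}
            for r in records
        ]
    )
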