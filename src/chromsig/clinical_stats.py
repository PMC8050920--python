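"""Clinical statistics: OLS of signature scores against clinical covariates
(CRP, DAS28 composites, joint counts, serology), score group comparisons,
and qPCR 2^(-ddCT) relative quantification.

Missing covariate values are handled by pairwise-complete deletion; they are
never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .differential import bh_fdr, t_test_two_sample
from .io_formats import CLINICAL_COVARIATES, SampleRecord
from .signature import SampleScore

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class RegressionFit:
    covariate: str
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n_used: int
    significant: bool = False


def ols_fit(x, y, covariate: str = "x") -> RegressionFit:
    """Simple least squares of score on covariate with the slope's two-sided
    t-test p (n - 2 df) and R^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete (x, y) pairs, got {n}")
    if np.all(x == x[0]):
        raise ValueError("constant covariate: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    # a constant response has SStot == 0; define R^2 = 0, slope exactly 0
    if np.all(y == y[0]):
        return RegressionFit(covariate, 0.0, float(y[0]), 0.0, 1.0, n)
    fit = RegressionFit(
        covariate, float(slope), float(intercept),
        float(model.rsquared), float(model.pvalues[1]), n,
    )
    fit.significant = fit.p_slope < SIGNIFICANCE_LEVEL
    return fit


def score_vs_clinical(
    scores: list[SampleScore],
    metadata: list[SampleRecord],
    covariates=CLINICAL_COVARIATES,
    adjust: bool = False,
) -> list[RegressionFit]:
    """One OLS fit of score on each covariate, over samples where that
    covariate is present.  ``adjust=True`` applies BH across the fits."""
    score_of = {s.sample_id: s.score for s in scores}
    fits: list[RegressionFit] = []
    for cov in covariates:
        x, y = [], []
        for rec in metadata:
            if rec.sample_id not in score_of:
                continue
            val = rec.clinical.get(cov, float("nan"))
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            x.append(val)
            y.append(score_of[rec.sample_id])
        if len(x) < 3 or (x and all(v == x[0] for v in x)):
            logger.warning("covariate %s: insufficient non-missing values; fit omitted", cov)
            continue
        fits.append(ols_fit(x, y, covariate=cov))
    if adjust and fits:
        q = bh_fdr([f.p_slope for f in fits])
        for f, qv in zip(fits, q):
            f.significant = qv < SIGNIFICANCE_LEVEL
    return fits


def compare_scores(
    scores: list[SampleScore],
    metadata: list[SampleRecord],
    group_a: str,
    group_b: str,
    paired: bool = False,
):
    """t-test of scores between two groups; returns ``(t, p, direction)``
    with direction the sign of mean(a) - mean(b).  Paired comparisons are
    ordered by pair_id."""
    score_of = {s.sample_id: s.score for s in scores}
    if paired:
        a_by_pair = {r.pair_id: r.sample_id for r in metadata
                     if r.group == group_a and r.pair_id}
        b_by_pair = {r.pair_id: r.sample_id for r in metadata
                     if r.group == group_b and r.pair_id}
        shared = sorted(set(a_by_pair) & set(b_by_pair))
        a = [score_of[a_by_pair[p]] for p in shared]
        b = [score_of[b_by_pair[p]] for p in shared]
    else:
        a = [score_of[r.sample_id] for r in metadata
             if r.group == group_a and r.sample_id in score_of]
        b = [score_of[r.sample_id] for r in metadata
             if r.group == group_b and r.sample_id in score_of]
    t, p = t_test_two_sample(a, b, paired=paired)
    direction = int(np.sign(np.mean(a) - np.mean(b)))
    return t, p, direction


def ddct_fold_change(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the standard 2^(-ddCT) rule: ddCT =
    (Ct_target - Ct_reference)_condition - (Ct_target - Ct_reference)_control."""
    for v in (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
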