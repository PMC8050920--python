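"""Motif scanning and enrichment, and pre-ranked GSEA.

Motif occurrences come from log-odds PWM scanning of peak sequences on both
strands; enrichment of a motif in a target region set against a background
set is a one-sided hypergeometric test on region presence/absence, BH
corrected across motifs.  GSEA is the classic weighted Kolmogorov-Smirnov
running sum over a descending-ranked gene statistic, with a gene-sampling
permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .io_formats import MotifModel

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NEGLOG10_CAP = 300.0


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    region_id: str
    offset: int  # 0-based match start on the forward strand
    strand: str  # '+' or '-'
    score: float


@dataclass
class EnrichmentScore:
    name: str
    es: float
    p: float
    n_perm: int


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------


def pwm_from_counts(motif: MotifModel, pseudocount: float = 0.25) -> np.ndarray:
    """Log-odds position weight matrix:
    w[b, j] = log2((counts[b, j] + pc) / sum_b(counts[., j] + pc)) - log2(bg[b])."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = motif.counts + pseudocount
    probs = c / c.sum(axis=0, keepdims=True)
    return np.log2(probs) - np.log2(motif.background)[:, None]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_one_strand(seq: str, pwm: np.ndarray) -> np.ndarray:
    """Score every offset of ``seq`` against the PWM; N scores the minimum
    column weight.  Returns an array of length len(seq) - W + 1."""
    w = pwm.shape[1]
    n = len(seq)
    if n < w:
        return np.empty(0)
    col_min = pwm.min(axis=0)
    # per-position base weights for each motif column
    scores = np.zeros(n - w + 1)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    for j in range(w):
        col = idx[j: j + n - w + 1]
        vals = np.where(col >= 0, pwm[np.clip(col, 0, 3), j], col_min[j])
        scores += vals
    return scores


def scan_sequences(
    sequences: dict[str, str],
    motif: MotifModel,
    score_fraction: float = 0.8,
    pseudocount: float = 0.25,
) -> list[MotifHit]:
    """Scan both strands of each sequence; report hits scoring at least
    ``score_fraction`` of the maximum attainable log-odds score.

    Minus-strand hits are reported at the offset of the match start on the
    forward strand.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    pwm = pwm_from_counts(motif, pseudocount)
    w = pwm.shape[1]
    threshold = score_fraction * pwm.max(axis=0).sum()
    hits: list[MotifHit] = []
    for region_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < w:
            logger.warning("sequence %s shorter than motif width %d; skipped",
                           region_id, w)
            continue
        fwd = _scan_one_strand(seq, pwm)
        for off in np.flatnonzero(fwd >= threshold):
            hits.append(MotifHit(motif.motif_id, region_id, int(off), "+", float(fwd[off])))
        rc = reverse_complement(seq)
        rev = _scan_one_strand(rc, pwm)
        for off in np.flatnonzero(rev >= threshold):
            fwd_off = len(seq) - int(off) - w
            hits.append(MotifHit(motif.motif_id, region_id, fwd_off, "-", float(rev[off])))
    return hits


# ---------------------------------------------------------------------------
# Motif enrichment
# ---------------------------------------------------------------------------


def motif_enrichment(
    target_regions,
    background_regions,
    hits: list[MotifHit],
    background_includes_target: bool = False,
) -> pd.DataFrame:
    """Per-motif hypergeometric enrichment of target vs background regions.

    A region "has" a motif if it carries >= 1 hit.  The universe is
    target + background; by default background must exclude the target
    (``background_includes_target=True`` subtracts it first).  Returns a
    DataFrame ranked by p with columns motif_id, n_target_hit, n_bg_hit,
    fold, p, fdr.
    """
    target = set(target_regions)
    if not target:
        raise ValueError("empty target region set")
    background = set(background_regions)
    if background_includes_target:
        background = background - target
    elif background & target:
        raise ValueError("background overlaps target; "
                         "pass background_includes_target=True to subtract it")
    universe = target | background
    n_universe, n_target = len(universe), len(target)

    regions_with: dict[str, set[str]] = {}
    for h in hits:
        regions_with.setdefault(h.motif_id, set()).add(h.region_id)

    rows = []
    for motif_id, with_motif in sorted(regions_with.items()):
        with_motif = with_motif & universe
        k = len(with_motif & target)
        n_bg = len(with_motif & background)
        big_k = len(with_motif)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_target))
        expected = big_k * n_target / n_universe
        fold = k / expected if expected > 0 else float("nan")
        rows.append({"motif_id": motif_id, "n_target_hit": k, "n_bg_hit": n_bg,
                     "fold": fold, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["motif_id", "n_target_hit", "n_bg_hit", "fold", "p"])
    if not df.empty:
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


def motif_significance_matrix(
    region_sets: dict[str, set],
    background_regions,
    hits: list[MotifHit],
    background_includes_target: bool = True,
) -> pd.DataFrame:
    """Motif x set matrix of -log10 enrichment p (capped at 300), each set
    tested against the common background."""
    if not region_sets:
        raise ValueError("need >= 1 region set")
    columns: dict[str, pd.Series] = {}
    for name, regions in region_sets.items():
        df = motif_enrichment(
            regions, background_regions, hits,
            background_includes_target=background_includes_target,
        )
        with np.errstate(divide="ignore"):
            neglog = -np.log10(df["p"].to_numpy())
        columns[name] = pd.Series(np.minimum(neglog, NEGLOG10_CAP),
                                  index=df["motif_id"])
    return pd.DataFrame(columns).fillna(0.0)


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------


def _as_ranked_series(ranked) -> pd.Series:
    if isinstance(ranked, pd.Series):
        s = ranked.copy()
    else:
        s = pd.Series(dict(ranked))
    s.index = s.index.str.upper()
    if s.index.duplicated().any():
        raise ValueError("duplicate genes in ranked list")
    return s.sort_values(ascending=False, kind="mergesort")


def _es_core(stats_desc: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Weighted KS running-sum ES on a descending statistic vector and a
    boolean membership mask."""
    n, n_hits = len(stats_desc), int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")
    hit_weights = np.abs(stats_desc) ** weight
    n_r = float(hit_weights[in_set].sum())
    if n_r == 0:
        raise ValueError("all in-set statistics are zero: hit weight undefined")
    # keep the miss ladder as exact integer ratios so that deviations that
    # are equal in exact arithmetic stay equal in floating point
    hit_cum = np.cumsum(np.where(in_set, hit_weights, 0.0)) / n_r
    miss_cum = np.cumsum(~in_set) / (n - n_hits)
    running = hit_cum - miss_cum
    # tie rule: positive and negative extremes of equal magnitude can occur
    # (e.g. a symmetric running sum); take the earliest extreme, judged with
    # a small tolerance so the choice is stable under float rounding
    absrun = np.abs(running)
    idx = int(np.argmax(absrun >= absrun.max() - 1e-9))
    return float(running[idx])


def gsea_es(ranked, gene_set, weight: float = 1.0) -> float:
    """Enrichment score: signed value of the weighted KS running sum at its
    maximal absolute deviation.

    Hits increment by \\|stat|^weight / N_R (N_R = total hit weight), misses
    decrement by 1 / (N - N_hits); the list is ranked descending.
    """
    s = _as_ranked_series(ranked)
    genes = {g.upper() for g in (gene_set.genes if hasattr(gene_set, "genes") else gene_set)}
    return _es_core(s.to_numpy(), s.index.isin(genes), weight)


def gsea_pvalue(
    ranked,
    gene_set,
    n_perm: int = 1000,
    seed: int = 17,
    weight: float = 1.0,
) -> EnrichmentScore:
    """Permutation p for the enrichment score: null ES from random gene sets
    of equal size drawn without replacement from the ranked genes;
    p = (1 + #{|ES_null| >= |ES_obs|}) / (1 + n_perm)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    s = _as_ranked_series(ranked)
    genes = {g.upper() for g in (gene_set.genes if hasattr(gene_set, "genes") else gene_set)}
    name = gene_set.name if hasattr(gene_set, "name") else "gene_set"
    stats_desc = s.to_numpy()
    obs_mask = s.index.isin(genes)
    es_obs = _es_core(stats_desc, obs_mask, weight)
    size = int(obs_mask.sum())
    rng = np.random.default_rng(seed)
    n = len(stats_desc)
    exceed = 0
    for _ in range(n_perm):
        null_mask = np.zeros(n, dtype=bool)
        null_mask[rng.choice(n, size=size, replace=False)] = True
        if abs(_es_core(stats_desc, null_mask, weight)) >= abs(es_obs):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return EnrichmentScore(name, es_obs, p, n_perm)
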