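"""Region-to-gene association and set-level annotation.

Genes get a regulatory domain by the basal-plus-extension rule: a fixed
basal window around the TSS (5 kb upstream / 1 kb downstream by default,
strand-aware), extended on each side up to a cap (1 Mb) but stopping at the
nearest neighboring gene's basal domain.  A peak is associated with every
gene whose domain it overlaps by >= 1 bp.  Gene-set association is tested
with a one-sided Fisher exact test; chromatin-state composition of a peak
set is summarized from a precomputed state segmentation BED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenomicRegion, TssRecord

BASAL_UP = 5_000
BASAL_DOWN = 1_000
MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class RegulatoryDomain:
    gene: str
    chrom: str
    basal_start: int
    basal_end: int
    domain_start: int
    domain_end: int


def build_domains(
    tss_records: list[TssRecord],
    basal_up: int = BASAL_UP,
    basal_down: int = BASAL_DOWN,
    max_extension: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains, one per gene.

    Basal window: [tss - basal_up, tss + basal_down) on +, mirrored on -.
    Extension: each side grows up to ``max_extension`` beyond the basal
    boundary but stops at the nearest neighboring basal domain; always
    contains the basal window; clipped at position 0.
    """
    genes = [t.gene for t in tss_records]
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        raise ValueError(f"duplicate gene {dup!r} in TSS table")

    basal: dict[str, tuple[int, int]] = {}
    for t in tss_records:
        if t.strand == "+":
            s, e = t.tss - basal_up, t.tss + basal_down
        else:
            s, e = t.tss - basal_down, t.tss + basal_up
        basal[t.gene] = (max(0, s), e)

    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)

    domains: list[RegulatoryDomain] = []
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda t: basal[t.gene][0])
        for i, t in enumerate(recs):
            bs, be = basal[t.gene]
            left_cap = max(0, bs - max_extension)
            right_cap = be + max_extension
            prev_end = max((basal[r.gene][1] for r in recs[:i]), default=0)
            next_start = min((basal[r.gene][0] for r in recs[i + 1:]), default=right_cap)
            ds = min(bs, max(left_cap, prev_end))
            de = max(be, min(right_cap, next_start))
            domains.append(RegulatoryDomain(t.gene, chrom, bs, be, ds, de))
    return domains


def associate(
    regions: list[GenomicRegion],
    domains: list[RegulatoryDomain],
) -> dict[str, set[str]]:
    """Map each region to every gene whose regulatory domain it overlaps by
    at least 1 bp (half-open overlap); regions with no overlap map to the
    empty set."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda d: d.domain_start)

    out: dict[str, set[str]] = {}
    for r in regions:
        hits: set[str] = set()
        for d in by_chrom.get(r.chrom, []):
            if d.domain_start >= r.end:
                break
            if d.domain_end > r.start:
                hits.add(d.gene)
        out[r.region_id] = hits
    return out


def associated_genes(region_gene_map: dict[str, set[str]]) -> set[str]:
    """Union of genes over a region-to-gene map (the peak-related genes)."""
    genes: set[str] = set()
    for g in region_gene_map.values():
        genes |= g
    return genes


def geneset_overlap_test(genes_a, genes_b, universe):
    """One-sided (enrichment) Fisher exact test on the overlap of two gene
    sets within a universe.  Returns ``(overlap, fold, p)`` with fold =
    observed / expected overlap."""
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    a = {g.upper() for g in genes_a} & universe
    b = {g.upper() for g in genes_b} & universe
    n = len(universe)
    overlap = len(a & b)
    # hypergeometric upper tail: P(X >= overlap) drawing |a| from n with |b| marked
    p = float(stats.hypergeom.sf(overlap - 1, n, len(b), len(a)))
    expected = len(a) * len(b) / n
    fold = overlap / expected if expected > 0 else float("nan")
    return overlap, fold, min(p, 1.0)


def state_overlap(
    regions: list[GenomicRegion],
    state_regions: list[GenomicRegion],
) -> dict[str, dict[str, float]]:
    """Chromatin-state composition of a peak set.

    ``state_regions`` is a segmentation BED whose name column carries the
    state label.  Returns per state the total bp of overlap and the fraction
    of peaks intersecting it; a peak overlapping several states counts once
    for each.
    """
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for s in state_regions:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda s: s.start)

    states = sorted({s.region_id for s in state_regions})
    bp = {st: 0 for st in states}
    n_regions_hit = {st: 0 for st in states}
    for r in regions:
        seen: set[str] = set()
        for s in by_chrom.get(r.chrom, []):
            if s.start >= r.end:
                break
            ov = min(r.end, s.end) - max(r.start, s.start)
            if ov > 0:
                bp[s.region_id] += ov
                seen.add(s.region_id)
        for st in seen:
            n_regions_hit[st] += 1
    n = len(regions)
    return {
        st: {
            "bp_overlap": float(bp[st]),
            "fraction_regions": (n_regions_hit[st] / n) if n else 0.0,
        }
        for st in states
    }
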