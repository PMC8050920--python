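"""Seeded synthetic-cohort generators with known ground truth.

The generators emulate the statistical structure of a three-arm ATAC-seq
cohort (healthy donors HD, osteoarthritis OA, rheumatoid arthritis RA, one
cell type at a time): log2-scale peak intensities with three planted
differential clusters (C1 high in HD, C2 high in OA and RA, C3 high in RA
only), a serum CRP covariate linearly coupled to each RA sample's C3
elevation, paired control/CRP-stimulation samples sharing donor baselines,
motif instances planted preferentially in target peaks, and Tn5 insertion
tracks with flanking enrichment and a centered, tapered depletion at motif
sites.

Every generator is a pure function of its config and seed, and everything
it emits is a valid input to the :mod:`chromsig.io_formats` readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .footprint import GenomicSite
from .io_formats import (
    AccessibilityMatrix,
    GeneSet,
    GenomicRegion,
    InsertionTrack,
    MotifModel,
    SampleRecord,
    TssRecord,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gmt,
    write_jaspar,
    write_matrix,
    write_metadata,
    write_tss,
)

PEAK_WIDTH = 500
PEAK_SPACING = 5_000
_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for the three-arm cohort.

    Arm sizes match the study design (14 healthy-donor profiles, 23 OA and
    26 RA patients); effect size and noise are in log2-intensity units.
    ``severity_sd`` spreads each RA sample's C3 effect around 1x (disease
    heterogeneity), which is what couples CRP to a per-sample signal.
    """

    n_peaks: int = 20_000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HD": 14, "OA": 23, "RA": 26}
    )
    cluster_sizes: tuple[int, int, int] = (500, 500, 500)
    effect_size: float = 1.5
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    severity_sd: float = 0.3
    crp_intercept: float = 4.0     # mg/L
    crp_coupling: float = 12.0     # mg/L per log2-unit of C3 elevation
    crp_noise_sd: float = 3.0      # mg/L
    crp_baseline_mean: float = 3.0  # OA / HD arms
    crp_baseline_sd: float = 2.0
    n_chry_peaks: int = 100
    cell_type: str = "monocyte"
    seed: int = 17

    def validate(self) -> None:
        if sum(self.cluster_sizes) >= self.n_peaks:
            raise ValueError("cluster sizes must sum to < n_peaks")
        for name in ("noise_sd", "baseline_sd", "severity_sd",
                     "crp_noise_sd", "crp_baseline_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs >= 2 samples")


@dataclass
class StimConfig:
    """Paired in-vitro CRP stimulation design: control/stimulated monocytes
    from the same donors (five biological replicates by default), with the
    C3-truth peaks shifted up in the stimulated arm."""

    n_peaks: int = 20_000
    n_pairs: int = 5
    cluster_sizes: tuple[int, int, int] = (500, 500, 500)
    stim_effect: float = 1.0   # log2 shift on C3 peaks in the stimulated arm
    noise_sd: float = 0.5
    donor_sd: float = 0.3
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    cell_type: str = "monocyte"
    seed: int = 17

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need >= 2 pairs")
        if sum(self.cluster_sizes) >= self.n_peaks:
            raise ValueError("cluster sizes must sum to < n_peaks")


@dataclass
class MotifConfig:
    n_target: int = 100
    n_background: int = 400
    seq_length: int = 200
    motif_width: int = 8
    target_fraction: float = 0.9
    background_fraction: float = 0.1
    n_decoys: int = 5
    seed: int = 17

    def validate(self) -> None:
        for f in (self.target_fraction, self.background_fraction):
            if not 0 <= f <= 1:
                raise ValueError("planted fractions must lie in [0, 1]")
        if self.seq_length < self.motif_width:
            raise ValueError("sequences shorter than the motif")


@dataclass
class TrackConfig:
    """Tn5 insertion-track model: Poisson counts at rate ``background_rate``
    away from sites, ``background_rate * flank_factor`` within the
    accessible peak around each site (``flank_extent`` spans the whole
    aggregation window, since motif sites sit inside called peaks), and a
    depletion at the site center that is maximal there and tapers linearly
    to zero at ±``depletion_halfwidth`` (a bound factor's footprint).  The
    stimulated arm uses a larger flank factor."""

    n_sites: int = 200
    background_rate: float = 10.0
    flank_factor: float = 2.0
    stim_flank_factor: float = 3.0
    depletion: float = 0.6       # in [0, 1)
    depletion_halfwidth: int = 10
    flank_extent: int = 120      # peaks span the whole aggregation window
    site_spacing: int = 1_000
    chrom: str = "chr1"
    seed: int = 17

    def validate(self) -> None:
        if self.n_sites < 50:
            raise ValueError("need >= 50 sites")
        if not 0 <= self.depletion < 1:
            raise ValueError("depletion must lie in [0, 1)")


@dataclass
class GeneContextConfig:
    n_genes: int = 300
    planted_set_size: int = 40
    n_random_sets: int = 5
    random_set_size: int = 30
    planted_overlap_fraction: float = 1.0  # fraction of C3 peaks put in planted domains
    de_strength: float = 2.0               # mean shift of planted genes' DE statistic
    seed: int = 17

    def validate(self) -> None:
        if self.n_genes < 100:
            raise ValueError("need >= 100 genes")
        if self.planted_set_size >= self.n_genes:
            raise ValueError("planted set must be smaller than the gene universe")


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _peak_layout(n_peaks: int, n_chry: int = 0) -> list[GenomicRegion]:
    """Deterministic non-overlapping peak coordinates across the autosomes
    (plus optional chrY peaks, which the normalization stage should drop)."""
    regions = []
    for i in range(n_peaks):
        chrom = _AUTOSOMES[i % len(_AUTOSOMES)]
        start = 10_000 + (i // len(_AUTOSOMES)) * PEAK_SPACING
        regions.append(GenomicRegion(chrom, start, start + PEAK_WIDTH))
    for i in range(n_chry):
        start = 10_000 + i * PEAK_SPACING
        regions.append(GenomicRegion("chrY", start, start + PEAK_WIDTH))
    return regions


def _cluster_assignment(n_peaks: int, cluster_sizes) -> dict[int, str]:
    """First |C1| peaks are C1, the next |C2| are C2, then |C3| are C3."""
    labels = {}
    c1, c2, c3 = cluster_sizes
    for i in range(c1):
        labels[i] = "C1"
    for i in range(c1, c1 + c2):
        labels[i] = "C2"
    for i in range(c1 + c2, c1 + c2 + c3):
        labels[i] = "C3"
    return labels


def _log2_to_counts(log2_values: np.ndarray) -> np.ndarray:
    """Emit raw counts whose log2(c + 1) round-trips to ~ the intended
    intensities, so the pipeline's own normalization path is exercised."""
    return np.maximum(np.round(2.0 ** log2_values - 1.0), 0.0)


@dataclass
class TruthTable:
    peak_clusters: dict[str, str | None]
    sample_groups: dict[str, str]
    true_crp: dict[str, float] = field(default_factory=dict)
    severity: dict[str, float] = field(default_factory=dict)

    def cluster_regions(self, label: str) -> set[str]:
        return {rid for rid, lab in self.peak_clusters.items() if lab == label}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig | None = None, outdir: str | None = None):
    """Three-arm cohort: raw-count matrix, metadata with CRP (coupled to the
    C3 truth signal in RA) and an independent ESR covariate, peak BED, and
    the truth table.  Returns ``(matrix, metadata, regions, truth)``."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    regions = _peak_layout(config.n_peaks, config.n_chry_peaks)
    cluster_of = _cluster_assignment(config.n_peaks, config.cluster_sizes)
    n_total_peaks = len(regions)

    samples: list[SampleRecord] = []
    groups_expanded: list[str] = []
    for group in ("HD", "OA", "RA"):
        for i in range(config.group_sizes[group]):
            samples.append(SampleRecord(f"{group}_{i + 1:02d}", config.cell_type, group))
            groups_expanded.append(group)
    n_samples = len(samples)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_total_peaks)
    severity = {
        s.sample_id: (
            max(0.1, rng.normal(1.0, config.severity_sd)) if s.group == "RA" else 0.0
        )
        for s in samples
    }

    log2 = baseline[:, None] + rng.normal(0.0, config.noise_sd,
                                          size=(n_total_peaks, n_samples))
    group_arr = np.array(groups_expanded)
    c1, c2, c3 = config.cluster_sizes
    sev = np.array([severity[s.sample_id] for s in samples])  # 0 outside RA
    log2[:c1, :] += config.effect_size * (group_arr == "HD")[None, :]
    log2[c1:c1 + c2, :] += config.effect_size * np.isin(group_arr, ("OA", "RA"))[None, :]
    log2[c1 + c2:c1 + c2 + c3, :] += config.effect_size * sev[None, :]

    true_crp = {}
    for s in samples:
        if s.group == "RA":
            signal = config.effect_size * severity[s.sample_id]
            crp = (config.crp_intercept + config.crp_coupling * signal
                   + rng.normal(0.0, config.crp_noise_sd))
        else:
            crp = rng.normal(config.crp_baseline_mean, config.crp_baseline_sd)
        crp = max(0.1, crp)
        s.clinical["CRP"] = crp
        s.clinical["ESR"] = max(1.0, rng.normal(20.0, 10.0))  # decoupled covariate
        true_crp[s.sample_id] = crp

    counts = _log2_to_counts(log2)
    matrix = AccessibilityMatrix(regions, [s.sample_id for s in samples], counts)

    truth = TruthTable(
        peak_clusters={
            r.region_id: cluster_of.get(i) if i < config.n_peaks else None
            for i, r in enumerate(regions)
        },
        sample_groups={s.sample_id: s.group for s in samples},
        true_crp=true_crp,
        severity=severity,
    )
    if outdir:
        _write_cohort(outdir, matrix, samples, regions)
    return matrix, samples, regions, truth


def _write_cohort(outdir, matrix, samples, regions):
    os.makedirs(outdir, exist_ok=True)
    write_matrix(os.path.join(outdir, "counts.tsv"), matrix)
    write_metadata(os.path.join(outdir, "metadata.tsv"), samples)
    write_bed(os.path.join(outdir, "peaks.bed"), regions)


def generate_stim_pairs(config: StimConfig | None = None, outdir: str | None = None):
    """Paired control/CRP-stimulation samples sharing donor baselines; the
    stimulated arm's C3-truth peaks are shifted up by ``stim_effect``.
    Returns ``(matrix, metadata, regions, truth)``."""
    config = config or StimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    regions = _peak_layout(config.n_peaks)
    cluster_of = _cluster_assignment(config.n_peaks, config.cluster_sizes)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_peaks)
    c3_mask = np.array([cluster_of.get(i) == "C3" for i in range(config.n_peaks)])

    samples: list[SampleRecord] = []
    columns = []
    for d in range(config.n_pairs):
        pair = f"P{d + 1:02d}"
        donor = baseline + rng.normal(0.0, config.donor_sd, size=config.n_peaks)
        ctrl = donor + rng.normal(0.0, config.noise_sd, size=config.n_peaks)
        stim = donor + rng.normal(0.0, config.noise_sd, size=config.n_peaks)
        stim[c3_mask] += config.stim_effect
        samples.append(SampleRecord(f"ctrl_{pair}", config.cell_type, "control", pair_id=pair))
        columns.append(ctrl)
        samples.append(SampleRecord(f"stim_{pair}", config.cell_type, "CRPstim", pair_id=pair))
        columns.append(stim)

    counts = _log2_to_counts(np.column_stack(columns))
    matrix = AccessibilityMatrix(regions, [s.sample_id for s in samples], counts)
    truth = TruthTable(
        peak_clusters={r.region_id: cluster_of.get(i) for i, r in enumerate(regions)},
        sample_groups={s.sample_id: s.group for s in samples},
    )
    if outdir:
        _write_cohort(outdir, matrix, samples, regions)
    return matrix, samples, regions, truth


_BASES = np.array(list("ACGT"))


def _random_kmer(rng, width: int) -> str:
    return "".join(rng.choice(_BASES, size=width))


def _consensus_pfm(motif_id: str, consensus: str, strength: float = 97.0) -> MotifModel:
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strength
    return MotifModel(motif_id, counts)


def generate_motif_data(config: MotifConfig | None = None, outdir: str | None = None):
    """Random peak sequences with a consensus motif embedded in a fraction
    of target and background peaks, plus decoy motifs planted nowhere.

    Returns ``(sequences, motifs, target_ids, background_ids, truth_hits)``
    where truth_hits maps region_id -> (offset, strand) of the plant.
    """
    config = config or MotifConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    consensus = _random_kmer(rng, config.motif_width)
    motifs = [_consensus_pfm("PLANTED", consensus)]
    for i in range(config.n_decoys):
        motifs.append(_consensus_pfm(f"DECOY_{i + 1}", _random_kmer(rng, config.motif_width)))

    sequences: dict[str, str] = {}
    truth_hits: dict[str, tuple[int, str]] = {}

    def emit(prefix, n, fraction):
        ids = []
        for i in range(n):
            rid = f"{prefix}_{i + 1:04d}"
            seq = list(_random_kmer(rng, config.seq_length))
            if rng.random() < fraction:
                off = int(rng.integers(0, config.seq_length - config.motif_width + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                planted = consensus
                if strand == "-":
                    from .enrichment import reverse_complement
                    planted = reverse_complement(consensus)
                seq[off: off + config.motif_width] = list(planted)
                truth_hits[rid] = (off, strand)
            sequences[rid] = "".join(seq)
            ids.append(rid)
        return ids

    target_ids = emit("target", config.n_target, config.target_fraction)
    background_ids = emit("bg", config.n_background, config.background_fraction)

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(os.path.join(outdir, "peaks.fa"), sequences)
        write_jaspar(os.path.join(outdir, "motifs.pfm"), motifs)
    return sequences, motifs, target_ids, background_ids, truth_hits


def generate_insertion_tracks(config: TrackConfig | None = None, outdir: str | None = None):
    """Per-arm Tn5 insertion tracks around planted binding sites.

    Expected rate: ``background_rate`` away from sites; ``rate * f`` on the
    flanks out to ±``flank_extent``; within ±``depletion_halfwidth`` the
    rate is additionally suppressed by ``depletion * (1 - |offset| / hw)``
    so the footprint is deepest exactly at the site center.  The stimulated
    arm uses ``stim_flank_factor``.  Returns ``(tracks, sites, config)``
    with tracks a dict arm-name -> InsertionTrack.
    """
    config = config or TrackConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sites = [
        GenomicSite(config.chrom, 500 + i * config.site_spacing, "+")
        for i in range(config.n_sites)
    ]

    window = 150  # simulate a little beyond the usual ±100 aggregation flank
    offsets = np.arange(-window, window + 1)
    hw = config.depletion_halfwidth

    def make_track(flank_factor: float) -> InsertionTrack:
        rate = np.full(offsets.shape, config.background_rate)
        flank_mask = np.abs(offsets) <= config.flank_extent
        rate[flank_mask] *= flank_factor
        dep_mask = np.abs(offsets) <= hw
        rate[dep_mask] *= 1.0 - config.depletion * (1.0 - np.abs(offsets[dep_mask]) / hw)
        counts = rng.poisson(np.tile(rate, (len(sites), 1)))
        track = InsertionTrack()
        for site, row in zip(sites, counts):
            chrom_counts = track.counts.setdefault(site.chrom, {})
            for off, count in zip(offsets, row):
                if count:
                    chrom_counts[site.center + int(off)] = (
                        chrom_counts.get(site.center + int(off), 0) + int(count)
                    )
        return track

    tracks = {
        "control": make_track(config.flank_factor),
        "CRPstim": make_track(config.stim_flank_factor),
    }
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        for arm, track in tracks.items():
            write_bedgraph(os.path.join(outdir, f"{arm}.bedGraph"), track)
    return tracks, sites, config


def generate_gene_context(
    c3_regions: list[GenomicRegion],
    config: GeneContextConfig | None = None,
    outdir: str | None = None,
):
    """TSS table, gene sets and a ranked DE statistic built around a set of
    RA-signature (C3) peaks.

    A planted gene set is positioned so that ``planted_overlap_fraction`` of
    the C3 peaks fall inside its genes' regulatory domains; the remaining
    genes are placed far away on a separate chromosome.  The ranked DE table
    shifts the planted genes' statistics up by ``de_strength``.

    Returns ``(tss_records, gene_sets, ranked_series, planted_genes)``.
    """
    import pandas as pd

    config = config or GeneContextConfig()
    config.validate()
    if not c3_regions:
        raise ValueError("need >= 1 C3 region")
    rng = np.random.default_rng(config.seed)

    gene_names = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    planted = gene_names[: config.planted_set_size]

    # anchor planted genes at C3 peak midpoints so associate() recovers them
    n_anchored = int(round(config.planted_overlap_fraction * len(c3_regions)))
    anchors = list(c3_regions[:n_anchored])
    tss_records: list[TssRecord] = []
    for i, gene in enumerate(planted):
        if anchors:
            peak = anchors[i % len(anchors)]
            tss_records.append(TssRecord(gene, peak.chrom, peak.midpoint(), "+"))
        else:
            tss_records.append(TssRecord(gene, "chrU", 10_000 + i * 3_000_000, "+"))
    for i, gene in enumerate(gene_names[config.planted_set_size:]):
        strand = "+" if i % 2 == 0 else "-"
        tss_records.append(TssRecord(gene, "chrU", 10_000 + i * 3_000_000, strand))

    gene_sets = [GeneSet("PLANTED_C3_SET", frozenset(planted))]
    others = gene_names[config.planted_set_size:]
    for k in range(config.n_random_sets):
        members = rng.choice(others, size=config.random_set_size, replace=False)
        gene_sets.append(GeneSet(f"RANDOM_SET_{k + 1}", frozenset(members)))

    stats = rng.normal(0.0, 1.0, size=config.n_genes)
    stats[: config.planted_set_size] += config.de_strength
    ranked = pd.Series(stats, index=gene_names).sort_values(ascending=False)

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        write_tss(os.path.join(outdir, "tss.tsv"), tss_records)
        write_gmt(os.path.join(outdir, "gene_sets.gmt"), gene_sets)
        ranked.rename("stat").to_csv(os.path.join(outdir, "ranked.tsv"), sep="\t",
                                     index_label="gene")
    return tss_records, gene_sets, ranked, set(planted)
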