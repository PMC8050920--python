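"""Readers and writers for the on-disk formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED-native) everywhere inside
the package; any 1-based external convention is converted at this boundary
and only here.  Gene symbols are upper-cased on ingest so gene sets, TSS
tables and association maps join case-insensitively.  Missing clinical
values are kept as NaN and never imputed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

RAW_COUNTS = "raw_counts"
LOG2_INTENSITY = "log2_intensity"

CELL_TYPES = {"monocyte", "B", "CD4T", "CD8T", "other"}
GROUPS = {"HD", "OA", "RA", "control", "CRPstim"}

#: clinical covariates recognised by the correlation stage
CLINICAL_COVARIATES = (
    "CRP", "DAS28-CRP", "DAS28-ESR", "ESR", "TCJ", "SCJ", "RF", "Anti-CCP",
)

_REGION_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    region_id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(f"end <= start in {self.chrom}:{self.start}-{self.end}")
        if not self.region_id:
            object.__setattr__(self, "region_id", f"{self.chrom}:{self.start}-{self.end}")

    @classmethod
    def from_id(cls, region_id: str) -> "GenomicRegion":
        m = _REGION_ID_RE.match(region_id)
        if m is None:
            raise ValueError(f"malformed region id {region_id!r}; expected chrom:start-end")
        return cls(m["chrom"], int(m["start"]), int(m["end"]), region_id)

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class AccessibilityMatrix:
    """Peak x sample matrix, the analysis spine.

    ``scale`` flags whether ``values`` are raw fragment counts or
    quantile-normalized log2 intensities; downstream statistics require the
    latter and refuse to run on the former.
    """

    regions: list[GenomicRegion]
    samples: list[str]
    values: np.ndarray  # regions x samples
    scale: str = RAW_COUNTS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.regions)}, {len(self.samples)})"
            )
        ids = self.region_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in matrix")
        if self.scale == RAW_COUNTS and np.any(self.values < 0):
            raise ValueError("negative raw counts")
        if self.scale not in (RAW_COUNTS, LOG2_INTENSITY):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def subset_regions(self, region_ids) -> "AccessibilityMatrix":
        wanted = set(region_ids)
        keep = [i for i, r in enumerate(self.regions) if r.region_id in wanted]
        missing = wanted - {self.regions[i].region_id for i in keep}
        if missing:
            raise KeyError(f"region ids not in matrix: {sorted(missing)[:5]}")
        return AccessibilityMatrix(
            [self.regions[i] for i in keep], list(self.samples),
            self.values[keep, :], self.scale,
        )

    def subset_samples(self, sample_ids) -> "AccessibilityMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return AccessibilityMatrix(
            list(self.regions), list(sample_ids), self.values[:, idx], self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.samples)


@dataclass
class SampleRecord:
    sample_id: str
    cell_type: str
    group: str
    pair_id: str | None = None
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for sample {self.sample_id}; "
                f"allowed: {sorted(GROUPS)}"
            )


@dataclass
class MotifModel:
    """A position frequency matrix over A,C,G,T with a background model."""

    motif_id: str
    counts: np.ndarray  # 4 x W
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x W")
        if self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"motif {self.motif_id}: empty column")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


class InsertionTrack:
    """Per-base Tn5 cleavage counts; absent positions are zero."""

    def __init__(self, counts: dict[str, dict[int, int]] | None = None):
        self.counts: dict[str, dict[int, int]] = counts or {}

    def add(self, chrom: str, pos: int, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative cleavage count at {chrom}:{pos}")
        self.counts.setdefault(chrom, {})
        self.counts[chrom][pos] = self.counts[chrom].get(pos, 0) + count

    def get(self, chrom: str, pos: int) -> int:
        return self.counts.get(chrom, {}).get(pos, 0)

    def window(self, chrom: str, center: int, flank: int) -> np.ndarray:
        """Counts at center-flank .. center+flank inclusive (length 2*flank+1)."""
        chrom_counts = self.counts.get(chrom, {})
        return np.array(
            [chrom_counts.get(p, 0) for p in range(center - flank, center + flank + 1)],
            dtype=float,
        )


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        object.__setattr__(self, "gene", self.gene.upper())
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for gene {self.gene}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicRegion]:
    """Read BED3/BED4; column 4, when present, becomes the region_id."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: fewer than 3 columns at line {lineno}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: non-integer coordinates at line {lineno}")
            if end <= start:
                raise ValueError(f"{path}: end <= start at line {lineno}")
            name = fields[3] if len(fields) >= 4 and fields[3] else ""
            regions.append(GenomicRegion(chrom, start, end, name))
    return regions


def write_bed(path, regions: list[GenomicRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_matrix(path) -> AccessibilityMatrix:
    """Read a TSV count matrix: header = sample ids, first column = region ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no regions")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate region id {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate sample id in header")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric cell at row {bad.index[0]!r}, column {col!r}"
            )
    regions = [GenomicRegion.from_id(rid) for rid in df.index]
    return AccessibilityMatrix(regions, list(df.columns), values, RAW_COUNTS)


def write_matrix(path, matrix: AccessibilityMatrix) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="region_id")


_META_FIXED = ("sample_id", "cell_type", "group", "pair_id")


def read_metadata(path) -> list[SampleRecord]:
    """Read the sample sheet; any column beyond the fixed ones is clinical."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "cell_type", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    clinical_cols = [c for c in df.columns if c not in _META_FIXED]
    records = []
    for _, row in df.iterrows():
        clinical = {}
        for c in clinical_cols:
            raw = row[c]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw) == "":
                clinical[c] = float("nan")
            else:
                clinical[c] = float(raw)
        pair = row.get("pair_id")
        if pair is not None and (not isinstance(pair, str) or pair == ""):
            pair = None
        records.append(
            SampleRecord(row["sample_id"], row["cell_type"], row["group"],
                         pair_id=pair, clinical=clinical)
        )
    return records


def write_metadata(path, records: list[SampleRecord]) -> None:
    clinical_cols: list[str] = []
    for r in records:
        for c in r.clinical:
            if c not in clinical_cols:
                clinical_cols.append(c)
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id, "cell_type": r.cell_type,
            "group": r.group, "pair_id": r.pair_id or "",
        }
        row.update({c: r.clinical.get(c, float("nan")) for c in clinical_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_jaspar(path) -> list[MotifModel]:
    """Parse JASPAR PFM text: '>' header, then 4 rows ``A [ 1 2 3 ]``."""
    motifs: list[MotifModel] = []
    with open(path) as fh:
        motif_id = None
        rows: list[list[float]] = []
        letters: list[str] = []

        def flush():
            if motif_id is None:
                return
            if len(rows) != 4:
                raise ValueError(f"{path}: motif {motif_id} has {len(rows)} rows, expected 4")
            order = [letters.index(b) for b in "ACGT"]
            motifs.append(MotifModel(motif_id, np.array([rows[i] for i in order])))

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows, letters = [], []
            else:
                m = re.match(r"^([ACGTacgt])\s*\[?\s*([-\d.\s]+?)\s*\]?$", line)
                if m is None:
                    raise ValueError(f"{path}: unparseable PFM row {line!r}")
                letters.append(m.group(1).upper())
                rows.append([float(x) for x in m.group(2).split()])
        flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def write_jaspar(path, motifs: list[MotifModel]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id}\n")
            for i, b in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in m.counts[i])
                fh.write(f"{b} [ {vals} ]\n")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(path, sets: list[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.genes)) + "\n")


def read_bedgraph(path) -> InsertionTrack:
    """4-column bedGraph; the value is an integer count applied to every base
    of the half-open interval, and overlapping intervals are summed."""
    track = InsertionTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: fewer than 4 columns at line {lineno}")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}: negative value at line {lineno}")
            count = int(round(value))
            if count == 0:
                continue
            for pos in range(start, end):
                track.add(chrom, pos, count)
    return track


def write_bedgraph(path, track: InsertionTrack) -> None:
    """Write one single-base interval per nonzero position (run-length merged)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            positions = sorted(track.counts[chrom])
            run_start = None
            run_val = None
            prev = None
            for pos in positions:
                val = track.counts[chrom][pos]
                if val == 0:
                    continue
                if run_start is not None and pos == prev + 1 and val == run_val:
                    prev = pos
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")
                run_start, run_val, prev = pos, val, pos
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA records keyed by id (the scan input; ids are peak region ids)."""
    from Bio import SeqIO

    sequences = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"{path}: no sequences")
    return sequences


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i: i + 80] + "\n")


def read_tss(path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "tss": int, "strand": str})
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    records = [TssRecord(r.gene, r.chrom, int(r.tss), r.strand) for r in df.itertuples()]
    genes = [r.gene for r in records]
    if len(set(genes)) != len(genes):
        dup = pd.Series(genes)[pd.Series(genes).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene {dup!r}")
    return records


def write_tss(path, records: list[TssRecord]) -> None:
    pd.DataFrame(
        [{"gene": r.gene, "chrom": r.chrom, "tss": r.tss, "strand": r.strand} for r in records]
    ).to_csv(path, sep="\t", index=False)
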