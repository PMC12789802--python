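"""Readers and writers for every on-disk format the pipeline touches.

All interval data are stored 0-based half-open internally, regardless of the
source dialect; BED-like files are read verbatim, 1-based table formats are
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell populations recognized by the pipeline.
POPULATIONS = (
    "HPC",
    "EarlyB",
    "NBC-B",
    "NBC-T",
    "GCBC",
    "MBC",
    "PB/PC",
    "cMCL",
    "nnMCL",
)

ASSAYS = ("methylation", "segmentation", "accessibility", "rnaseq")

#: ChromHMM-style chromatin states consumed by the classifier.
STATES = tuple(f"E{i}" for i in range(1, 13))

NA_MARKER = "NA"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# basic genomic records


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0:
            raise FormatError(f"negative start: {self}")
        if self.start >= self.end:
            raise FormatError(f"start must be < end: {self}")
        if self.strand not in (None, "+", "-"):
            raise FormatError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample, population, assay."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "assay"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"sample sheet needs columns {sorted(required)}")
    bad_pop = set(sheet["population"]) - set(POPULATIONS)
    if bad_pop:
        raise FormatError(f"unknown populations: {sorted(bad_pop)}")
    bad_assay = set(sheet["assay"]) - set(ASSAYS)
    if bad_assay:
        raise FormatError(f"unknown assays: {sorted(bad_assay)}")
    dup = sheet.duplicated(subset=["sample", "assay"])
    if dup.any():
        raise FormatError(
            f"duplicate (sample, assay) pairs: {sheet.loc[dup, 'sample'].tolist()}"
        )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def samples_for(sheet: pd.DataFrame, assay: str, population: str | None = None) -> list[str]:
    """Sample ids of an assay, optionally restricted to one population."""
    mask = sheet["assay"] == assay
    if population is not None:
        mask &= sheet["population"] == population
    return sheet.loc[mask, "sample"].tolist()


# ---------------------------------------------------------------------------
# CpG probe tables


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """Read a CpG probe table (probe_id, chrom, pos) indexed by probe id.

    ``pos`` is the 0-based coordinate of the C of the CpG dinucleotide on
    the plus strand.
    """
    cpgs = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": np.int64})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(cpgs.columns):
        raise FormatError(f"CpG table needs columns {sorted(required)}")
    if cpgs["probe_id"].duplicated().any():
        raise FormatError("duplicate probe ids in CpG table")
    if (cpgs["pos"] < 0).any():
        raise FormatError("negative CpG position")
    return cpgs.set_index("probe_id")


def write_cpg_table(cpgs: pd.DataFrame, path: str | Path) -> None:
    cpgs.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# beta matrix


@dataclass
class BetaMatrix:
    """CpG x sample methylation beta values in [0, 1] (NaN = missing)."""

    values: pd.DataFrame  # probes x samples, float with NaN

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise FormatError("beta values outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def read_beta_matrix(path: str | Path, sample_sheet: pd.DataFrame | None = None) -> BetaMatrix:
    """Read a TSV beta matrix (probe-id row keys, sample columns).

    Values must be numeric in [0, 1] or the missing marker ``NA``. When a
    sample sheet is given, every column must appear in it under the
    methylation assay.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_MARKER], keep_default_na=False)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise FormatError(f"beta value outside [0,1] at probe {row}, sample {col}")
    if sample_sheet is not None:
        known = set(samples_for(sample_sheet, "methylation"))
        unknown = set(df.columns) - known
        if unknown:
            raise FormatError(f"beta columns not in sample sheet: {sorted(unknown)}")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep=NA_MARKER, float_format="%.6g")


def drop_sparse_probes(
    beta: BetaMatrix, sample_sheet: pd.DataFrame, max_missing_frac: float = 0.5
) -> BetaMatrix:
    """Drop probes missing in >= ``max_missing_frac`` of any population's samples."""
    keep = pd.Series(True, index=beta.probes)
    for pop in sample_sheet["population"].unique():
        cols = [s for s in samples_for(sample_sheet, "methylation", pop) if s in beta.samples]
        if not cols:
            continue
        frac_missing = beta.values[cols].isna().mean(axis=1)
        keep &= frac_missing < max_missing_frac
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d probes with >=%.0f%% missing values in some population",
                       n_drop, 100 * max_missing_frac)
    return BetaMatrix(beta.values.loc[keep])


# ---------------------------------------------------------------------------
# chromatin-state segmentations


@dataclass
class SegmentationTrack:
    """Per-chromosome partition into E1..E12 state intervals.

    Intervals are non-overlapping; a coverage map (the interval bounds
    themselves) is retained so uncovered positions are detectable.
    """

    # chrom -> (starts, ends, state indices 1..12), sorted by start
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def state_at(self, chrom: str, pos: int) -> str:
        """State of the half-open bin containing ``pos``; raises if uncovered."""
        if chrom not in self.data:
            raise KeyError(f"no segmentation for contig {chrom}")
        starts, ends, states = self.data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            raise KeyError(f"position {chrom}:{pos} not covered by segmentation")
        return f"E{states[i]}"

    def states_at(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized lookup; returns int state indices (1..12)."""
        out = np.empty(len(positions), dtype=np.int64)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            if chrom not in self.data:
                raise KeyError(f"no segmentation for contig {chrom}")
            starts, ends, states = self.data[chrom]
            idx = np.searchsorted(starts, positions[mask], side="right") - 1
            pos = positions[mask]
            bad = (idx < 0) | (pos >= ends[np.clip(idx, 0, None)])
            if bad.any():
                p = pos[bad][0]
                raise KeyError(f"position {chrom}:{p} not covered by segmentation")
            out[mask] = states[idx]
        return out


def read_segmentation(path: str | Path) -> SegmentationTrack:
    """Read a BED-like 4-column segmentation (chrom, start, end, E1..E12)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str})
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise FormatError(f"unknown chromatin states in {path}: {sorted(bad)}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise FormatError(f"invalid interval bounds in {path}")
    track = SegmentationTrack()
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"overlapping segmentation intervals on {chrom} in {path}")
        states = grp["state"].str.lstrip("E").astype(np.int64).to_numpy()
        track.data[str(chrom)] = (starts, ends, states)
    return track


def write_segmentation(track: SegmentationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, states = track.data[chrom]
            for s, e, st in zip(starts, ends, states):
                fh.write(f"{chrom}\t{s}\t{e}\tE{st}\n")


# ---------------------------------------------------------------------------
# BED peaks


def read_bed(path: str | Path, n_cols: int | None = None) -> pd.DataFrame:
    """Read BED3/BED4/BED6 into a DataFrame (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >=3 columns")
    df = df.iloc[:, : min(df.shape[1], 6)]
    df.columns = names[: df.shape[1]]
    if n_cols is not None and df.shape[1] < n_cols:
        raise FormatError(f"{path}: expected >= {n_cols} BED columns")
    df["chrom"] = df["chrom"].astype(str)
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise FormatError(f"invalid interval bounds in {path}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR PFMs


@dataclass
class PFM:
    """Position frequency matrix: 4 x L non-negative counts (rows A, C, G, T)."""

    motif_id: str
    name: str
    counts: np.ndarray  # (4, L) float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"PFM {self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise FormatError(f"PFM {self.motif_id}: empty matrix")
        if (self.counts < 0).any():
            raise FormatError(f"PFM {self.motif_id}: negative count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError(f"PFM {self.motif_id}: zero-total column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


def read_jaspar_pfms(path: str | Path) -> list[PFM]:
    """Parse JASPAR text format: '>ID NAME' then four A/C/G/T count rows."""
    pfms: list[PFM] = []
    header: str | None = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"motif {header}: expected 4 base rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"motif {header}: rows of unequal length")
        parts = header.split(maxsplit=1)
        motif_id = parts[0]
        name = parts[1] if len(parts) > 1 else motif_id
        pfms.append(PFM(motif_id, name, np.array(rows)))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
            else:
                # tolerate both "A [ 1 2 3 ]" and bare numeric rows
                body = line
                for ch in "ACGT":
                    if body.startswith(ch):
                        body = body[1:]
                        break
                body = body.replace("[", " ").replace("]", " ")
                rows.append([float(x) for x in body.split()])
    flush()
    if not pfms:
        raise FormatError(f"no motifs parsed from {path}")
    return pfms


def write_jaspar_pfms(pfms: list[PFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for base, row in zip("ACGT", pfm.counts):
                cells = " ".join(f"{x:g}" for x in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """One transcript-level gene model.

    Coordinates are 0-based half-open. ``tss`` is the transcription start
    site: ``start`` for plus-strand genes, ``end - 1`` for minus-strand.
    ``cds_start``/``cds_end`` bound the coding region for coding genes and
    are ``None`` otherwise.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    coding: bool
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.gene_id}: bad span")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise FormatError(f"gene {self.gene_id}: malformed exon lists")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.start <= s < e <= self.end):
                raise FormatError(f"gene {self.gene_id}: exon [{s},{e}) outside gene span")
        if self.coding and (self.cds_start is None or self.cds_end is None):
            raise FormatError(f"gene {self.gene_id}: coding gene without CDS bounds")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in zip(self.exon_starts, self.exon_ends))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV.

    Columns: gene_id, chrom, strand, start, end, exon_starts, exon_ends
    (comma-separated), coding (0/1), cds_start, cds_end (blank for
    non-coding genes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "start", "end",
                "exon_starts", "exon_ends", "coding"}
    if not required.issubset(df.columns):
        raise FormatError(f"gene model table needs columns {sorted(required)}")
    genes = []
    for row in df.itertuples(index=False):
        coding = str(row.coding) in ("1", "True", "true")
        cds_start = cds_end = None
        if coding:
            cds_start = int(float(row.cds_start))
            cds_end = int(float(row.cds_end))
        genes.append(GeneModel(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            strand=str(row.strand),
            start=int(row.start),
            end=int(row.end),
            exon_starts=tuple(int(x) for x in str(row.exon_starts).split(",")),
            exon_ends=tuple(int(x) for x in str(row.exon_ends).split(",")),
            coding=coding,
            cds_start=cds_start,
            cds_end=cds_end,
        ))
    if len({g.gene_id for g in genes}) != len(genes):
        raise FormatError("duplicate gene ids in gene model table")
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "start": g.start, "end": g.end,
            "exon_starts": ",".join(map(str, g.exon_starts)),
            "exon_ends": ",".join(map(str, g.exon_ends)),
            "coding": int(g.coding),
            "cds_start": "" if g.cds_start is None else g.cds_start,
            "cds_end": "" if g.cds_end is None else g.cds_end,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices and FASTA


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample matrix of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"non-integer count in {path}: {exc}") from exc
    if (df < 0).any().any():
        raise FormatError(f"negative count in {path}")
    df.index = df.index.astype(str)
    return df


def write_counts_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
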