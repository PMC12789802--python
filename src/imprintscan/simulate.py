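"""Synthetic dataset generator with planted ground truth.

The generator emulates the structure of a methylation-array study of
conventional mantle cell lymphoma (cMCL) against the normal B-cell
differentiation lineage, at a desk scale that keeps every downstream stage
exercised:

* per-population beta values drawn from Beta distributions around planted
  class means: cMCL-specific demethylated classes sit at 0.08 in cMCL and
  0.92 in naive B cells (NBC); NBC-het CpGs carry an intermediately lowered
  NBC mean f*0.10 + (1-f)*0.93 from a hidden subpopulation of fraction f;
  proliferation-drift CpGs are additionally demethylated (mean 0.30) in
  GCBC/MBC/PB-PC so the drift filter must exclude them;
* per-sample 200-bp chromatin-state segmentations where planted active CpGs
  sit in strong-enhancer bins (E2/E6) in cMCL and planted inactive classes
  in E8/E10/E11/E12 bins in both populations, with 10% per-sample state
  noise;
* accessibility peaks covering exactly the planted accessible subset;
* a genome FASTA with motif consensus sequences inserted within ±50 bp of
  planted CpGs, using disjoint motif sets for the active, NBC-hom and
  NBC-het classes;
* a ReMap-style TF peak BED whose planted-TF peaks cover planted windows;
* gene models and negative-binomial RNA-seq counts with de novo expression
  (cMCL-only) planted at the genes nearest the NBC-hom CpGs.

One seed sequence drives everything; sub-streams are derived per component
so adding a component does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iomod
from .expression import assign_closest_genes
from .io import PFM, GeneModel

logger = logging.getLogger(__name__)

CPG_CLASSES = (
    "background-methylated",
    "background-unmethylated",
    "drift",
    "active-demethylated",
    "active-accessible-demethylated",
    "inactive-NBC-hom",
    "inactive-NBC-het",
)

ACTIVE_STATES = (1, 2, 6, 7)
INACTIVE_STATES = (8, 10, 11, 12)

# genome-wide base-state probabilities for bins without planted CpGs
_BG_STATES = np.arange(1, 13)
_BG_STATE_P = np.array([0.04, 0.05, 0.05, 0.03, 0.06, 0.04,
                        0.05, 0.10, 0.08, 0.08, 0.35, 0.07])

BIN = 200  # segmentation resolution, bp


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset (defaults are the study conditions)."""

    contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    n_cpgs: int = 20_000
    # methylation sample counts mirror the real cohort structure
    sample_counts: dict[str, int] = field(default_factory=lambda: {
        "HPC": 6, "EarlyB": 16, "NBC-B": 10, "NBC-T": 5, "GCBC": 9,
        "MBC": 10, "PB/PC": 11, "cMCL": 62, "nnMCL": 20,
    })
    segmentation_counts: dict[str, int] = field(
        default_factory=lambda: {"cMCL": 2, "NBC-B": 3})
    rnaseq_counts: dict[str, int] = field(default_factory=lambda: {
        "NBC-B": 3, "NBC-T": 3, "GCBC": 3, "MBC": 3, "PB/PC": 3, "cMCL": 2,
    })
    # planted class counts
    n_active: int = 600           # includes the accessible subset
    n_accessible: int = 150
    n_nbc_hom: int = 80
    n_nbc_het: int = 230
    n_drift: int = 400
    frac_bg_unmethylated: float = 0.3  # fraction of leftover CpGs set low everywhere
    # noise / effect parameters
    beta_precision: float = 150.0
    nbc_het_fraction: float = 0.15
    state_noise: float = 0.1
    motif_plant_rate: float = 0.8
    tf_peak_rate: float = 0.7
    tf_background_rate: float = 0.02
    motif_length: int = 10
    sample_motif_from_pfm: bool = False
    # expression
    n_genes: int = 600
    nb_dispersion: float = 0.05
    planted_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self):
        planted = self.n_active + self.n_nbc_hom + self.n_nbc_het + self.n_drift
        if planted > self.n_cpgs:
            raise ValueError("planted class counts exceed CpG count")
        if self.n_accessible > self.n_active:
            raise ValueError("accessible subset larger than the active class")
        if not 0 < self.nbc_het_fraction < 1:
            raise ValueError("nbc_het_fraction must be in (0, 1)")
        for name in ("beta_precision", "nb_dispersion", "motif_plant_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def simulate_beta(mean: float, precision: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` beta values around ``mean`` with concentration ``precision``.

    Shape parameters are (mean*precision, (1-mean)*precision).  Means of 0
    or 1 are clamped to [1e-3, 1-1e-3] with a warning.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    if mean <= 0 or mean >= 1:
        warnings.warn("beta mean clamped away from {0,1}", stacklevel=2)
        mean = min(max(mean, 1e-3), 1 - 1e-3)
    return rng.beta(mean * precision, (1 - mean) * precision, size=n)


# ---------------------------------------------------------------------------
# per-component builders


def _place_cpgs(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One CpG per chosen 200-bp bin, >=1 kb from contig ends."""
    total_len = sum(cfg.contigs.values())
    rows = []
    remaining = cfg.n_cpgs
    items = list(cfg.contigs.items())
    for i, (chrom, length) in enumerate(items):
        n_here = remaining if i == len(items) - 1 else round(cfg.n_cpgs * length / total_len)
        n_here = min(n_here, remaining)
        remaining -= n_here
        n_slots = length // BIN
        usable = np.arange(5, n_slots - 5)
        if n_here > len(usable):
            raise ValueError(f"too many CpGs for contig {chrom}")
        slots = np.sort(rng.choice(usable, size=n_here, replace=False))
        offsets = rng.integers(60, 140, size=n_here)
        for slot, off in zip(slots, offsets):
            rows.append((chrom, int(slot) * BIN + int(off)))
    cpgs = pd.DataFrame(rows, columns=["chrom", "pos"])
    cpgs.index = pd.Index([f"cg{i:07d}" for i in range(len(cpgs))], name="probe_id")
    return cpgs


def _assign_classes(cfg: SimulationConfig, cpgs: pd.DataFrame,
                    rng: np.random.Generator) -> pd.Series:
    classes = np.empty(len(cpgs), dtype=object)
    order = rng.permutation(len(cpgs))
    i = 0

    def take(n):
        nonlocal i
        sel = order[i : i + n]
        i += n
        return sel

    classes[take(cfg.n_accessible)] = "active-accessible-demethylated"
    classes[take(cfg.n_active - cfg.n_accessible)] = "active-demethylated"
    classes[take(cfg.n_nbc_hom)] = "inactive-NBC-hom"
    classes[take(cfg.n_nbc_het)] = "inactive-NBC-het"
    classes[take(cfg.n_drift)] = "drift"
    left = len(cpgs) - i
    n_unmeth = int(round(left * cfg.frac_bg_unmethylated))
    classes[take(n_unmeth)] = "background-unmethylated"
    classes[take(left - n_unmeth)] = "background-methylated"
    return pd.Series(classes, index=cpgs.index, name="planted_class")


def _class_means(cfg: SimulationConfig) -> pd.DataFrame:
    """Planted mean beta per (class, population)."""
    pops = list(cfg.sample_counts)
    high, low = 0.92, 0.08
    het_nbc = cfg.nbc_het_fraction * 0.10 + (1 - cfg.nbc_het_fraction) * 0.93
    means = pd.DataFrame(high, index=list(CPG_CLASSES), columns=pops, dtype=float)
    means.loc["background-unmethylated", :] = 0.10
    for cls in ("drift", "active-demethylated", "active-accessible-demethylated",
                "inactive-NBC-hom", "inactive-NBC-het"):
        means.loc[cls, "cMCL"] = low
    means.loc["inactive-NBC-het", ["NBC-B", "NBC-T"]] = het_nbc
    means.loc["drift", ["GCBC", "MBC", "PB/PC"]] = 0.30
    return means


def _simulate_beta_matrix(cfg: SimulationConfig, classes: pd.Series,
                          rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (beta DataFrame, methylation sample sheet rows)."""
    means = _class_means(cfg)
    columns, sheet_rows = [], []
    for pop, n in cfg.sample_counts.items():
        tag = pop.replace("/", "")
        for k in range(n):
            sid = f"{tag}_{k + 1:02d}"
            columns.append((sid, pop))
            sheet_rows.append({"sample": sid, "population": pop, "assay": "methylation"})
    values = np.empty((len(classes), len(columns)))
    class_arr = classes.to_numpy()
    for cls in CPG_CLASSES:
        mask = class_arr == cls
        n_rows = int(mask.sum())
        if n_rows == 0:
            continue
        for j, (_, pop) in enumerate(columns):
            m = float(means.loc[cls, pop])
            values[mask, j] = simulate_beta(m, cfg.beta_precision, n_rows, rng)
    beta = pd.DataFrame(values, index=classes.index,
                        columns=[sid for sid, _ in columns])
    return beta, pd.DataFrame(sheet_rows)


def _planted_bin_states(cfg: SimulationConfig, cpgs: pd.DataFrame, classes: pd.Series,
                        rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Per population, per contig, planted state per 200-bp bin.

    Bins without a planted-class CpG share one genome-wide base state across
    populations; bins holding planted CpGs get class-consistent states.
    """
    base = {}
    for chrom, length in cfg.contigs.items():
        n_slots = length // BIN
        base[chrom] = rng.choice(_BG_STATES, size=n_slots, p=_BG_STATE_P)
    planted: dict[str, dict[str, np.ndarray]] = {
        "cMCL": {c: base[c].copy() for c in base},
        "NBC-B": {c: base[c].copy() for c in base},
    }
    slot = (cpgs["pos"] // BIN).to_numpy()
    chrom_arr = cpgs["chrom"].to_numpy()
    cls = classes.to_numpy()
    is_active = np.isin(cls, ["active-demethylated", "active-accessible-demethylated"])
    is_inactive = np.isin(cls, ["inactive-NBC-hom", "inactive-NBC-het", "drift"])
    enh = rng.choice([2, 6], size=len(cpgs))
    inact = rng.choice(INACTIVE_STATES, size=len(cpgs))
    for chrom in base:
        m = chrom_arr == chrom
        a = m & is_active
        planted["cMCL"][chrom][slot[a]] = enh[a]
        planted["NBC-B"][chrom][slot[a]] = 11
        i = m & is_inactive
        planted["cMCL"][chrom][slot[i]] = inact[i]
        planted["NBC-B"][chrom][slot[i]] = inact[i]
    return planted


def _noisy_sample_states(planted: np.ndarray, protected_active: np.ndarray,
                         protected_inactive: np.ndarray, noise: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-sample states: planted with prob 1-noise, else a random other state.

    At protected bins (those holding planted active / planted inactive CpGs)
    the replacement state is drawn within the same category tier, so the
    hierarchy never flips a planted category while any sample noise remains.
    """
    out = planted.copy()
    flip = rng.random(len(planted)) < noise
    idx = np.flatnonzero(flip)
    if len(idx) == 0:
        return out
    # draw replacements: uniform over the allowed set minus the planted state
    repl = np.empty(len(idx), dtype=planted.dtype)
    for j, i in enumerate(idx):
        if protected_active[i]:
            pool = [s for s in ACTIVE_STATES if s != planted[i]]
        elif protected_inactive[i]:
            pool = [s for s in INACTIVE_STATES if s != planted[i]]
        else:
            pool = [s for s in range(1, 13) if s != planted[i]]
        repl[j] = pool[rng.integers(0, len(pool))]
    out[idx] = repl
    return out


def _write_segmentations(cfg: SimulationConfig, outdir: Path, cpgs: pd.DataFrame,
                         classes: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    planted = _planted_bin_states(cfg, cpgs, classes, rng)
    slot = (cpgs["pos"] // BIN).to_numpy()
    chrom_arr = cpgs["chrom"].to_numpy()
    cls = classes.to_numpy()
    is_active = np.isin(cls, ["active-demethylated", "active-accessible-demethylated"])
    is_inactive = np.isin(cls, ["inactive-NBC-hom", "inactive-NBC-het", "drift"])

    prot_a, prot_i = {}, {}
    for chrom, length in cfg.contigs.items():
        n_slots = length // BIN
        a = np.zeros(n_slots, dtype=bool)
        b = np.zeros(n_slots, dtype=bool)
        m = chrom_arr == chrom
        a[slot[m & is_active]] = True
        b[slot[m & is_inactive]] = True
        prot_a[chrom], prot_i[chrom] = a, b

    seg_dir = outdir / "segmentations"
    seg_dir.mkdir(parents=True, exist_ok=True)
    sheet_rows = []
    for pop, n in cfg.segmentation_counts.items():
        tag = pop.replace("/", "")
        for k in range(n):
            sid = f"{tag}_seg{k + 1}"
            sheet_rows.append({"sample": sid, "population": pop, "assay": "segmentation"})
            parts = []
            for chrom in cfg.contigs:
                states = _noisy_sample_states(planted[pop][chrom], prot_a[chrom],
                                              prot_i[chrom], cfg.state_noise, rng)
                n_slots = len(states)
                parts.append(pd.DataFrame({
                    "chrom": chrom,
                    "start": np.arange(n_slots, dtype=np.int64) * BIN,
                    "end": (np.arange(n_slots, dtype=np.int64) + 1) * BIN,
                    "state": [f"E{s}" for s in states],
                }))
            pd.concat(parts).to_csv(seg_dir / f"{sid}.bed", sep="\t",
                                    header=False, index=False)
    return pd.DataFrame(sheet_rows)


def _make_pfms(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[list[PFM], pd.DataFrame]:
    """Synthetic PFMs: 2 per planted class (active, NBC-hom, NBC-het) + 4 decoys."""
    spec = ([("active", f"ACT{i}") for i in (1, 2)]
            + [("nbc_hom", f"HOM{i}") for i in (1, 2)]
            + [("nbc_het", f"HET{i}") for i in (1, 2)]
            + [("decoy", f"DEC{i}") for i in (1, 2, 3, 4)])
    pfms, rows = [], []
    for j, (cls, name) in enumerate(spec):
        consensus = rng.integers(0, 4, size=cfg.motif_length)
        counts = np.full((4, cfg.motif_length), 5.0)
        counts[consensus, np.arange(cfg.motif_length)] = 85.0
        motif_id = f"SM{j + 1:04d}"
        pfms.append(PFM(motif_id, name, counts))
        rows.append({"motif": motif_id, "tf": name, "planted_class": cls})
    return pfms, pd.DataFrame(rows)


def _build_genome(cfg: SimulationConfig, cpgs: pd.DataFrame, classes: pd.Series,
                  pfms: list[PFM], motif_classes: pd.DataFrame,
                  rng: np.random.Generator) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with a CG at every probe and planted motif consensi."""
    codes = {c: rng.integers(0, 4, size=length).astype(np.int8)
             for c, length in cfg.contigs.items()}
    for chrom, grp in cpgs.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        codes[chrom][pos] = 1      # C
        codes[chrom][pos + 1] = 2  # G

    by_class: dict[str, list[PFM]] = {}
    for pfm, cls in zip(pfms, motif_classes["planted_class"]):
        by_class.setdefault(cls, []).append(pfm)
    target_class = {
        "active-demethylated": "active",
        "active-accessible-demethylated": "active",
        "inactive-NBC-hom": "nbc_hom",
        "inactive-NBC-het": "nbc_het",
    }
    planted_rows = []
    for probe_id, row in cpgs.iterrows():
        cls = classes.loc[probe_id]
        if cls not in target_class:
            continue
        if rng.random() >= cfg.motif_plant_rate:
            continue
        pool = by_class[target_class[cls]]
        pfm = pool[rng.integers(0, len(pool))]
        L = pfm.length
        pos = int(row["pos"])
        if rng.random() < 0.5:
            start = pos + 2 + int(rng.integers(0, 50 - 1 - L))
        else:
            start = pos - 50 + int(rng.integers(0, 50 - L - 1))
        if cfg.sample_motif_from_pfm:
            probs = pfm.counts / pfm.counts.sum(axis=0, keepdims=True)
            inserted = np.array([rng.choice(4, p=probs[:, j]) for j in range(L)],
                                dtype=np.int8)
        else:
            inserted = pfm.counts.argmax(axis=0).astype(np.int8)
        codes[row["chrom"]][start : start + L] = inserted
        planted_rows.append({"motif": pfm.motif_id, "probe_id": probe_id,
                             "offset": start - pos})
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {c: bases[v].tobytes().decode("ascii") for c, v in codes.items()}
    return genome, pd.DataFrame(planted_rows, columns=["motif", "probe_id", "offset"])


def _make_remap(cfg: SimulationConfig, cpgs: pd.DataFrame, classes: pd.Series,
                planted_motifs: pd.DataFrame, motif_classes: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """ReMap-style BED: planted-TF peaks over planted windows + background rate."""
    tf_of = dict(zip(motif_classes["motif"], motif_classes["tf"]))
    rows = []
    for rec in planted_motifs.itertuples(index=False):
        if rng.random() >= cfg.tf_peak_rate:
            continue
        row = cpgs.loc[rec.probe_id]
        rows.append((row["chrom"], int(row["pos"]) - 40, int(row["pos"]) + 41,
                     tf_of[rec.motif]))
    # base-rate binding of every TF over random CpGs (keeps Fisher tables full)
    all_ids = cpgs.index.to_numpy()
    for tf in motif_classes["tf"]:
        n_bg = rng.binomial(len(all_ids), cfg.tf_background_rate)
        for probe_id in rng.choice(all_ids, size=n_bg, replace=False):
            row = cpgs.loc[probe_id]
            rows.append((row["chrom"], int(row["pos"]) - 40, int(row["pos"]) + 41,
                         tf))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return peaks.sort_values(["chrom", "start", "name"], kind="mergesort").reset_index(drop=True)


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    total_len = sum(cfg.contigs.values())
    genes: list[GeneModel] = []
    gid = 0
    for chrom, length in cfg.contigs.items():
        n_here = round(cfg.n_genes * length / total_len)
        starts = np.sort(rng.choice(np.arange(10_000, length - 40_000, 1_000),
                                    size=n_here, replace=False))
        for s in starts:
            span = int(rng.integers(4_000, 20_000))
            n_exons = int(rng.integers(3, 7))
            cuts = np.sort(rng.choice(np.arange(1, span // 100), size=2 * n_exons,
                                      replace=False)) * 100
            exon_starts = tuple(int(s + c) for c in cuts[0::2])
            exon_ends = tuple(int(s + c) for c in cuts[1::2])
            end = exon_ends[-1] + int(rng.integers(50, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            cds_start = exon_starts[0] + min(50, (exon_ends[0] - exon_starts[0]) // 2)
            cds_end = exon_ends[-1] - min(50, (exon_ends[-1] - exon_starts[-1]) // 2)
            gid += 1
            genes.append(GeneModel(
                gene_id=f"G{gid:05d}", chrom=chrom, strand=strand,
                start=int(s), end=int(end),
                exon_starts=exon_starts, exon_ends=exon_ends,
                coding=True, cds_start=int(cds_start), cds_end=int(cds_end),
            ))
    return genes


def _plant_gene_classes(cfg: SimulationConfig, genes: list[GeneModel],
                        cpgs: pd.DataFrame, classes: pd.Series,
                        rng: np.random.Generator) -> pd.Series:
    """Planted expression class per gene; de novo at genes nearest NBC-hom CpGs."""
    hom_cpgs = cpgs[classes == "inactive-NBC-hom"]
    assigned = assign_closest_genes(hom_cpgs, genes)
    denovo = set(assigned["gene"].dropna())
    gene_ids = [g.gene_id for g in genes]
    cls = pd.Series("stable expression", index=pd.Index(gene_ids, name="gene_id"),
                    dtype=object)
    cls[list(denovo)] = "de novo expression"
    others = [g for g in gene_ids if g not in denovo]
    others = list(rng.permutation(others))
    n_lost, n_up, n_down = 30, 30, 30
    cls[others[:n_lost]] = "lost expression"
    cls[others[n_lost : n_lost + n_up]] = "upregulated"
    cls[others[n_lost + n_up : n_lost + n_up + n_down]] = "downregulated"
    rest = others[n_lost + n_up + n_down :]
    n_off = int(round(len(rest) * 0.25))
    cls[rest[:n_off]] = "not expressed"
    return cls


def _simulate_counts(cfg: SimulationConfig, genes: list[GeneModel],
                     gene_classes: pd.Series,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts per gene per RNA-seq sample following the planted class."""
    high, low = 300.0, 0.3
    fc = 2.0 ** cfg.planted_log2fc
    mean_by_class = {
        # (normal populations, cMCL)
        "stable expression": (high, high),
        "not expressed": (low, low),
        "de novo expression": (low, high),
        "lost expression": (high, low),
        "upregulated": (high, high * fc),
        "downregulated": (high, high / fc),
    }
    columns, sheet_rows = [], []
    for pop, n in cfg.rnaseq_counts.items():
        tag = pop.replace("/", "")
        for k in range(n):
            sid = f"{tag}_rna{k + 1}"
            columns.append((sid, pop))
            sheet_rows.append({"sample": sid, "population": pop, "assay": "rnaseq"})
    gene_ids = [g.gene_id for g in genes]
    values = np.empty((len(gene_ids), len(columns)), dtype=np.int64)
    r = 1.0 / cfg.nb_dispersion
    for i, gid in enumerate(gene_ids):
        mn_normal, mn_tumor = mean_by_class[gene_classes.loc[gid]]
        for j, (_, pop) in enumerate(columns):
            mu = mn_tumor if pop == "cMCL" else mn_normal
            values[i, j] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=[sid for sid, _ in columns])
    return counts, pd.DataFrame(sheet_rows)


# ---------------------------------------------------------------------------
# top-level entry point


def generate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full synthetic dataset and its truth tables; return paths.

    The same config and seed produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ("positions", "classes", "beta", "segmentation", "motifs", "genome",
         "remap", "genes", "counts"),
        ss.spawn(9),
    )}

    cpgs = _place_cpgs(config, streams["positions"])
    classes = _assign_classes(config, cpgs, streams["classes"])
    beta, meth_sheet = _simulate_beta_matrix(config, classes, streams["beta"])
    seg_sheet = _write_segmentations(config, outdir, cpgs, classes,
                                     streams["segmentation"])
    pfms, motif_classes = _make_pfms(config, streams["motifs"])
    genome, planted_motifs = _build_genome(config, cpgs, classes, pfms,
                                           motif_classes, streams["genome"])
    remap = _make_remap(config, cpgs, classes, planted_motifs, motif_classes,
                        streams["remap"])
    genes = _make_genes(config, streams["genes"])
    gene_classes = _plant_gene_classes(config, genes, cpgs, classes, streams["counts"])
    counts, rna_sheet = _simulate_counts(config, genes, gene_classes, streams["counts"])

    # accessibility peaks: exactly the planted accessible subset
    acc = cpgs[classes == "active-accessible-demethylated"]
    peaks = pd.DataFrame({
        "chrom": acc["chrom"].to_numpy(),
        "start": acc["pos"].to_numpy() - 40,
        "end": acc["pos"].to_numpy() + 41,
    }).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    atac_sheet = pd.DataFrame([{"sample": "cMCL_atac1", "population": "cMCL",
                                "assay": "accessibility"}])
    sheet = pd.concat([meth_sheet, seg_sheet, atac_sheet, rna_sheet],
                      ignore_index=True)

    paths = {
        "sample_sheet": outdir / "sample_sheet.tsv",
        "cpgs": outdir / "cpgs.tsv",
        "beta": outdir / "beta.tsv",
        "segmentation_dir": outdir / "segmentations",
        "peaks": outdir / "atac_peaks.bed",
        "genome": outdir / "genome.fa",
        "pfms": outdir / "motifs.jaspar",
        "remap": outdir / "remap.bed",
        "genes": outdir / "genes.tsv",
        "counts": outdir / "counts.tsv",
    }
    iomod.write_sample_sheet(sheet, paths["sample_sheet"])
    iomod.write_cpg_table(cpgs, paths["cpgs"])
    iomod.write_beta_matrix(iomod.BetaMatrix(beta), paths["beta"])
    iomod.write_bed(peaks, paths["peaks"])
    iomod.write_fasta(genome, paths["genome"])
    iomod.write_jaspar_pfms(pfms, paths["pfms"])
    iomod.write_bed(remap, paths["remap"])
    iomod.write_gene_models(genes, paths["genes"])
    iomod.write_counts_matrix(counts, paths["counts"])

    het_frac = pd.Series(np.nan, index=cpgs.index, name="nbc_mixture_fraction")
    het_frac[classes == "inactive-NBC-het"] = config.nbc_het_fraction
    truth_cpg = pd.DataFrame({"planted_class": classes,
                              "nbc_mixture_fraction": het_frac})
    truth_cpg.to_csv(outdir / "truth" / "cpg_classes.tsv", sep="\t")
    gene_classes.rename("planted_class").to_csv(outdir / "truth" / "gene_classes.tsv",
                                                sep="\t")
    motif_classes.to_csv(outdir / "truth" / "motif_classes.tsv", sep="\t", index=False)
    planted_motifs.to_csv(outdir / "truth" / "planted_motifs.tsv", sep="\t", index=False)

    manifest = {"seed": config.seed, "checksums": {}}
    for key, p in sorted(paths.items()):
        if Path(p).is_dir():
            for f in sorted(Path(p).iterdir()):
                manifest["checksums"][f"{key}/{f.name}"] = _sha256(f)
        else:
            manifest["checksums"][key] = _sha256(p)
    with open(outdir / "truth" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "paths": paths,
        "truth_cpg": truth_cpg,
        "truth_genes": gene_classes,
        "truth_motifs": motif_classes,
        "planted_motifs": planted_motifs,
    }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
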