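"""End-to-end orchestration: select -> classify -> subtype -> motifs/TF -> expression.

Every stage writes its TSV before the next starts; a JSON manifest with
row counts and checksums is written last.  A master seed spawns per-stage
child seeds deterministically, so re-running with the same config and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as iomod
from .chromatin import (annotation_enrichment, classify_cpgs,
                        fractionated_annotation_scores, split_by_accessibility)
from .expression import (assign_closest_genes, classify_expression_categories,
                         differential_expression, expression_flags, fpkm,
                         gene_category_enrichment)
from .motifs import remap_binding_enrichment, run_motif_enrichment, score_background
from .selection import (SelectionThresholds, population_mean_beta,
                        select_cmcl_specific)
from .stats import monte_carlo_enrichment, results_to_frame
from .subtypes import best_split_threshold, cluster_inactive_cpgs

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

#: CpG categories analyzed separately in the motif / TF / gene stages
MOTIF_CATEGORIES = ("Active", "Inactive", "ActiveAccessible",
                    "ActiveInaccessible", "NBC-hom", "NBC-het")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    beta: Path
    sample_sheet: Path
    cpgs: Path
    segmentation_dir: Path
    peaks: Path
    genome: Path
    pfms: Path
    remap: Path
    genes: Path
    counts: Path
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    n_sims_chromatin: int = 100_000
    n_sims_genes: int = 10_000
    flank: int = 50
    background_nbc_min: float = 0.75
    seed: int = 0

    def __post_init__(self):
        for name in ("beta", "sample_sheet", "cpgs", "segmentation_dir", "peaks",
                     "genome", "pfms", "remap", "genes", "counts"):
            setattr(self, name, Path(getattr(self, name)))
        if min(self.n_sims_chromatin, self.n_sims_genes) < 100:
            raise ValueError("n_sims must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.pop("inputs")
        thr = SelectionThresholds(**raw.pop("thresholds", {}))
        return cls(**inputs, thresholds=thr, **raw)

    def validate(self) -> None:
        for name in ("beta", "sample_sheet", "cpgs", "peaks", "genome",
                     "pfms", "remap", "genes", "counts"):
            p = getattr(self, name)
            if not p.is_file():
                raise PipelineError("validate", f"missing input file {name}: {p}")
        if not self.segmentation_dir.is_dir():
            raise PipelineError("validate",
                                f"missing segmentation dir {self.segmentation_dir}")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    try:
        manifest = _run(config, outdir, outputs)
    except PipelineError as exc:
        (outdir / "FAILED").write_text(f"{exc}\n")
        raise
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return manifest


def _run(config: PipelineConfig, outdir: Path, outputs: dict[str, Path]) -> dict:
    try:
        return _run_stages(config, outdir, outputs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(_CURRENT_STAGE[0], str(exc)) from exc


_CURRENT_STAGE = ["load"]


def _stage(name: str) -> None:
    _CURRENT_STAGE[0] = name
    logger.info("stage %s", name)


def _run_stages(config: PipelineConfig, outdir: Path, outputs: dict[str, Path]) -> dict:
    import pyfaidx

    master = np.random.SeedSequence(config.seed)
    seeds = {name: child for name, child in zip(
        ("chromatin", "annotation", "genes"), master.spawn(3))}

    # ----- load -----------------------------------------------------------
    _stage("load")
    sheet = iomod.read_sample_sheet(config.sample_sheet)
    cpgs = iomod.read_cpg_table(config.cpgs)
    beta = iomod.read_beta_matrix(config.beta, sheet)
    beta = iomod.drop_sparse_probes(beta, sheet)
    cpgs = cpgs.loc[cpgs.index.intersection(beta.probes)]
    peaks = iomod.read_bed(config.peaks)
    remap_peaks = iomod.read_bed(config.remap, n_cols=4)
    pfms = iomod.read_jaspar_pfms(config.pfms)
    genes = iomod.read_gene_models(config.genes)
    counts = iomod.read_counts_matrix(config.counts)
    genome = pyfaidx.Fasta(str(config.genome))
    seg_samples = iomod.samples_for(sheet, "segmentation")
    tracks = {}
    for sid in seg_samples:
        path = config.segmentation_dir / f"{sid}.bed"
        if not path.is_file():
            raise PipelineError("load", f"missing segmentation file {path}")
        tracks[sid] = iomod.read_segmentation(path)
    population_of = dict(zip(sheet["sample"], sheet["population"]))
    logger.info("loaded %d CpGs, %d samples, %d segmentations, %d PFMs, %d genes",
                len(cpgs), len(beta.samples), len(tracks), len(pfms), len(genes))

    # ----- stage 1: selection ---------------------------------------------
    _stage("select")
    means = population_mean_beta(beta, sheet)
    sel_table = select_cmcl_specific(means, config.thresholds)
    outputs["selected"] = _write(sel_table, outdir / "selected.tsv")
    selected_ids = sel_table.index[sel_table["selected"]]
    if len(selected_ids) == 0:
        raise PipelineError("select", "no CpGs selected")
    logger.info("selected %d / %d CpGs", len(selected_ids), len(sel_table))

    # ----- stage 2: chromatin classification ------------------------------
    _stage("classify")
    all_states = classify_cpgs(cpgs, tracks, population_of)
    sel_cpgs = cpgs.loc[selected_ids]
    acc = split_by_accessibility(sel_cpgs, peaks, all_states.loc[selected_ids,
                                                                 "merged_cMCL"])
    classified = pd.concat([sel_cpgs, all_states.loc[selected_ids], acc], axis=1)
    outputs["classified"] = _write(classified, outdir / "classified.tsv")

    chrom_enr = monte_carlo_enrichment(
        all_states.loc[selected_ids, "merged_cMCL"].to_numpy(),
        all_states["merged_cMCL"].to_numpy(),
        config.n_sims_chromatin,
        np.random.default_rng(seeds["chromatin"]),
    )
    outputs["chromatin_enrichment"] = _write(
        results_to_frame(chrom_enr), outdir / "chromatin_enrichment.tsv", index=False)

    weights_all = fractionated_annotation_scores(cpgs, genes)
    rng_ann = np.random.default_rng(seeds["annotation"])
    ann_frames = []
    inactive_ids = classified.index[classified["merged_cMCL"] == "Inactive"]
    for label, ids in (("selection", selected_ids), ("Inactive", inactive_ids)):
        if len(ids) == 0:
            continue
        res = annotation_enrichment(weights_all.loc[ids], weights_all,
                                    config.n_sims_chromatin, rng_ann)
        frame = results_to_frame(res)
        frame.insert(0, "cpg_set", label)
        ann_frames.append(frame)
    outputs["annotation_enrichment"] = _write(
        pd.concat(ann_frames, ignore_index=True),
        outdir / "annotation_enrichment.tsv", index=False)

    # ----- stage 3: NBC-het / NBC-hom -------------------------------------
    _stage("subtype")
    nbc_samples = [s for s in iomod.samples_for(sheet, "methylation", "NBC-B")
                   + iomod.samples_for(sheet, "methylation", "NBC-T")
                   if s in beta.samples]
    subtypes = cluster_inactive_cpgs(beta.values.loc[inactive_ids, nbc_samples])
    threshold, n_err = best_split_threshold(subtypes["mean_nbc"], subtypes["label"])
    outputs["subtypes"] = _write(subtypes, outdir / "subtypes.tsv")
    meta = {"best_split_threshold": threshold, "misclassified": n_err,
            "metric": subtypes.attrs.get("metric"),
            "linkage": subtypes.attrs.get("linkage"),
            "silhouette": subtypes.attrs.get("silhouette")}
    with open(outdir / "subtypes_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    outputs["subtypes_meta"] = outdir / "subtypes_meta.json"

    category_ids = {
        "Active": classified.index[classified["merged_cMCL"] == "Active"],
        "Inactive": inactive_ids,
        "ActiveAccessible": classified.index[
            classified["refined_category"] == "ActiveAccessible"],
        "ActiveInaccessible": classified.index[
            classified["refined_category"] == "ActiveInaccessible"],
        "NBC-hom": subtypes.index[subtypes["label"] == "NBC-hom"],
        "NBC-het": subtypes.index[subtypes["label"] == "NBC-het"],
    }

    # ----- stage 4: motif and TF-binding enrichment ------------------------
    _stage("motifs")
    # shared background: NBC mean > threshold, selection excluded
    bg_ids = means.index[(means["NBC"] > config.background_nbc_min)
                         & ~means.index.isin(selected_ids)]
    bg_cpgs = cpgs.loc[cpgs.index.intersection(bg_ids)]
    bg_scores = score_background(bg_cpgs, pfms, genome, config.flank)
    motif_frames, remap_frames = [], []
    for cat in MOTIF_CATEGORIES:
        ids = category_ids[cat]
        if len(ids) == 0:
            logger.warning("category %s empty; skipping motif stage", cat)
            continue
        res = run_motif_enrichment(cpgs.loc[ids], bg_cpgs, pfms, genome,
                                   config.flank, background_scores=bg_scores)
        res.insert(0, "cpg_set", cat)
        motif_frames.append(res)
        rb = remap_binding_enrichment(cpgs.loc[ids], bg_cpgs, remap_peaks,
                                      config.flank)
        rb.insert(0, "cpg_set", cat)
        remap_frames.append(rb)
    outputs["motif_enrichment"] = _write(
        pd.concat(motif_frames, ignore_index=True),
        outdir / "motif_enrichment.tsv", index=False)
    outputs["remap_enrichment"] = _write(
        pd.concat(remap_frames, ignore_index=True),
        outdir / "remap_enrichment.tsv", index=False)

    # ----- stage 5: expression ---------------------------------------------
    _stage("expression")
    lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
    fpkm_mat = fpkm(counts, lengths)
    flags = expression_flags(fpkm_mat, sheet)
    groups = pd.Series({s: population_of[s] for s in counts.columns})
    de = differential_expression(counts, groups, reference="NBC-B", treatment="cMCL")
    categories = classify_expression_categories(flags, de)
    expr = pd.concat([flags, de, categories.rename("category")], axis=1)
    outputs["expression"] = _write(expr, outdir / "expression_categories.tsv")

    assignments = assign_closest_genes(cpgs, genes)
    outputs["gene_assignments"] = _write(assignments, outdir / "gene_assignments.tsv")
    rng_genes = np.random.default_rng(seeds["genes"])
    gene_frames = []
    for cat in MOTIF_CATEGORIES:
        ids = category_ids[cat]
        if len(ids) == 0:
            continue
        res = gene_category_enrichment(ids, bg_cpgs.index, assignments, categories,
                                       config.n_sims_genes, rng_genes)
        frame = results_to_frame(res)
        frame.insert(0, "cpg_set", cat)
        gene_frames.append(frame)
    outputs["gene_enrichment"] = _write(
        pd.concat(gene_frames, ignore_index=True),
        outdir / "gene_enrichment.tsv", index=False)

    # ----- manifest --------------------------------------------------------
    _stage("manifest")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.snapshot(),
        "outputs": {},
    }
    for key, path in sorted(outputs.items()):
        n_rows = sum(1 for _ in open(path)) - 1
        manifest["outputs"][key] = {
            "path": str(path.name),
            "rows": n_rows,
            "sha256": _sha256(path),
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
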