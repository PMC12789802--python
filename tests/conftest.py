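"""Shared fixtures: one default synthetic dataset + pipeline run per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from imprintscan.pipeline import PipelineConfig, run_pipeline
from imprintscan.simulate import SimulationConfig, generate_dataset

#: seed of the study-conditions dataset used throughout the suite
DATASET_SEED = 11


def make_pipeline_config(dataset_dir, seed: int, **overrides) -> PipelineConfig:
    d = dataset_dir
    return PipelineConfig(
        beta=d / "beta.tsv",
        sample_sheet=d / "sample_sheet.tsv",
        cpgs=d / "cpgs.tsv",
        segmentation_dir=d / "segmentations",
        peaks=d / "atac_peaks.bed",
        genome=d / "genome.fa",
        pfms=d / "motifs.jaspar",
        remap=d / "remap.bed",
        genes=d / "genes.tsv",
        counts=d / "counts.tsv",
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-scale synthetic dataset with planted ground truth."""
    outdir = tmp_path_factory.mktemp("dataset")
    cfg = SimulationConfig(seed=DATASET_SEED)
    result = generate_dataset(cfg, outdir)
    result["dir"] = outdir
    result["config"] = cfg
    return result


@pytest.fixture(scope="session")
def pipeline_run(default_dataset, tmp_path_factory):
    """Full pipeline run on the default synthetic dataset."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = make_pipeline_config(default_dataset["dir"], seed=DATASET_SEED)
    manifest = run_pipeline(cfg, outdir)
    return {"dir": outdir, "manifest": manifest, "config": cfg}


def small_simulation_config(seed: int = 3) -> SimulationConfig:
    """Reduced-scale config for fast structural tests (not the study conditions)."""
    return SimulationConfig(
        contigs={"chr1": 1_000_000, "chr2": 1_000_000},
        n_cpgs=3_000,
        sample_counts={"HPC": 2, "EarlyB": 2, "NBC-B": 6, "NBC-T": 3, "GCBC": 4,
                       "MBC": 4, "PB/PC": 4, "cMCL": 10, "nnMCL": 3},
        rnaseq_counts={"NBC-B": 3, "cMCL": 2},
        n_active=120, n_accessible=30, n_nbc_hom=30, n_nbc_het=60, n_drift=80,
        n_genes=150,
        seed=seed,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_cpgs():
    return pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr1", "chr2"],
         "pos": [100, 140, 400, 100]},
        index=pd.Index(["c1", "c2", "c3", "c4"], name="probe_id"),
    )
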