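"""Stage 1: selection of tumor-specific demethylated CpGs.

CpGs are selected when their mean beta is below ``tumor_max`` in cMCL and
above ``normal_min`` in naive B cells (NBC), and — to correct for
proliferation-associated epigenetic drift — when the methylation difference
between each highly proliferative mature B-cell subtype (GCBC, MBC, PB/PC)
and cMCL exceeds ``drift_min_diff``.  All comparisons are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, samples_for

logger = logging.getLogger(__name__)

#: populations whose means the selection rule needs
REQUIRED_POPULATIONS = ("cMCL", "NBC", "GCBC", "MBC", "PB/PC")


@dataclass(frozen=True)
class SelectionThresholds:
    tumor_max: float = 0.25
    normal_min: float = 0.75
    drift_min_diff: float = 0.25
    drift_populations: tuple[str, ...] = ("GCBC", "MBC", "PB/PC")

    def __post_init__(self):
        if not (0 < self.tumor_max < self.normal_min < 1):
            raise ValueError("need 0 < tumor_max < normal_min < 1")
        if self.drift_min_diff <= 0:
            raise ValueError("drift_min_diff must be > 0")


def population_mean_beta(
    beta: BetaMatrix,
    sample_sheet: pd.DataFrame,
    pool_nbc: bool = True,
) -> pd.DataFrame:
    """Missing-excluded per-population mean beta per CpG.

    Returns a CpG x population DataFrame.  The pooled ``NBC`` column is the
    sample-level mean over NBC-B + NBC-T samples (not the mean of the two
    per-source means); set ``pool_nbc=False`` to use NBC-B samples only.
    The number of samples used per population is stored in
    ``result.attrs["n_samples"]``.
    """
    means = {}
    n_samples = {}
    pops = [p for p in sample_sheet["population"].unique()]
    for pop in pops:
        cols = [s for s in samples_for(sample_sheet, "methylation", pop)
                if s in beta.samples]
        if not cols:
            continue
        means[pop] = beta.values[cols].mean(axis=1, skipna=True)
        n_samples[pop] = len(cols)
    nbc_sources = ("NBC-B", "NBC-T") if pool_nbc else ("NBC-B",)
    nbc_cols = [s for src in nbc_sources
                for s in samples_for(sample_sheet, "methylation", src)
                if s in beta.samples]
    if nbc_cols:
        means["NBC"] = beta.values[nbc_cols].mean(axis=1, skipna=True)
        n_samples["NBC"] = len(nbc_cols)
    out = pd.DataFrame(means)
    n_all_missing = int(out.isna().any(axis=1).sum())
    if n_all_missing:
        logger.info("%d CpGs have a missing population mean", n_all_missing)
    out.attrs["n_samples"] = n_samples
    return out


def select_cmcl_specific(
    pop_means: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Apply the selection rule; returns a per-CpG table with a reason column.

    A CpG is selected iff mean(cMCL) < tumor_max, mean(NBC) > normal_min and
    mean(pop) - mean(cMCL) > drift_min_diff for every drift population.
    CpGs with a missing required mean are excluded and tallied.
    """
    missing_pops = [p for p in REQUIRED_POPULATIONS if p not in pop_means.columns]
    if missing_pops:
        raise ValueError(f"population means missing columns: {missing_pops}")

    out = pop_means.copy()
    required = list(dict.fromkeys(REQUIRED_POPULATIONS + thresholds.drift_populations))
    usable = out[required].notna().all(axis=1)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.warning("%d CpGs excluded for missing required population means", n_excluded)

    reason = pd.Series("", index=out.index, dtype=object)
    reason[~usable] = "missing_mean"
    ok = usable.copy()

    fail_tumor = usable & ~(out["cMCL"] < thresholds.tumor_max)
    reason[fail_tumor] = "tumor_mean_too_high"
    ok &= ~fail_tumor
    fail_normal = ok & ~(out["NBC"] > thresholds.normal_min)
    reason[fail_normal] = "normal_mean_too_low"
    ok &= ~fail_normal
    for pop in thresholds.drift_populations:
        fail = ok & ~((out[pop] - out["cMCL"]) > thresholds.drift_min_diff)
        reason[fail] = f"drift_{pop.replace('/', '')}"
        ok &= ~fail

    out["selected"] = ok
    out["reason"] = reason
    out.attrs["n_excluded_missing"] = n_excluded
    return out


def proximity_fraction(
    cpgs: pd.DataFrame,
    grouping: pd.Series,
    window_bp: int = 50,
) -> pd.Series:
    """Per group, fraction of CpGs with a same-group neighbor within ``window_bp``.

    ``cpgs`` must carry ``chrom`` and ``pos`` columns; ``grouping`` assigns a
    category per CpG (shared index).  Distance is |pos_i - pos_j| on the same
    contig; cross-contig pairs never count.  Empty groups are reported as NaN.
    """
    fractions = {}
    for group, ids in grouping.groupby(grouping).groups.items():
        sub = cpgs.loc[ids]
        if sub.empty:
            fractions[group] = np.nan
            continue
        has_neighbor = np.zeros(len(sub), dtype=bool)
        offset = 0
        for _, chrom_grp in sub.groupby("chrom", sort=False):
            pos = np.sort(chrom_grp["pos"].to_numpy())
            n = len(pos)
            close = np.zeros(n, dtype=bool)
            if n > 1:
                gap = np.diff(pos) <= window_bp
                close[:-1] |= gap
                close[1:] |= gap
            # map back in sorted order; fraction is order-invariant
            has_neighbor[offset : offset + n] = close
            offset += n
        fractions[group] = float(has_neighbor.mean())
    return pd.Series(fractions, name="proximity_fraction")
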