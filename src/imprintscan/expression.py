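"""Stage 5: closest-gene assignment and expression-category enrichment.

Each CpG is assigned to the closest protein-coding gene: intragenic CpGs to
the host gene, intergenic CpGs to the nearest transcription start site.
Genes are classified into six expression categories from FPKM-based
expressed flags and a cMCL vs NBC-B differential-expression test, applying
the rules strictly in order (first match wins):

(i)   not expressed      — not expressed in either cMCL or NBC-B
(ii)  stable expression  — |log2 FC| < 1 or adjusted p >= .1
(iii) lost expression    — expressed in NBC-B but not in cMCL
(iv)  downregulated      — log2 FC <= -1 and adjusted p < .1
(v)   de novo expression — expressed in cMCL but not in NBC-B
(vi)  upregulated        — log2 FC > 1 and adjusted p < .1

Category enrichment of a CpG set uses a probe-density-corrected permutation
null: random CpG samples from the background are reduced to their unique
closest-gene sets inside every simulation, exactly as for the observed set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneModel, samples_for
from .stats import EnrichmentResult, _finalize, benjamini_hochberg

logger = logging.getLogger(__name__)

CATEGORIES = (
    "not expressed",
    "stable expression",
    "lost expression",
    "downregulated",
    "de novo expression",
    "upregulated",
)

DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# closest-gene assignment


def assign_closest_genes(cpgs: pd.DataFrame, gene_models: list[GeneModel]) -> pd.DataFrame:
    """Closest protein-coding gene per CpG.

    Host-gene ties (overlapping genes) are broken by nearest TSS, then
    lexicographic gene id; intergenic CpGs take the nearest TSS with the
    same tie-break.  CpGs on contigs without genes are returned unassigned.
    Returns columns (gene, relation, distance).
    """
    coding = [g for g in gene_models if g.coding]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)

    chrom_arrays = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.gene_id)
        chrom_arrays[chrom] = (
            genes,
            np.array([g.start for g in genes]),
            np.array([g.end for g in genes]),
            np.array([g.tss for g in genes]),
        )

    rows = []
    for probe_id, row in cpgs.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in chrom_arrays:
            rows.append({"gene": None, "relation": "unassigned", "distance": np.nan})
            continue
        genes, starts, ends, tss = chrom_arrays[chrom]
        dist = np.abs(tss - pos)
        inside = (starts <= pos) & (pos < ends)
        if inside.any():
            cand = np.flatnonzero(inside)
            best = cand[np.argmin(dist[cand])]  # ties fall to lowest index = lex id
            rows.append({"gene": genes[best].gene_id, "relation": "intragenic-host",
                         "distance": 0})
        else:
            best = int(np.argmin(dist))
            rows.append({"gene": genes[best].gene_id, "relation": "intergenic-nearest-TSS",
                         "distance": int(dist[best])})
    out = pd.DataFrame(rows, index=cpgs.index)
    n_un = int((out["relation"] == "unassigned").sum())
    if n_un:
        logger.warning("%d CpGs on contigs without protein-coding genes", n_un)
    return out


# ---------------------------------------------------------------------------
# FPKM and expressed flags


def fpkm(counts: pd.DataFrame, gene_lengths_bp: pd.Series) -> pd.DataFrame:
    """FPKM_gs = count_gs / (length_g / 1e3) / (column_total_s / 1e6)."""
    lengths = gene_lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("zero library size")
    return counts.div(lengths / 1e3, axis=0).div(libsize / 1e6, axis=1)


def expression_flags(
    fpkm_matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene, per-population mean log10(FPKM + 0.01) and expressed flags.

    A gene is expressed in a population when the mean log value is strictly
    above 0 (i.e. FPKM > 1 on average in log space).
    """
    logv = np.log10(fpkm_matrix + 0.01)
    out = {}
    for pop in sample_sheet["population"].unique():
        cols = [s for s in samples_for(sample_sheet, "rnaseq", pop)
                if s in fpkm_matrix.columns]
        if not cols:
            continue
        out[f"meanlog_{pop}"] = logv[cols].mean(axis=1)
        out[f"expressed_{pop}"] = out[f"meanlog_{pop}"] > 0
    return pd.DataFrame(out, index=fpkm_matrix.index)


# ---------------------------------------------------------------------------
# simplified negative-binomial Wald test


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with all-positive counts for size factors")
    log_geo = np.log(x[all_pos]).mean(axis=1)
    ratios = np.log(x[all_pos]) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def differential_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    treatment: str,
) -> pd.DataFrame:
    """Negative-binomial Wald test of ``treatment`` vs ``reference``.

    Size factors by median-of-ratios; per-gene dispersion by method of
    moments on normalized counts (pooled within-group), floored; log2 fold
    change of normalized group means with a 0.5 pseudo-count; Wald z from
    the delta-method variance of the log mean under NB sampling; BH
    adjustment.  Returns columns (base_mean, log2fc, p, padj).
    """
    groups = groups.reindex(counts.columns)
    cols_ref = groups.index[groups == reference]
    cols_trt = groups.index[groups == treatment]
    if len(cols_ref) < 2 or len(cols_trt) < 2:
        raise ValueError("each group needs >= 2 samples")
    if counts[cols_ref].to_numpy().sum() == 0 or counts[cols_trt].to_numpy().sum() == 0:
        raise ValueError("a group has zero total counts")

    sf = size_factors(counts[list(cols_ref) + list(cols_trt)])
    norm = counts[sf.index].div(sf, axis=1)
    x_ref = norm[cols_ref].to_numpy(dtype=float)
    x_trt = norm[cols_trt].to_numpy(dtype=float)
    m_ref = x_ref.mean(axis=1)
    m_trt = x_trt.mean(axis=1)

    # method-of-moments dispersion alpha: var = mu + alpha * mu^2, pooled
    def mom_alpha(x, m):
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        return np.where(np.isfinite(a), a, 0.0)

    n_ref, n_trt = x_ref.shape[1], x_trt.shape[1]
    w_ref, w_trt = n_ref - 1, n_trt - 1
    alpha = (mom_alpha(x_ref, m_ref) * w_ref + mom_alpha(x_trt, m_trt) * w_trt) / (w_ref + w_trt)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    log2fc = np.log2(m_trt + 0.5) - np.log2(m_ref + 0.5)
    # delta method: var(ln mean) ~ (1/mu + alpha) / n per group
    var_ln = (1.0 / (m_ref + 0.5) + alpha) / n_ref + (1.0 / (m_trt + 0.5) + alpha) / n_trt
    se_log2 = np.sqrt(var_ln) / np.log(2)
    z = np.where(se_log2 > 0, log2fc / se_log2, 0.0)
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "base_mean": (m_ref * n_ref + m_trt * n_trt) / (n_ref + n_trt),
        "log2fc": log2fc,
        "p": p,
        "padj": benjamini_hochberg(p),
    }, index=counts.index)


# ---------------------------------------------------------------------------
# six-category hierarchy


def classify_expression_categories(
    flags: pd.DataFrame,
    de: pd.DataFrame,
    tumor: str = "cMCL",
    normal: str = "NBC-B",
    strict_loss_precedence: bool = False,
) -> pd.Series:
    """Apply the six-rule expression hierarchy, first match wins.

    With ``strict_loss_precedence`` the lost/de-novo rules are evaluated
    before the stable rule (sensitivity analysis for the literal ordering,
    under which a gene expressed only in one population with a
    non-significant fold change is labeled stable).
    """
    expressed_t = flags[f"expressed_{tumor}"]
    expressed_n = flags[f"expressed_{normal}"]
    out = pd.Series(index=flags.index, dtype=object)

    rule_not = ~expressed_t & ~expressed_n
    out[rule_not] = "not expressed"
    rest = ~rule_not

    de = de.reindex(flags.index)
    need = rest & (de["log2fc"].isna() | de["padj"].isna())
    if need.any():
        raise ValueError(
            f"{int(need.sum())} genes reach the DE-based rules without DE statistics")

    lost = expressed_n & ~expressed_t
    denovo = expressed_t & ~expressed_n
    stable = (de["log2fc"].abs() < 1) | (de["padj"] >= 0.1)
    down = (de["log2fc"] <= -1) & (de["padj"] < 0.1)
    up = (de["log2fc"] > 1) & (de["padj"] < 0.1)

    if strict_loss_precedence:
        order = [(lost, "lost expression"), (denovo, "de novo expression"),
                 (stable, "stable expression"), (down, "downregulated"),
                 (up, "upregulated")]
    else:
        order = [(stable, "stable expression"), (lost, "lost expression"),
                 (down, "downregulated"), (denovo, "de novo expression"),
                 (up, "upregulated")]
    for mask, label in order:
        hit = rest & mask & out.isna()
        out[hit] = label
    if out.isna().any():
        raise ValueError("expression hierarchy failed to classify some genes")
    return out


# ---------------------------------------------------------------------------
# probe-density-corrected gene-category enrichment


def gene_category_enrichment(
    selected_cpg_ids,
    background_cpg_ids,
    assignments: pd.DataFrame,
    gene_categories: pd.Series,
    n_sims: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> list[EnrichmentResult]:
    """Enrichment of expression categories among unique closest genes.

    The observed statistic per category is the fraction of the unique
    closest-gene set of the selection in that category; the null draws
    size-matched CpG samples without replacement from the background and
    maps each sample to its own unique gene set (probe-density correction).
    Genes absent from the expression table are excluded from the fractions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    selected_cpg_ids = pd.Index(selected_cpg_ids)
    background_cpg_ids = pd.Index(background_cpg_ids)
    if len(selected_cpg_ids) == 0 or len(background_cpg_ids) == 0:
        raise ValueError("selection and background must be non-empty")
    if len(selected_cpg_ids) > len(background_cpg_ids):
        raise ValueError("selection larger than background")

    cat_codes = {c: i for i, c in enumerate(CATEGORIES)}

    # encode background CpGs as gene indices with per-gene category codes
    bg_genes = assignments.reindex(background_cpg_ids)["gene"]
    usable = bg_genes.notna().to_numpy()
    bg_ids_usable = background_cpg_ids[usable]
    bg_gene_names = bg_genes[usable].to_numpy()
    uniq_genes, bg_gene_idx = np.unique(bg_gene_names, return_inverse=True)
    gene_cat = gene_categories.reindex(uniq_genes)
    gene_cat_code = np.array([cat_codes.get(c, -1) for c in gene_cat])  # -1 = not in table

    def fractions_from_gene_idx(idx: np.ndarray) -> np.ndarray:
        genes = np.unique(idx)
        codes = gene_cat_code[genes]
        codes = codes[codes >= 0]
        counts = np.bincount(codes, minlength=len(CATEGORIES))
        total = counts.sum()
        return counts / total if total else np.zeros(len(CATEGORIES))

    # observed: unique genes of the selection (mapped independently of bg)
    sel_genes = assignments.reindex(selected_cpg_ids)["gene"].dropna().unique()
    sel_cats = gene_categories.reindex(sel_genes).dropna()
    sel_counts = np.zeros(len(CATEGORIES))
    for c, k in sel_cats.value_counts().items():
        sel_counts[cat_codes[c]] = k
    total = sel_counts.sum()
    if total == 0:
        raise ValueError("no selected gene appears in the expression table")
    observed = sel_counts / total

    n_bg = len(bg_ids_usable)
    n_sel = len(selected_cpg_ids)
    sims = np.empty((n_sims, len(CATEGORIES)))
    for s in range(n_sims):
        take = rng.choice(n_bg, size=min(n_sel, n_bg), replace=False)
        sims[s] = fractions_from_gene_idx(bg_gene_idx[take])

    bg_frac = fractions_from_gene_idx(np.arange(len(uniq_genes)))
    return _finalize(list(CATEGORIES), observed, sims, n_sims, 1.0, bg_frac)
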