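"""Stage 2: chromatin-state classification and genic-annotation scores.

Each CpG gets a per-population hierarchical category from the ChromHMM-style
states of that population's samples, prioritizing active annotations:

1. ActivePromoter      — any sample in E1
2. ActiveTranscription — any sample in E7
3. ActiveEnhancer      — any sample in E2 or E6
4. Other               — any sample in E3, E4 or E9
5. Primed              — any sample in E5
6. Inactive            — none of the above (E8, E10, E11, E12 only)

The three Active subcategories merge into a single ``Active`` class.
Accessibility peaks split Active CpGs into ActiveAccessible /
ActiveInaccessible; non-Active CpGs keep the flag for reporting only.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .io import GeneModel, SegmentationTrack
from .stats import EnrichmentResult, weighted_mc_enrichment

HIERARCHY: tuple[tuple[str, frozenset[int]], ...] = (
    ("ActivePromoter", frozenset({1})),
    ("ActiveTranscription", frozenset({7})),
    ("ActiveEnhancer", frozenset({2, 6})),
    ("Other", frozenset({3, 4, 9})),
    ("Primed", frozenset({5})),
)

HIERARCHICAL_CATEGORIES = tuple(name for name, _ in HIERARCHY) + ("Inactive",)
MERGED_CATEGORIES = ("Active", "Other", "Primed", "Inactive")

ANNOTATIONS = (
    "intergenic", "1-5kb_upstream", "promoter", "5UTR",
    "first_exon", "exon", "intron", "3UTR",
)


def state_at_position(segmentation: SegmentationTrack, chrom: str, pos: int) -> str:
    """Chromatin state of the half-open bin containing ``pos``."""
    return segmentation.state_at(chrom, pos)


def classify_population_state(states) -> str:
    """Hierarchical category for a population's per-sample state set.

    ``states`` is an iterable of 'E1'..'E12' labels or integer indices,
    one per sample of the population.
    """
    idx = set()
    for s in states:
        i = int(str(s).lstrip("E"))
        if not 1 <= i <= 12:
            raise ValueError(f"unknown chromatin state {s!r}")
        idx.add(i)
    if not idx:
        raise ValueError("empty state set")
    for name, members in HIERARCHY:
        if idx & members:
            return name
    return "Inactive"


def merge_active(category: str) -> str:
    """Collapse the three Active subcategories into 'Active'."""
    if category not in HIERARCHICAL_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return "Active" if category.startswith("Active") else category


def classify_cpgs(
    cpgs: pd.DataFrame,
    tracks: dict[str, SegmentationTrack],
    population_of: dict[str, str],
) -> pd.DataFrame:
    """Per-CpG hierarchical and merged categories for each population.

    ``tracks`` maps sample id -> segmentation; ``population_of`` maps sample
    id -> population label.  Returns a DataFrame indexed like ``cpgs`` with
    columns ``state_<pop>`` and ``merged_<pop>``.
    """
    chroms = cpgs["chrom"].to_numpy()
    positions = cpgs["pos"].to_numpy()
    by_pop: dict[str, list[np.ndarray]] = {}
    for sample, track in tracks.items():
        pop = population_of[sample]
        by_pop.setdefault(pop, []).append(track.states_at(chroms, positions))

    out = pd.DataFrame(index=cpgs.index)
    for pop, cols in by_pop.items():
        mat = np.stack(cols, axis=1)  # cpgs x samples, state ints
        cats = np.empty(mat.shape[0], dtype=object)
        cats[:] = "Inactive"
        assigned = np.zeros(mat.shape[0], dtype=bool)
        for name, members in HIERARCHY:
            hit = np.isin(mat, list(members)).any(axis=1) & ~assigned
            cats[hit] = name
            assigned |= hit
        out[f"state_{pop}"] = cats
        out[f"merged_{pop}"] = [merge_active(c) for c in cats]
    return out


def split_by_accessibility(
    cpgs: pd.DataFrame,
    peaks: pd.DataFrame,
    merged_category: pd.Series,
) -> pd.DataFrame:
    """Flag CpGs inside accessibility peaks and refine Active categories.

    A CpG is accessible iff its position lies in at least one half-open
    peak interval.  Active CpGs become ActiveAccessible/ActiveInaccessible;
    other categories keep the flag but not a refined category.
    """
    accessible = pd.Series(False, index=cpgs.index)
    for chrom, grp in peaks.groupby("chrom"):
        mask = cpgs["chrom"] == chrom
        if not mask.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        order = np.argsort(grp["start"].to_numpy())
        ends = grp["end"].to_numpy()[order]
        # allow overlapping peaks: running max of ends up to each start
        run_end = np.maximum.accumulate(ends)
        pos = cpgs.loc[mask, "pos"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < run_end[np.clip(i, 0, None)])
        accessible.loc[mask] = inside
    refined = merged_category.copy().astype(object)
    is_active = merged_category == "Active"
    refined[is_active & accessible] = "ActiveAccessible"
    refined[is_active & ~accessible] = "ActiveInaccessible"
    return pd.DataFrame({"accessible": accessible, "refined_category": refined})


# ---------------------------------------------------------------------------
# fractionated genic-annotation scores


def _transcript_features(gene: GeneModel) -> list[tuple[str, int, int]]:
    """Genic feature intervals (0-based half-open) of one transcript."""
    feats: list[tuple[str, int, int]] = []
    tss = gene.tss
    if gene.strand == "+":
        feats.append(("promoter", max(0, tss - 1000), tss))
        feats.append(("1-5kb_upstream", max(0, tss - 5000), max(0, tss - 1000)))
    else:
        feats.append(("promoter", tss + 1, tss + 1001))
        feats.append(("1-5kb_upstream", tss + 1001, tss + 5001))

    exons = list(zip(gene.exon_starts, gene.exon_ends))
    exons.sort()
    first = exons[0] if gene.strand == "+" else exons[-1]
    for s, e in exons:
        feats.append(("exon", s, e))
        if (s, e) == first:
            feats.append(("first_exon", s, e))
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if e1 < s2:
            feats.append(("intron", e1, s2))

    if gene.coding:
        cs, ce = gene.cds_start, gene.cds_end
        for s, e in exons:
            # exonic sequence outside the CDS is UTR
            if s < cs:
                left = ("5UTR" if gene.strand == "+" else "3UTR", s, min(e, cs))
                feats.append(left)
            if e > ce:
                right = ("3UTR" if gene.strand == "+" else "5UTR", max(s, ce), e)
                feats.append(right)
    return [(a, s, e) for a, s, e in feats if s < e]


def fractionated_annotation_scores(
    cpgs: pd.DataFrame,
    gene_models: list[GeneModel],
    exact: bool = False,
) -> pd.DataFrame:
    """Per-CpG genic-annotation weights summing to one.

    Every (transcript, feature) interval containing the CpG position counts
    one hit; if any first-exon hit exists the plain exon hits are removed to
    avoid redundancy; weights are hits/total.  A CpG hit by nothing gets
    {intergenic: 1}.  With ``exact=True`` weights are computed in rational
    arithmetic before conversion to float.
    """
    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for gene in gene_models:
        by_chrom.setdefault(gene.chrom, []).extend(_transcript_features(gene))

    # flatten to arrays per chromosome for fast point-in-interval queries
    ann_index = {a: i for i, a in enumerate(ANNOTATIONS)}
    chrom_arrays = {}
    for chrom, feats in by_chrom.items():
        starts = np.array([s for _, s, _ in feats])
        ends = np.array([e for _, _, e in feats])
        codes = np.array([ann_index[a] for a, _, _ in feats])
        chrom_arrays[chrom] = (starts, ends, codes)

    weights = np.zeros((len(cpgs), len(ANNOTATIONS)))
    positions = cpgs["pos"].to_numpy()
    chroms = cpgs["chrom"].to_numpy()
    i_first, i_exon, i_inter = (ann_index["first_exon"], ann_index["exon"],
                                ann_index["intergenic"])
    for row, (chrom, pos) in enumerate(zip(chroms, positions)):
        arrays = chrom_arrays.get(chrom)
        hits = np.zeros(len(ANNOTATIONS), dtype=np.int64)
        if arrays is not None:
            starts, ends, codes = arrays
            inside = (starts <= pos) & (pos < ends)
            if inside.any():
                hits = np.bincount(codes[inside], minlength=len(ANNOTATIONS))
        if hits[i_first] > 0:
            hits[i_exon] = 0
        total = hits.sum()
        if total == 0:
            weights[row, i_inter] = 1.0
        elif exact:
            for j, h in enumerate(hits):
                weights[row, j] = float(Fraction(int(h), int(total)))
        else:
            weights[row] = hits / total
    return pd.DataFrame(weights, index=cpgs.index, columns=list(ANNOTATIONS))


def annotation_enrichment(
    selected_weights: pd.DataFrame,
    background_weights: pd.DataFrame,
    n_sims: int,
    seed: int | np.random.Generator,
) -> list[EnrichmentResult]:
    """Monte-Carlo enrichment of summed fractionated annotation weights.

    The observed statistic per annotation is the sum of weights over the
    selected CpGs; the null is the same statistic over size-matched samples
    from the background, with the usual (r+1)/(n+1) scoring.
    """
    for df, which in ((selected_weights, "selection"), (background_weights, "background")):
        sums = df.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{which} weights must sum to 1 per CpG")
    return weighted_mc_enrichment(selected_weights, background_weights, n_sims, seed)
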