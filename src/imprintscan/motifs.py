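"""Stage 4: PWM motif enrichment with a lognormal tile background.

Each CpG is extended by ``flank`` bp on each side; background base
frequencies computed from the background windows convert PFMs into log2-odds
PWMs.  A sequence's affinity for a motif is the mean, over all windows on
both strands, of 2**(sum of PWM entries), i.e. the average odds of the
sequence under the motif versus the background composition.  Per motif, a
lognormal null is fitted to the affinities of the ~100-bp background
windows (the "tiles"); group-level enrichment of a target set of N windows
tests the mean log affinity, whose null under the fitted lognormal is
exactly Normal(mu, sigma^2/N) (a Fenton–Wilkinson mean-odds variant is
available).  A motif is called enriched when its group p-value is
below .05 and it ranks within the top 5% of motifs in at least 10% of the
target sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PFM
from .stats import benjamini_hochberg, fisher_exact_2x2

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# selection rule constants
TOP_RANK_FRACTION = 0.05
MIN_TOP_PCT = 10.0
MAX_P = 0.05


@dataclass
class MotifModel:
    """PFM + background-corrected log2-odds PWM + fitted lognormal null."""

    motif_id: str
    name: str
    pfm: np.ndarray
    pwm: np.ndarray
    mu: float = math.nan
    sigma: float = math.nan


# ---------------------------------------------------------------------------
# sequence handling


def extract_windows(
    cpgs: pd.DataFrame,
    genome,
    flank: int = 50,
) -> tuple[pd.Index, list[str]]:
    """Plus-strand sequences of length 2*flank+1 centered on each CpG.

    ``genome`` is a mapping contig -> sequence string (e.g. a pyfaidx.Fasta
    works via __getitem__ slicing on str()).  CpGs whose window would cross
    a contig end are dropped and logged.
    """
    ids, seqs = [], []
    lengths = {}
    n_dropped = 0
    for probe_id, row in cpgs.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in lengths:
            try:
                contig = genome[chrom]
            except KeyError as exc:
                raise KeyError(f"CpG {probe_id} on unknown contig {chrom}") from exc
            lengths[chrom] = len(contig)
        start, end = pos - flank, pos + flank + 1
        if start < 0 or end > lengths[chrom]:
            n_dropped += 1
            continue
        seq = str(genome[chrom][start:end]).upper()
        ids.append(probe_id)
        seqs.append(seq)
    if n_dropped:
        logger.warning("dropped %d CpGs with windows crossing contig ends", n_dropped)
    return pd.Index(ids), seqs


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as int codes (A=0..T=3, other=4)."""
    if not seqs:
        raise ValueError("no sequences")
    n, L = len(seqs), len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    lut = np.full(256, 4, dtype=np.int8)
    for b, c in BASE_TO_CODE.items():
        lut[ord(b)] = c
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return lut[flat].reshape(n, L)


def base_frequencies(seqs: list[str]) -> np.ndarray:
    """ACGT frequencies over a set of sequences (non-ACGT ignored)."""
    codes = encode_sequences(seqs)
    counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("no ACGT bases in sequences")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# PWM construction and scoring


def pfm_to_pwm(pfm: PFM | np.ndarray, background_freqs) -> np.ndarray:
    """Log2-odds PWM with pseudocount mass k=1 distributed by background.

    Column probabilities are (count_b + q_b) / (N_col + 1) with q the
    background base frequencies; entries are log2(p_b / q_b).
    """
    counts = pfm.counts if isinstance(pfm, PFM) else np.asarray(pfm, dtype=float)
    q = np.asarray(background_freqs, dtype=float)
    if q.shape != (4,) or (q <= 0).any() or not math.isclose(q.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("background frequencies must be positive and sum to 1")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total PFM column")
    probs = (counts + q[:, None]) / (totals[None, :] + 1.0)
    return np.log2(probs / q[:, None])


def _window_log2_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Per-window log2 sums for all plus-strand windows; NaN where invalid.

    ``codes`` is (n_seq, L_seq); returns (n_seq, L_seq - L + 1).
    """
    n, L_seq = codes.shape
    L = pwm.shape[1]
    W = L_seq - L + 1
    if W < 1:
        raise ValueError("sequence shorter than motif")
    acc = np.zeros((n, W))
    valid = np.ones((n, W), dtype=bool)
    pwm_ext = np.vstack([pwm, np.zeros((1, L))])  # row 4: placeholder for non-ACGT
    for j in range(L):
        col_codes = codes[:, j : j + W]
        acc += pwm_ext[col_codes, j]
        valid &= col_codes < 4
    acc[~valid] = np.nan
    return acc


def affinity_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Mean-odds affinity per sequence over all windows on both strands.

    Windows containing non-ACGT bases are skipped; a sequence with no valid
    window raises.
    """
    fwd = _window_log2_scores(codes, pwm)
    # reverse strand: score the reverse complement of each window, which is
    # equivalent to scoring the sequence with the reverse-complemented PWM
    pwm_rc = pwm[::-1, ::-1]
    rev = _window_log2_scores(codes, pwm_rc)
    both = np.concatenate([fwd, rev], axis=1)
    with np.errstate(over="ignore"):
        odds = np.exp2(both)
    n_valid = (~np.isnan(odds)).sum(axis=1)
    if (n_valid == 0).any():
        raise ValueError("sequence with no valid scoring window")
    return np.nansum(odds, axis=1) / n_valid


def affinity_score(sequence: str, pwm: np.ndarray) -> float:
    """Affinity of a single sequence (convenience wrapper)."""
    return float(affinity_scores(encode_sequences([sequence]), pwm)[0])


# ---------------------------------------------------------------------------
# lognormal null


def fit_lognormal_background(scores: np.ndarray, min_tiles: int = 30) -> tuple[float, float]:
    """Fit (mu, sigma) of ln(affinity) over background tiles.

    NaN scores (tiles with no valid window) are skipped; sigma is floored
    at 1e-6 to keep the null proper for degenerate inputs.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if len(scores) < min_tiles:
        raise ValueError(f"need >= {min_tiles} background tiles, got {len(scores)}")
    if (scores <= 0).any():
        raise ValueError("non-positive affinity score")
    logs = np.log(scores)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma < SIGMA_FLOOR:
        logger.warning("degenerate background: sigma floored at %g", SIGMA_FLOOR)
        sigma = SIGMA_FLOOR
    return mu, sigma


def group_pvalue(
    target_scores: np.ndarray,
    mu: float,
    sigma: float,
    statistic: str = "geom_mean",
) -> float:
    """Upper-tail p of a group affinity statistic under the lognormal null.

    With the default ``geom_mean`` statistic the test uses the mean of the
    log affinities over the N target sequences; under the fitted
    LogNormal(mu, sigma^2) null that mean is exactly Normal(mu, sigma^2/N),
    which keeps the group p-value calibrated even when the raw affinity
    distribution is heavier-tailed than lognormal.

    ``arith_mean`` instead tests the mean raw affinity against a
    Fenton–Wilkinson lognormal approximation of the mean of N i.i.d.
    lognormal scores (matched first two moments):

        sigma_N^2 = ln(1 + (e^(sigma^2) - 1) / N)
        mu_N      = mu + sigma^2 / 2 - sigma_N^2 / 2

    For N = 1 both reduce to the plain lognormal upper tail.
    """
    scores = np.asarray(target_scores, dtype=float)
    if scores.size < 1:
        raise ValueError("empty target set")
    if (scores <= 0).any():
        raise ValueError("non-positive affinity score")
    n = scores.size
    if statistic == "geom_mean":
        stat = float(np.log(scores).mean())
        return float(sps.norm.sf((stat - mu) / (sigma / math.sqrt(n))))
    if statistic == "arith_mean":
        stat = scores.mean()
        sigma_n_sq = math.log1p(math.expm1(sigma**2) / n)
        sigma_n = max(math.sqrt(sigma_n_sq), SIGMA_FLOOR)
        mu_n = mu + sigma**2 / 2 - sigma_n_sq / 2
        return float(sps.norm.sf((math.log(stat) - mu_n) / sigma_n))
    raise ValueError(f"unknown statistic {statistic!r}")


def sequence_pvalues(scores: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Per-sequence lognormal upper-tail p-values."""
    return sps.norm.sf((np.log(scores) - mu) / sigma)


def top_motif_percentage(pvalue_matrix: np.ndarray) -> np.ndarray:
    """Percentage of sequences where each motif ranks in the top 5%.

    ``pvalue_matrix`` is motifs x sequences of per-sequence p-values.
    Per sequence, motifs are ranked ascending by p; ties share the minimal
    rank; a motif counts as top when its rank <= ceil(0.05 * n_motifs).
    """
    M, n_seq = pvalue_matrix.shape
    if M < 2:
        raise ValueError("need at least 2 motifs to rank")
    cutoff = math.ceil(TOP_RANK_FRACTION * M)
    ranks = sps.rankdata(pvalue_matrix, method="min", axis=0)
    return 100.0 * (ranks <= cutoff).mean(axis=1)


# ---------------------------------------------------------------------------
# end-to-end motif enrichment


def run_motif_enrichment(
    target_cpgs: pd.DataFrame,
    background_cpgs: pd.DataFrame,
    pfms: list[PFM],
    genome,
    flank: int = 50,
    background_scores: pd.DataFrame | None = None,
    statistic: str = "geom_mean",
) -> pd.DataFrame:
    """Motif enrichment of target windows against the CpG background.

    Any CpG present in both sets is removed from the background with a
    warning.  ``background_scores`` (motifs x background windows), e.g. from
    :func:`score_background`, can be passed to reuse one scored background
    across categories.  Returns a DataFrame ranked by p-value with columns
    (motif, tf, raw_score, p, top_pct, selected).
    """
    overlap = target_cpgs.index.intersection(background_cpgs.index)
    if len(overlap):
        logger.warning("removing %d CpGs from background that are also targets", len(overlap))
        background_cpgs = background_cpgs.drop(overlap)

    target_ids, target_seqs = extract_windows(target_cpgs, genome, flank)
    if not target_seqs:
        raise ValueError("no usable target windows")
    if background_scores is None:
        background_scores = score_background(background_cpgs, pfms, genome, flank)
    target_codes = encode_sequences(target_seqs)

    rows = []
    pval_matrix = np.empty((len(pfms), len(target_seqs)))
    for i, pfm in enumerate(pfms):
        info = background_scores.attrs["models"][pfm.motif_id]
        scores = affinity_scores(target_codes, info.pwm)
        p = group_pvalue(scores, info.mu, info.sigma, statistic=statistic)
        pval_matrix[i] = sequence_pvalues(scores, info.mu, info.sigma)
        rows.append({"motif": pfm.motif_id, "tf": pfm.name,
                     "raw_score": float(scores.mean()), "p": p})
    top_pct = top_motif_percentage(pval_matrix)
    out = pd.DataFrame(rows)
    out["top_pct"] = top_pct
    out["selected"] = (out["top_pct"] >= MIN_TOP_PCT) & (out["p"] < MAX_P)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def score_background(
    background_cpgs: pd.DataFrame,
    pfms: list[PFM],
    genome,
    flank: int = 50,
) -> pd.DataFrame:
    """Score background windows for every motif and fit the lognormal nulls.

    Returns a motifs x windows DataFrame of affinities whose ``attrs`` carry
    the fitted :class:`MotifModel` per motif and the background base
    frequencies.
    """
    bg_ids, bg_seqs = extract_windows(background_cpgs, genome, flank)
    if not bg_seqs:
        raise ValueError("no usable background windows")
    freqs = base_frequencies(bg_seqs)
    codes = encode_sequences(bg_seqs)
    models: dict[str, MotifModel] = {}
    mat = np.empty((len(pfms), len(bg_seqs)))
    for i, pfm in enumerate(pfms):
        pwm = pfm_to_pwm(pfm, freqs)
        scores = affinity_scores(codes, pwm)
        mu, sigma = fit_lognormal_background(scores)
        models[pfm.motif_id] = MotifModel(pfm.motif_id, pfm.name, pfm.counts, pwm, mu, sigma)
        mat[i] = scores
    out = pd.DataFrame(mat, index=[p.motif_id for p in pfms], columns=bg_ids)
    out.attrs["models"] = models
    out.attrs["base_frequencies"] = freqs
    return out


# ---------------------------------------------------------------------------
# TF peak (ReMap-style) overlap enrichment


def remap_binding_enrichment(
    target_cpgs: pd.DataFrame,
    background_cpgs: pd.DataFrame,
    tf_peaks: pd.DataFrame,
    flank: int = 50,
    tfs: list[str] | None = None,
    min_background_bound: int = 5,
) -> pd.DataFrame:
    """Per-TF Fisher tests of peak overlap in the ±flank window around CpGs.

    ``tf_peaks`` is BED-like with the TF name in the ``name`` column; one
    file, many TFs.  A CpG is bound by a TF when [pos - flank, pos + flank]
    intersects at least one of its peaks.  Returns a DataFrame with columns
    (tf, n_target_bound, n_bg_bound, odds_ratio, p, padj, low_background,
    assessable); TFs with fewer than ``min_background_bound`` bound
    background CpGs are flagged.
    """
    if "name" not in tf_peaks.columns:
        raise ValueError("TF peak table needs a name column with the TF")
    wanted = sorted(set(tfs)) if tfs is not None else sorted(tf_peaks["name"].unique())

    def bound_counts(cpgs: pd.DataFrame, peaks: pd.DataFrame) -> int:
        bound = np.zeros(len(cpgs), dtype=bool)
        for chrom, grp in peaks.groupby("chrom"):
            mask = (cpgs["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            order = np.argsort(grp["start"].to_numpy())
            starts = grp["start"].to_numpy()[order]
            run_end = np.maximum.accumulate(grp["end"].to_numpy()[order])
            pos = cpgs.loc[mask, "pos"].to_numpy()
            # window [pos-flank, pos+flank] intersects peak [s, e) iff
            # s <= pos + flank and e > pos - flank
            i = np.searchsorted(starts, pos + flank, side="right") - 1
            inside = (i >= 0) & (run_end[np.clip(i, 0, None)] > pos - flank)
            bound[mask] = inside
        return int(bound.sum())

    rows = []
    n_t, n_b = len(target_cpgs), len(background_cpgs)
    for tf in wanted:
        peaks = tf_peaks[tf_peaks["name"] == tf]
        if peaks.empty:
            rows.append({"tf": tf, "n_target_bound": 0, "n_bg_bound": 0,
                         "odds_ratio": math.nan, "p": math.nan,
                         "low_background": True, "assessable": False})
            continue
        tb = bound_counts(target_cpgs, peaks)
        bb = bound_counts(background_cpgs, peaks)
        if tb == 0 and bb == 0:
            rows.append({"tf": tf, "n_target_bound": 0, "n_bg_bound": 0,
                         "odds_ratio": math.nan, "p": math.nan,
                         "low_background": True, "assessable": False})
            continue
        odds, p = fisher_exact_2x2(tb, n_t - tb, bb, n_b - bb)
        rows.append({"tf": tf, "n_target_bound": tb, "n_bg_bound": bb,
                     "odds_ratio": odds, "p": p,
                     "low_background": bb < min_background_bound, "assessable": True})
    out = pd.DataFrame(rows)
    mask = out["assessable"]
    padj = np.full(len(out), np.nan)
    if mask.any():
        padj[mask.to_numpy()] = benjamini_hochberg(out.loc[mask, "p"].to_numpy())
    out["padj"] = padj
    return out
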