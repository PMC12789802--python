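"""Shared statistical engine.

The central primitive is a scored Monte-Carlo permutation test: ``n_sims``
random samplings without replacement are drawn from a background set, the
sample size matched to the selection, and for each annotation class a
simulation scores 1 when its simulated count is >= the observed count
(enrichment) or <= it (depletion).  P-values follow the add-one rule

    P = (r + 1) / (n + 1),

treating the observed sample as one of the permutations, so the smallest
attainable p-value is 1/(n+1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Observed-vs-permutation-null result for one annotation class."""

    label: str
    observed: float
    expected: float            # permutation mean of the statistic
    expected_analytic: float   # analytic proportion-based expectation
    fold: float                # observed / expected (inf marker if expected 0)
    r_enrich: int
    r_deplete: int
    n_sims: int
    p_enrich: float
    p_deplete: float

    def __post_init__(self):
        assert 0 <= self.r_enrich <= self.n_sims
        assert 0 <= self.r_deplete <= self.n_sims


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    return df.rename(columns={"label": "class", "n_sims": "n"})


def _finalize(labels, observed, sims, n_sims, n_selected, bg_frac) -> list[EnrichmentResult]:
    """Score simulated statistics against observed ones.

    ``sims`` has shape (n_sims, n_classes); ``observed`` length n_classes.
    """
    r_enr = (sims >= observed[None, :]).sum(axis=0)
    r_dep = (sims <= observed[None, :]).sum(axis=0)
    expected = sims.mean(axis=0)
    out = []
    for j, label in enumerate(labels):
        exp = float(expected[j])
        obs = float(observed[j])
        fold = obs / exp if exp > 0 else math.inf
        out.append(EnrichmentResult(
            label=str(label),
            observed=obs,
            expected=exp,
            expected_analytic=float(bg_frac[j] * n_selected),
            fold=fold,
            r_enrich=int(r_enr[j]),
            r_deplete=int(r_dep[j]),
            n_sims=n_sims,
            p_enrich=(int(r_enr[j]) + 1) / (n_sims + 1),
            p_deplete=(int(r_dep[j]) + 1) / (n_sims + 1),
        ))
    return out


def monte_carlo_enrichment(
    selected_labels,
    background_labels,
    n_sims: int,
    seed: int | np.random.Generator,
) -> list[EnrichmentResult]:
    """Permutation enrichment/depletion test on class labels.

    For each class, simulated class counts in size-matched random samples
    (without replacement) from the background are compared to the observed
    count in the selection.  Sampling without replacement followed by
    counting is realized exactly as a multivariate hypergeometric draw over
    the background class counts, which is distributionally identical to a
    per-item shuffle at O(classes) cost per simulation.

    The selection may be a subset of the background or disjoint from it;
    both contracts lead to the same simulation (samples are always drawn
    from the background).
    """
    selected = np.asarray(selected_labels)
    background = np.asarray(background_labels)
    if selected.size == 0 or background.size == 0:
        raise ValueError("selection and background must be non-empty")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if selected.size > background.size:
        raise ValueError("selection larger than background")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    orphan = set(np.unique(selected)) - set(np.unique(background))
    if orphan:
        logger.warning("classes present in selection but absent from background: %s",
                       sorted(map(str, orphan)))
    labels = sorted(set(np.unique(background)) | orphan, key=str)
    sel_onehot = pd.DataFrame(
        {c: (selected == c).astype(float) for c in labels})
    bg_onehot = pd.DataFrame(
        {c: (background == c).astype(float) for c in labels})
    return weighted_mc_enrichment(sel_onehot, bg_onehot, n_sims, rng)


def weighted_mc_enrichment(
    selected_weights: pd.DataFrame,
    background_weights: pd.DataFrame,
    n_sims: int,
    seed: int | np.random.Generator,
    atol: float = 1e-9,
) -> list[EnrichmentResult]:
    """Permutation test where each item carries a weight vector over classes.

    The statistic per class is the sum of weights over the selection;
    the null is the same statistic over size-matched samples from the
    background.  Items are grouped by distinct weight profile so the
    without-replacement sample reduces to a multivariate hypergeometric
    draw over profiles — exact, and independent of background size.
    """
    if selected_weights.empty or background_weights.empty:
        raise ValueError("selection and background must be non-empty")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    cols = list(background_weights.columns)
    if list(selected_weights.columns) != cols:
        raise ValueError("selection and background must share class columns")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bw = background_weights.to_numpy(dtype=float)
    sw = selected_weights.to_numpy(dtype=float)
    n_sel = sw.shape[0]
    if n_sel > bw.shape[0]:
        raise ValueError("selection larger than background")
    observed = sw.sum(axis=0)

    # group background rows by weight profile (rounded to kill fp jitter)
    profiles, inverse = np.unique(np.round(bw / atol).astype(np.int64),
                                  axis=0, return_inverse=True)
    profile_w = profiles.astype(float) * atol
    counts = np.bincount(inverse, minlength=profiles.shape[0]).astype(np.int64)
    sims_counts = rng.multivariate_hypergeometric(counts, n_sel, size=n_sims)
    sims = sims_counts.astype(float) @ profile_w

    bg_frac = bw.mean(axis=0)
    return _finalize(cols, observed, sims, n_sims, n_sel, bg_frac)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) of Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if k < 0:
        k = 0
    if k > min(n, K):
        return 0.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns the conditional-MLE odds ratio and the two-sided p-value
    obtained by summing the probabilities of all tables with the same
    margins that are as or less probable than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    table = [[a, b], [c, d]]
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    odds = float(sps.contingency.odds_ratio(table, kind="conditional").statistic)
    return odds, min(p, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
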