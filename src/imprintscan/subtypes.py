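"""Stage 3: NBC-het / NBC-hom subdivision of inactive CpGs.

Inactive demethylated CpGs are clustered on their methylation profiles
across the naive-B-cell (NBC) samples.  The dendrogram (agglomerative,
Euclidean distance, complete linkage) is cut into two clusters; the cluster
with the lower mean of per-CpG NBC means is labeled NBC-het (consistent
with an intermediately demethylated hidden subpopulation), the other
NBC-hom (uniformly high NBC methylation, i.e. tumor-specific imprints).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

LABELS = ("NBC-het", "NBC-hom")


def cluster_inactive_cpgs(
    beta_submatrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> pd.DataFrame:
    """Cluster CpG rows into two groups and label them het/hom.

    ``beta_submatrix`` is inactive CpGs x NBC samples.  Missing values are
    imputed by the CpG row mean (logged).  Returns a DataFrame with columns
    ``cluster`` (1/2), ``label`` and ``mean_nbc``; clustering metadata is
    stored in ``result.attrs``.
    """
    if beta_submatrix.shape[0] < 2:
        raise ValueError("need at least 2 CpGs to cluster")
    x = beta_submatrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        n_bad = int(np.isnan(x).any(axis=1).sum())
        logger.warning("imputing missing NBC values in %d CpG rows by row mean", n_bad)
        row_mean = np.nanmean(x, axis=1)
        idx = np.where(np.isnan(x))
        x[idx] = row_mean[idx[0]]

    mean_nbc = x.mean(axis=1)
    if not np.any(pdist(x, metric=metric)):
        logger.warning("all rows identical: degenerate clustering, assigning all to NBC-hom")
        out = pd.DataFrame({
            "cluster": 1, "label": "NBC-hom", "mean_nbc": mean_nbc,
        }, index=beta_submatrix.index)
        out.attrs.update(metric=metric, linkage=linkage, degenerate=True)
        return out

    Z = sch.linkage(x, method=linkage, metric=metric)
    clusters = sch.fcluster(Z, t=2, criterion="maxclust")
    m1 = mean_nbc[clusters == 1].mean()
    m2 = mean_nbc[clusters == 2].mean()
    het_cluster = 1 if m1 <= m2 else 2
    labels = np.where(clusters == het_cluster, "NBC-het", "NBC-hom")
    out = pd.DataFrame({
        "cluster": clusters, "label": labels, "mean_nbc": mean_nbc,
    }, index=beta_submatrix.index)
    out.attrs.update(metric=metric, linkage=linkage, degenerate=False,
                     silhouette=_mean_silhouette(x, clusters, metric))
    return out


def _mean_silhouette(x: np.ndarray, clusters: np.ndarray, metric: str) -> float:
    """Mean silhouette width of a 2-cluster partition (diagnostic only)."""
    from scipy.spatial.distance import squareform

    d = squareform(pdist(x, metric=metric))
    s = []
    for i in range(len(x)):
        same = (clusters == clusters[i])
        same[i] = False
        other = clusters != clusters[i]
        if not same.any() or not other.any():
            s.append(0.0)
            continue
        a = d[i, same].mean()
        b = d[i, other].mean()
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


def best_split_threshold(
    mean_nbc: pd.Series,
    labels: pd.Series,
) -> tuple[float, int]:
    """DNAm value that best separates het from hom by per-CpG mean NBC beta.

    The rule is ``mean < t -> NBC-het``.  Candidate thresholds are midpoints
    of consecutive distinct observed means (plus open ends); the threshold
    minimizing misclassifications is returned, ties resolved to the midpoint
    of the tightest bracketing pair of observed means.  Returns
    ``(threshold, n_errors)``.
    """
    labels = labels.reindex(mean_nbc.index)
    if labels.nunique() < 2:
        raise ValueError("both labels must be present")
    values = mean_nbc.to_numpy(dtype=float)
    is_het = (labels == "NBC-het").to_numpy()

    uniq = np.unique(values)
    if len(uniq) == 1:
        raise ValueError("all means identical; no separating threshold exists")
    mids = (uniq[:-1] + uniq[1:]) / 2
    gaps = np.diff(uniq)

    best_t, best_err, best_gap = None, None, None
    for t, gap in zip(mids, gaps):
        pred_het = values < t
        err = int((pred_het != is_het).sum())
        if best_err is None or err < best_err or (err == best_err and gap < best_gap):
            best_t, best_err, best_gap = float(t), err, float(gap)
    return best_t, best_err
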