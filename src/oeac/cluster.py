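"""Unsupervised sanity check: hierarchical clustering of sample profiles.

Methylation profiles from this kind of multi-species panel separate first
by tissue and only secondarily by species, so an average-linkage cut at
k = 2 recovering the tissue labels is a quick QC that the matrix is not
scrambled.  The distance between two samples is 1 minus the Pearson
correlation of their beta profiles, computed over probes observed in both
(pairwise-complete), which avoids imputing at the QC stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["correlation_distance_matrix", "hierarchical_cluster"]


def correlation_distance_matrix(beta: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson distance between sample columns.

    Missing betas are excluded pairwise.  Symmetric with zero diagonal.
    A pair of samples with a constant overlapping profile has undefined
    correlation and is assigned the maximal distance 1 (r treated as 0).
    """
    x = beta.to_numpy(dtype=float)
    if np.all(np.isnan(x), axis=0).any():
        bad = [c for c, col in zip(beta.columns, x.T) if np.all(np.isnan(col))]
        raise ValueError(f"sample profile(s) entirely missing: {bad}")
    if not np.isnan(x).any():
        r = np.corrcoef(x.T)
        r = np.nan_to_num(r, nan=0.0)
    else:
        n = x.shape[1]
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
                if ok.sum() < 2:
                    rij = 0.0
                else:
                    a, b = x[ok, i], x[ok, j]
                    sa, sb = a.std(), b.std()
                    rij = 0.0 if sa == 0 or sb == 0 else float(np.corrcoef(a, b)[0, 1])
                r[i, j] = r[j, i] = rij
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # guard tiny negative values from floating error before squareform
    return np.clip((d + d.T) / 2.0, 0.0, None)


def hierarchical_cluster(beta: pd.DataFrame, k: int) -> pd.Series:
    """Average-linkage clustering of samples; returns the k-cluster labels.

    Labels are integers 1..k indexed by sample id.
    """
    n = beta.shape[1]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    d = correlation_distance_matrix(beta)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=beta.columns, name="cluster")
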