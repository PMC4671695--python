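"""K-means staging of expression profiles and newly-expressed-gene calling.

Profiles are clustered on shape (log2(FPKM+1), per-row z-score) while the
newly/highly-expressed thresholds are applied on raw FPKM — clustering on
shape, filtering on level.  The clustering contract is Lloyd iterations from
k-means++ starts with the best of ``n_starts`` kept by total within-cluster
SSE; the SSE is asserted non-increasing across iterations of every run.
Cluster labels are canonicalized by lexicographic order of the center
vectors, so the output is invariant to input row order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .io_core import ValidationError

CLASS_NEW = "newly_expressed"
CLASS_NEW_HIGH = "newly_and_highly"
CLASS_OTHER = "other"


def preprocess_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) then per-row z-standardization; constant rows map to zeros."""
    log = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    mu = log.mean(axis=1, keepdims=True)
    sd = log.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((log - mu) / sd, index=matrix.index,
                        columns=matrix.columns)


def _lloyd(data: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """Plain Lloyd iterations; returns (labels, centers, sse_history)."""
    sse_prev = np.inf
    history = []
    labels = None
    reseeded = False
    for _ in range(max_iter):
        d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        sse = float(d2[np.arange(len(data)), labels].sum())
        if not reseeded:  # reseeding an empty cluster may transiently raise SSE
            assert sse <= sse_prev + 1e-9 * (1.0 + abs(sse)), \
                "k-means SSE increased across a Lloyd iteration"
        history.append(sse)
        new_centers = centers.copy()
        reseeded = False
        for k in range(len(centers)):
            members = data[labels == k]
            if len(members):
                new_centers[k] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                new_centers[k] = data[d2.min(axis=1).argmax()]
                reseeded = True
        if np.allclose(new_centers, centers) and sse == sse_prev:
            break
        if abs(sse_prev - sse) <= 1e-12 * (1.0 + abs(sse)):
            centers = new_centers
            break
        centers = new_centers
        sse_prev = sse
    # final assignment against the final centers
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    sse = float(d2[np.arange(len(data)), labels].sum())
    history.append(sse)
    return labels, centers, history


def kmeans_cluster(matrix: pd.DataFrame, k: int, seed: int = 0,
                   n_starts: int = 10, standardize: bool = True):
    """Cluster gene profiles into ``k`` groups.

    Returns ``(labels, centers, sse)``: ``labels`` is a Series of integer
    cluster ids (0..k-1), ``centers`` a k x n_columns array on the
    standardized scale, ``sse`` the total within-cluster sum of squares of
    the best start.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    work = preprocess_profiles(matrix) if standardize else matrix.astype(float)
    data = work.to_numpy()
    n_distinct = len(np.unique(data, axis=0))
    if k > n_distinct:
        raise ValidationError(f"k={k} exceeds {n_distinct} distinct rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        rs = int(rng.integers(0, 2**31 - 1))
        if k == 1:
            centers0 = data.mean(axis=0, keepdims=True)
        else:
            centers0, _ = kmeans_plusplus(data, n_clusters=k, random_state=rs)
        labels, centers, history = _lloyd(data, centers0)
        if best is None or history[-1] < best[2][-1]:
            best = (labels, centers, history)
    labels, centers, history = best
    # canonical relabeling: lexicographic order of center vectors
    order = np.lexsort(centers.T[::-1])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centers = centers[order]
    return (pd.Series(labels, index=matrix.index, name="cluster"),
            centers, history[-1])


def identify_rising_cluster(centers: np.ndarray, earlier_cols, later_cols,
                            min_rise: float = 1.0):
    """Index of the cluster with the largest later-minus-earlier center rise.

    Returns ``None`` when no cluster rises by at least ``min_rise`` (on the
    standardized scale).  Ties break toward the lowest index.
    """
    earlier_cols = np.asarray(earlier_cols, dtype=int)
    later_cols = np.asarray(later_cols, dtype=int)
    if set(earlier_cols) & set(later_cols):
        raise ValueError("earlier and later column groups must be disjoint")
    rise = centers[:, later_cols].mean(axis=1) - centers[:, earlier_cols].mean(axis=1)
    best = int(rise.argmax())
    if rise[best] < min_rise:
        return None
    return best


def classify_new_expression(earlier: pd.Series, later: pd.Series,
                            labels: pd.Series, rising_cluster: int,
                            low: float = 1.0, high: float = 10.0):
    """Classify genes as newly (and highly) expressed between two stages.

    ``newly_expressed``: raw FPKM strictly below ``low`` at the earlier stage
    and membership in the rising cluster.  ``newly_and_highly`` additionally
    requires later FPKM strictly above ``high``.  Genes missing a stage value
    are ``other`` and flagged.  Returns ``(classes, flagged_missing)``.
    """
    genes = labels.index
    e = earlier.reindex(genes)
    l = later.reindex(genes)
    missing = e.isna() | l.isna()
    in_cluster = labels == rising_cluster
    new = in_cluster & (e < low) & ~missing
    new_high = new & (l > high)
    classes = pd.Series(CLASS_OTHER, index=genes, name="class")
    classes[new] = CLASS_NEW
    classes[new_high] = CLASS_NEW_HIGH
    return classes, list(genes[missing])
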