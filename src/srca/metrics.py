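"""Embedding-quality metrics.

Reconstruction error (MSE), rank-based coranking scores (Q_NX / R_NX curves
and their areas), cophenetic correlation between distance matrices, and the
usual cluster-separation indices computed on the embedded coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr


def mse(X, X_hat) -> float:
    """Mean squared Euclidean reconstruction error."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X_hat = np.atleast_2d(np.asarray(X_hat, dtype=float))
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(np.mean(np.sum((X - X_hat) ** 2, axis=1)))


def _check_distance_matrix(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def rank_matrix(D) -> np.ndarray:
    """Ranks of pairwise distances per row, ties broken by smaller index.

    Entry (i, j), j != i, is the rank (1-based) of j among all points by
    distance from i; a tie between k and j at the same distance counts k
    first when k < j.  The diagonal is 0.
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    ranks = np.zeros((n, n), dtype=int)
    cols = np.arange(n)
    for i in range(n):
        others = cols[cols != i]
        order = others[np.lexsort((others, D[i, others]))]
        ranks[i, order] = np.arange(1, n)
    return ranks


def coranking(D_high, D_low) -> np.ndarray:
    """(n-1) x (n-1) joint histogram of distance ranks in the two spaces.

    Entry (k, l) (1-based ranks) counts ordered pairs (i, j) whose rank is k
    in the original space and l in the reduced space.  With the fixed
    tie-break every row and column sums to n.
    """
    Rh = rank_matrix(D_high)
    Rl = rank_matrix(D_low)
    n = Rh.shape[0]
    if Rl.shape[0] != n:
        raise ValueError("distance matrices must have matching size")
    off = ~np.eye(n, dtype=bool)
    flat = (Rh[off] - 1) * (n - 1) + (Rl[off] - 1)
    Q = np.bincount(flat, minlength=(n - 1) ** 2).reshape(n - 1, n - 1)
    return Q


def rnx_scores(Q: np.ndarray):
    """Neighborhood-preservation curves and their areas from a coranking
    matrix.

    Returns ``(q_nx, r_nx, auc, wauc)`` where for K = 1..n-2::

        Q_NX(K) = (1 / (K n)) * sum_{k<=K, l<=K} Q_kl
        R_NX(K) = ((n-1) Q_NX(K) - K) / (n-1-K)

    ``auc`` is the flat mean of R_NX over K and ``wauc`` the 1/K-weighted
    mean (emphasizing small neighborhoods, log-scale flavor).
    """
    Q = np.asarray(Q)
    n = Q.shape[0] + 1
    if n < 4:
        raise ValueError("need at least 4 samples for R_NX scores")
    cum = Q.cumsum(axis=0).cumsum(axis=1)
    K = np.arange(1, n - 1)
    q_nx = np.diag(cum)[: n - 2] / (K * n)
    r_nx = ((n - 1) * q_nx - K) / (n - 1 - K)
    auc = float(r_nx.mean())
    w = 1.0 / K
    wauc = float((r_nx * w).sum() / w.sum())
    return q_nx, r_nx, auc, wauc


def cophenetic_correlation(D_high, D_low) -> float:
    """Pearson correlation between the upper triangles of two distance
    matrices."""
    Dh = _check_distance_matrix(D_high)
    Dl = _check_distance_matrix(D_low)
    if Dh.shape != Dl.shape:
        raise ValueError("distance matrices must have matching shape")
    a = squareform(Dh, checks=False)
    b = squareform(Dl, checks=False)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a distance matrix")
    return float(pearsonr(a, b).statistic)


def cluster_scores(Y, labels):
    """Silhouette, Calinski-Harabasz and Davies-Bouldin scores of an
    embedding.

    ``Y`` is treated as Euclidean coordinates (for spherical embeddings,
    pass the angle representation; the 2-pi wrap-around is ignored).
    Coincident clusters make Davies-Bouldin diverge; that case is reported
    as ``inf``.
    """
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    sc = float(silhouette_score(Y, labels))
    chi = float(calinski_harabasz_score(Y, labels))
    with np.errstate(divide="ignore", invalid="ignore"):
        dbi = float(davies_bouldin_score(Y, labels))
    if not np.isfinite(dbi):
        dbi = float("inf")
    elif dbi == 0.0:
        # sklearn reports 0 when every centroid distance is ~0; if clusters
        # still have scatter the ratio actually diverges
        cents = np.array([Y[labels == u].mean(axis=0)
                          for u in np.unique(labels)])
        scatter = sum(float(((Y[labels == u] - c) ** 2).sum())
                      for u, c in zip(np.unique(labels), cents))
        if scatter > 0:
            dbi = float("inf")
    return sc, chi, dbi


def circular_correlation(alpha, beta) -> float:
    """Fisher-Lee circular correlation between two angle samples."""
    a = np.asarray(alpha, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("angle vectors must have equal length")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    num = np.sum(da * db)
    den = np.sqrt(np.sum(da ** 2) * np.sum(db ** 2))
    if den == 0:
        raise ValueError("degenerate angle sample")
    return float(num / den)


def circular_rank_correlation(alpha, beta) -> float:
    """Circular correlation of the uniform-rank transforms of two angle
    samples; invariant to monotone circular reparameterizations."""
    from scipy.stats import rankdata

    a = np.asarray(alpha, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    n = a.size
    ra = 2.0 * np.pi * rankdata(a, method="average") / n
    rb = 2.0 * np.pi * rankdata(b, method="average") / n
    return circular_correlation(ra, rb)


def score_report(X=None, X_hat=None, D_high=None, D_low=None, Y=None,
                 labels=None, which=("mse",)) -> dict:
    """Assemble the requested metrics into a flat dict."""
    out = {}
    if "mse" in which:
        out["mse"] = mse(X, X_hat)
    if "coranking" in which:
        Q = coranking(D_high, D_low)
        _, _, auc, wauc = rnx_scores(Q)
        out["cc"] = cophenetic_correlation(D_high, D_low)
        out["auc"] = auc
        out["wauc"] = wauc
    if "cluster" in which:
        sc, chi, dbi = cluster_scores(Y, labels)
        out.update(sc=sc, chi=chi, dbi=dbi)
    return out
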