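"""Linear and two-step spherical baselines.

``pca_reduce`` reconstructs data from its top principal plane.  ``spca_fit``
is the classical two-step spherical method: fit a (d'+1)-dimensional PCA
subspace first, then an algebraic least-squares sphere inside it, and
reconstruct by radial projection.  Both serve as reference points for the
one-step geometric fit, which is guaranteed to match or beat their
reconstruction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PlaneModel:
    """Affine d'-plane: mean plus an orthonormal basis of the subspace."""

    mean: np.ndarray
    basis: np.ndarray  # d x d', orthonormal columns


@dataclass
class SpcaModel:
    """Sphere of intrinsic dimension d' inside a (d'+1)-dim PCA subspace."""

    mean: np.ndarray          # d-vector
    basis: np.ndarray         # d x (d'+1), orthonormal columns
    center: np.ndarray        # (d'+1)-vector, subspace coordinates
    radius: float


def _principal_axes(X: np.ndarray, k: int):
    """Top-k unit eigenvectors of the sample covariance (descending)."""
    C = np.atleast_2d(np.cov(X, rowvar=False))
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return evecs[:, order[:k]], evals[order]


def pca_reduce(X, dprime: int):
    """Project onto the top-d' principal plane and reconstruct.

    Returns ``(PlaneModel, X_hat, mse)`` with
    ``x_hat = mean + V V' (x - mean)``; the mse equals the sum of the
    discarded covariance eigenvalues (up to the n vs n-1 normalization).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if not 1 <= dprime < d:
        raise ValueError(f"retained dimension must be in [1, {d - 1}]")
    mean = X.mean(axis=0)
    V, _ = _principal_axes(X, dprime)
    scores = (X - mean) @ V
    X_hat = mean + scores @ V.T
    mse = float(np.mean(np.sum((X - X_hat) ** 2, axis=1)))
    return PlaneModel(mean=mean, basis=V), X_hat, mse


def algebraic_sphere_fit(Y):
    """Closed-form least-squares sphere through points in R^m.

    Minimizes sum_i (||y_i - c||^2 - r^2)^2 via the linear parameterization
    ||y_i||^2 = 2 y_i' c + (r^2 - ||c||^2); exact on points lying on a
    sphere.  A rank-deficient system (collinear points) yields the
    minimum-norm solution with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, m = Y.shape
    if n < m + 1:
        raise ValueError(f"need at least {m + 1} points to fit a sphere in R^{m}")
    if np.allclose(Y, Y[0]):
        raise ValueError("all points coincide; sphere is undefined")
    A = np.column_stack([2.0 * Y, np.ones(n)])
    b = np.sum(Y ** 2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < m + 1:
        warnings.warn("rank-deficient sphere fit; returning minimum-norm solution")
    c = sol[:m]
    r_sq = sol[m] + c @ c
    if r_sq <= 0:
        raise ValueError("degenerate sphere fit: non-positive squared radius")
    return c, float(np.sqrt(r_sq))


def spca_fit(X, dprime: int):
    """Two-step spherical PCA: PCA subspace of dimension d'+1, then an
    algebraic sphere fit in subspace coordinates.

    Returns ``(SpcaModel, X_hat, mse)`` where the reconstruction radially
    projects each point's subspace coordinates onto the fitted sphere and
    maps back to the ambient space.  Subspace-degenerate points (exactly at
    the center) are sent deterministically along the first basis axis.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    k = dprime + 1
    if not 1 <= dprime <= d - 1:
        raise ValueError(f"retained dimension must be in [1, {d - 1}]")
    if n < k + 1:
        raise ValueError("not enough samples for the sphere fit")
    mean = X.mean(axis=0)
    V, _ = _principal_axes(X, k)
    Y = (X - mean) @ V                      # n x (d'+1) subspace coordinates
    c, r = algebraic_sphere_fit(Y)
    D = Y - c
    norms = np.linalg.norm(D, axis=1)
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    Y_hat = c + r * D / safe[:, None]
    if degenerate.any():
        fb = c.copy()
        fb[0] += r
        Y_hat[degenerate] = fb
    X_hat = mean + Y_hat @ V.T
    mse = float(np.mean(np.sum((X - X_hat) ** 2, axis=1)))
    return SpcaModel(mean=mean, basis=V, center=c, radius=r), X_hat, mse
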