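"""Data-driven orthogonal rotations used before sphere fitting.

The rotate step brings the data to a standard position so the fitted sphere
can be assumed to live in a coordinate subspace.  PCA is the default; the
orthomax family (varimax, quartimax, equamax, parsimax) and FastICA are
alternatives for data with non-Gaussian structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import check_orthogonal

ROTATION_METHODS = (
    "pca", "varimax", "quartimax", "equamax", "parsimax", "orthomax",
    "ica", "identity",
)

#: fixed-point ICA settings (log-cosh contrast)
ICA_MAX_ITER = 500
ICA_TOL = 1e-6
ORTHOMAX_MAX_ITER = 1000
ORTHOMAX_TOL = 1e-10


@dataclass
class RotationSpec:
    """Which rotation to compute and with what knobs.

    ``n_components_rotated`` limits the factor rotations (orthomax family,
    ICA) to the leading principal block; the complement keeps its PCA axes.
    """

    method: str = "pca"
    orthomax_gamma: float = 1.0
    n_components_rotated: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.method not in ROTATION_METHODS:
            raise ValueError(f"unknown rotation method {self.method!r}")
        if self.orthomax_gamma < 0:
            raise ValueError("orthomax_gamma must be >= 0")


def _fix_column_signs(R: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    signs = np.sign(R[np.argmax(np.abs(R), axis=0), np.arange(R.shape[1])])
    signs[signs == 0] = 1.0
    return R * signs


def pca_rotation(X: np.ndarray) -> np.ndarray:
    """Eigenvectors of the sample covariance, ordered by descending variance.

    Columns are unit eigenvectors; ties in eigenvalues keep the original
    eigen-solver order, and each column's largest-magnitude entry is positive.
    Constant data (zero covariance) returns the identity with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples for a PCA rotation")
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    if np.allclose(C, 0.0):
        warnings.warn("constant data: PCA rotation falls back to identity")
        return np.eye(d)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    R = _fix_column_signs(evecs[:, order])
    check_orthogonal(R, 1e-8)
    return R


def orthomax_criterion(L: np.ndarray, gamma: float) -> float:
    """Orthomax objective: sum(L^4) - (gamma/d) * sum_k (sum_j L_jk^2)^2."""
    d = L.shape[0]
    return float(np.sum(L ** 4) - (gamma / d) * np.sum(np.sum(L ** 2, axis=0) ** 2))


def gamma_for(method: str, m: int, d: int, user_gamma: float = 1.0) -> float:
    """Criterion weight for each member of the orthomax family."""
    return {
        "quartimax": 0.0,
        "varimax": 1.0,
        "equamax": m / 2.0,
        "parsimax": d * (m - 1.0) / (d + m - 2.0) if d + m > 2 else 0.0,
        "orthomax": user_gamma,
    }[method]


def _orthomax_rotate(L: np.ndarray, gamma: float):
    """Kaiser-style SVD iteration maximizing the orthomax criterion.

    Returns the m x m orthogonal rotation T (loadings rotate as L T).
    """
    d, m = L.shape
    T = np.eye(m)
    crit = orthomax_criterion(L, gamma)
    for _ in range(ORTHOMAX_MAX_ITER):
        LT = L @ T
        G = L.T @ (LT ** 3 - (gamma / d) * LT * np.sum(LT ** 2, axis=0))
        U, _, Vt = np.linalg.svd(G)
        T_new = U @ Vt
        new_crit = orthomax_criterion(L @ T_new, gamma)
        if new_crit < crit - 1e-12:
            break  # keep the best iterate
        done = new_crit - crit < ORTHOMAX_TOL * max(1.0, abs(crit))
        T, crit = T_new, new_crit
        if done:
            return T, crit, True
    else:
        warnings.warn("orthomax rotation did not converge; best iterate returned")
    return T, crit, False


def orthomax_rotation(X: np.ndarray, spec: RotationSpec) -> np.ndarray:
    """Rotate the leading principal block by an orthomax-family criterion.

    The top-m PCA loadings (m = ``spec.n_components_rotated``) are rotated to
    maximize the orthomax objective; the trailing principal axes are kept as
    is, so the result is a full d x d orthogonal matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    m = spec.n_components_rotated or d
    if m > d:
        raise ValueError(f"cannot rotate {m} components in dimension {d}")
    R_pca = pca_rotation(X)
    if m == 1:
        return R_pca
    gamma = gamma_for(spec.method if spec.method != "pca" else "orthomax",
                      m, d, spec.orthomax_gamma)
    L = R_pca[:, :m]
    T, _, _ = _orthomax_rotate(L, gamma)
    R = R_pca.copy()
    R[:, :m] = _fix_column_signs(L @ T)
    check_orthogonal(R, 1e-8)
    return R


def ica_rotation(X: np.ndarray, spec: RotationSpec) -> np.ndarray:
    """Orthogonal rotation aligned with FastICA's independent axes.

    The data are whitened and unmixed by a fixed-point iteration with the
    log-cosh contrast; the resulting mixing directions are orthonormalized by
    polar decomposition so the output is a valid rotation.  Deterministic for
    a fixed ``spec.seed``; falls back to the PCA rotation on non-convergence.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    m = spec.n_components_rotated or d
    if m > d:
        raise ValueError(f"cannot extract {m} components in dimension {d}")
    ica = FastICA(n_components=m, fun="logcosh", max_iter=ICA_MAX_ITER,
                  tol=ICA_TOL, whiten="unit-variance",
                  random_state=spec.seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            ica.fit(X)
    except ConvergenceWarning:
        warnings.warn("FastICA did not converge; falling back to PCA rotation")
        return pca_rotation(X)
    A = ica.mixing_  # d x m, columns span the independent directions
    # polar orthonormalization of the mixing block
    U, _, Vt = np.linalg.svd(A, full_matrices=False)
    block = U @ Vt
    if m == d:
        R = block
    else:
        # complete with the orthogonal complement from PCA
        R_pca = pca_rotation(X)
        Q_rest = R_pca[:, m:]
        # re-orthogonalize the complement against the ICA block
        proj = Q_rest - block @ (block.T @ Q_rest)
        Q_rest, _ = np.linalg.qr(proj)
        R = np.column_stack([block, Q_rest])
    R = _fix_column_signs(R)
    check_orthogonal(R, 1e-8)
    return R


def compute_rotation(X: np.ndarray, spec: RotationSpec | str | None = None) -> np.ndarray:
    """Dispatch to the requested rotation method; returns a d x d rotation."""
    if spec is None:
        spec = RotationSpec()
    if isinstance(spec, str):
        spec = RotationSpec(method=spec)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    if spec.method == "identity":
        return np.eye(d)
    if spec.method == "pca":
        return pca_rotation(X)
    if spec.method == "ica":
        return ica_rotation(X, spec)
    return orthomax_rotation(X, spec)
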