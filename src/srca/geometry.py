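"""Point-to-sphere geometry: distances, losses, projections, angle coordinates.

A fitted sphere lives in a coordinate subspace of the (rotated) data frame:
given an index set ``I`` of size d'+1, a center ``c`` and a radius ``r``, the
sphere is ``{z : ||z_I - c_I|| = r, z_j = c_j for j not in I}``.  The squared
distance from a point to that set decomposes into an off-subspace part and an
in-subspace radial part; an optional symmetric positive-semidefinite weight
matrix ``W`` turns the Euclidean distance into a Mahalanobis-type one.

Index sets are 0-based throughout the Python API; 1-based indices appear only
in serialized files and logs.
"""

from __future__ import annotations

import numpy as np

#: tolerance for orthogonality checks R^T R = I
ORTHOGONALITY_TOL = 1e-8
#: tolerance for weight-matrix symmetry
SYMMETRY_TOL = 1e-10
#: smallest admissible eigenvalue of a weight matrix
PSD_TOL = -1e-10
#: unit-norm tolerance for angle conversion
UNIT_NORM_TOL = 1e-8


def validate_index_set(index_set, d: int) -> np.ndarray:
    """Return a sorted, duplicate-free 0-based integer index array.

    Raises ``ValueError`` when empty, out of range or containing duplicates.
    """
    idx = np.asarray(index_set, dtype=int).ravel()
    if idx.size == 0:
        raise ValueError("index set must be non-empty")
    if np.unique(idx).size != idx.size:
        raise ValueError("index set contains duplicates")
    if idx.min() < 0 or idx.max() >= d:
        raise ValueError(f"index set out of range for dimension d={d}")
    return np.sort(idx)


def validate_weight(W, d: int) -> np.ndarray:
    """Validate a d x d symmetric PSD weight matrix; ``None`` means identity."""
    if W is None:
        return np.eye(d)
    W = np.asarray(W, dtype=float)
    if W.shape != (d, d):
        raise ValueError(f"weight matrix must be {d}x{d}, got {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix contains non-finite entries")
    if np.max(np.abs(W - W.T)) > SYMMETRY_TOL:
        raise ValueError("weight matrix is not symmetric")
    if np.linalg.eigvalsh(W).min() < PSD_TOL:
        raise ValueError("weight matrix is not positive semidefinite")
    return W


def check_orthogonal(R: np.ndarray, tol: float = ORTHOGONALITY_TOL) -> None:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("rotation must be a square matrix")
    if np.max(np.abs(R.T @ R - np.eye(R.shape[0]))) > tol:
        raise ValueError("matrix is not orthogonal within tolerance")


def _weighted_terms(X: np.ndarray, c: np.ndarray, index_set: np.ndarray,
                    W: np.ndarray | None):
    """Per-row quadratic form (x-c)'W(x-c) and radical (x-c)'W'I_W (x-c)."""
    D = X - c
    if W is None:
        quad = np.einsum("ij,ij->i", D, D)
        radical_sq = np.einsum("ij,ij->i", D[:, index_set], D[:, index_set])
    else:
        WD = D @ W.T  # rows are W (x_i - c) since W symmetric
        quad = np.einsum("ij,ij->i", D, WD)
        radical_sq = np.einsum("ij,ij->i", WD[:, index_set], WD[:, index_set])
    return quad, np.maximum(radical_sq, 0.0)


def sqdist_to_sphere(X, c, r: float, index_set, W=None) -> np.ndarray:
    """Vector of squared (weighted) point-to-sphere distances, one per row of X.

    For each row x the value is
    ``(x-c)'W(x-c) + r^2 - 2 r sqrt((x-c)'W' I_I W (x-c))``,
    which for ``W = I`` equals the squared Euclidean distance from x to the
    sphere embedded in the coordinate subspace selected by ``index_set``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    d = c.size
    if X.shape[1] != d:
        raise ValueError(f"point dimension {X.shape[1]} != center dimension {d}")
    if r <= 0:
        raise ValueError("radius must be positive")
    idx = validate_index_set(index_set, d)
    if W is None:
        # stable decomposition: off-subspace part plus in-subspace radial part
        # (the expanded radical form cancels catastrophically at large radius)
        D = X - c
        in_norm = np.linalg.norm(D[:, idx], axis=1)
        comp = np.setdiff1d(np.arange(d), idx)
        off = np.einsum("ij,ij->i", D[:, comp], D[:, comp])
        return off + (in_norm - r) ** 2
    W = validate_weight(W, d)
    quad, radical_sq = _weighted_terms(X, c, idx, W)
    vals = quad + r * r - 2.0 * r * np.sqrt(radical_sq)
    # exact arithmetic gives >= 0; clip roundoff on points near the sphere
    return np.maximum(vals, 0.0)


def point_to_sphere_sqdist(x, c, r: float, index_set, W=None) -> float:
    """Squared (weighted) distance from a single point to the sub-sphere."""
    return float(sqdist_to_sphere(np.atleast_2d(x), c, r, index_set, W)[0])


def geometric_loss(X, c, r: float, index_set, W=None) -> float:
    """Sum of squared point-to-sphere distances over the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty data matrix")
    return float(sqdist_to_sphere(X, c, r, index_set, W).sum())


def project_to_sphere(Z, c, r: float, index_set):
    """Project rows of Z (rotated frame) onto the sub-sphere, W = I.

    Returns ``(Z_hat, degenerate)`` where ``Z_hat[i]`` is the closest sphere
    point to ``Z[i]`` and ``degenerate`` flags rows whose in-subspace part
    coincides with the center (those are sent to ``c + r e_min(I)``).

    In-subspace coordinates move radially onto the sphere; coordinates outside
    the index set are set to the matching center coordinate, so the projection
    attains the point-to-sphere distance.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    d = c.size
    if r <= 0:
        raise ValueError("radius must be positive")
    idx = validate_index_set(index_set, d)
    D = Z[:, idx] - c[idx]
    norms = np.linalg.norm(D, axis=1)
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    out = np.tile(c, (Z.shape[0], 1))
    out[:, idx] = c[idx] + r * D / safe[:, None]
    if degenerate.any():
        fallback = c.copy()
        fallback[idx[0]] += r
        out[degenerate] = fallback
    return out, degenerate


def to_hyperspherical(unit_coords: np.ndarray) -> np.ndarray:
    """Angles of unit vectors in R^(d'+1); returns an n x d' matrix (radians).

    d' = 1: the single angle is atan2(y, x) in (-pi, pi].
    d' = 2: columns are (longitude, latitude) with longitude = atan2(y, x)
        and latitude = arcsin(z); at the poles longitude is 0.
    d' >= 3: standard hyperspherical recursion; the first d'-1 angles lie in
        [0, pi] and the last in (-pi, pi].
    """
    U = np.atleast_2d(np.asarray(unit_coords, dtype=float))
    norms = np.linalg.norm(U, axis=1)
    if np.max(np.abs(norms - 1.0)) > UNIT_NORM_TOL:
        raise ValueError("rows must have unit norm")
    m = U.shape[1]
    if m < 2:
        raise ValueError("need at least 2 embedded coordinates")
    if m == 2:
        return np.arctan2(U[:, 1], U[:, 0])[:, None]
    if m == 3:
        lon = np.arctan2(U[:, 1], U[:, 0])
        lat = np.arcsin(np.clip(U[:, 2], -1.0, 1.0))
        return np.column_stack([lon, lat])
    angles = np.empty((U.shape[0], m - 1))
    for k in range(m - 2):
        tail = np.linalg.norm(U[:, k:], axis=1)
        with np.errstate(invalid="ignore"):
            ratio = np.where(tail > 0, U[:, k] / np.where(tail > 0, tail, 1.0), 1.0)
        angles[:, k] = np.arccos(np.clip(ratio, -1.0, 1.0))
    angles[:, -1] = np.arctan2(U[:, -1], U[:, -2])
    return angles


def from_hyperspherical(angles: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_hyperspherical`; returns unit vectors."""
    A = np.atleast_2d(np.asarray(angles, dtype=float))
    dprime = A.shape[1]
    n = A.shape[0]
    if dprime == 1:
        return np.column_stack([np.cos(A[:, 0]), np.sin(A[:, 0])])
    if dprime == 2:
        lon, lat = A[:, 0], A[:, 1]
        return np.column_stack([
            np.cos(lat) * np.cos(lon),
            np.cos(lat) * np.sin(lon),
            np.sin(lat),
        ])
    U = np.empty((n, dprime + 1))
    sin_prod = np.ones(n)
    for k in range(dprime - 1):
        U[:, k] = sin_prod * np.cos(A[:, k])
        sin_prod = sin_prod * np.sin(A[:, k])
    U[:, dprime - 1] = sin_prod * np.cos(A[:, -1])
    U[:, dprime] = sin_prod * np.sin(A[:, -1])
    return U


def reconstruct_original_frame(Z_hat, R, mean) -> np.ndarray:
    """Map rotated-frame rows back to the original frame: ``Z_hat R' + mean``."""
    R = np.asarray(R, dtype=float)
    check_orthogonal(R)
    Z_hat = np.atleast_2d(np.asarray(Z_hat, dtype=float))
    mean = np.asarray(mean, dtype=float).ravel()
    return Z_hat @ R.T + mean


def rotate_to_standard(X, R, mean) -> np.ndarray:
    """Forward map ``(X - mean) R`` of the rotate step."""
    R = np.asarray(R, dtype=float)
    check_orthogonal(R)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float).ravel()
    return (X - mean) @ R
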