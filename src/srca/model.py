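"""Model / Results objects for the rotate-optimize-project pipeline.

:class:`SphericalRotationAnalysis` is constructed from a data matrix and a
retained dimension; :meth:`~SphericalRotationAnalysis.fit` rotates the data
to a standard position, searches for the best coordinate subset with its
sphere parameters, projects every point onto the fitted sphere and maps it
back, returning a :class:`SRCAResults` carrying the fitted sphere, the
embedding (angles, reconstructions, per-point squared distances) and the
reconstruction error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .geometry import (
    from_hyperspherical,
    project_to_sphere,
    reconstruct_original_frame,
    rotate_to_standard,
    sqdist_to_sphere,
    to_hyperspherical,
    validate_weight,
)
from .optimize import FitOptions, SearchResult, fit_fixed_subset, search_subsets
from .rotations import RotationSpec, compute_rotation

logger = logging.getLogger("srca")


@dataclass
class SphereModel:
    """A fitted sub-sphere: rotation, mean, index set, center, radius, weight.

    ``rotation`` and ``mean`` define the standard position
    ``Z = (X - mean) rotation``; the sphere lives in the rotated frame on the
    coordinates of ``index_set`` (0-based here; serialized 1-based).
    """

    rotation: np.ndarray
    mean: np.ndarray
    index_set: np.ndarray
    center: np.ndarray
    radius: float
    weight: np.ndarray | None = None
    retained_dim: int = 0
    seed: int = 0

    def __post_init__(self):
        geometry.check_orthogonal(self.rotation)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        d = self.mean.size
        self.index_set = geometry.validate_index_set(self.index_set, d)
        if self.retained_dim == 0:
            self.retained_dim = self.index_set.size - 1

    @property
    def center_original_frame(self) -> np.ndarray:
        """The sphere center mapped back to the original data frame."""
        return self.center @ self.rotation.T + self.mean


@dataclass
class EmbeddingResult:
    """Per-point output of the projection step."""

    reconstructed: np.ndarray      # n x d, original frame
    unit_coords: np.ndarray        # n x (d'+1), rows on the unit sphere
    angles: np.ndarray             # n x d' hyperspherical angles (radians)
    per_point_sqdist: np.ndarray   # n-vector
    total_loss: float
    degenerate: np.ndarray = field(default=None)  # boolean flags

    @property
    def mse(self) -> float:
        return float(self.per_point_sqdist.mean())


def embed_on_sphere(Z: np.ndarray, model: SphereModel) -> EmbeddingResult:
    """Project rotated-frame points onto the model sphere and compute the
    embedding (unit coordinates, angles, reconstructions, distances)."""
    idx = model.index_set
    Z_hat, degenerate = project_to_sphere(Z, model.center, model.radius, idx)
    unit = (Z_hat[:, idx] - model.center[idx]) / model.radius
    angles = to_hyperspherical(unit)
    sq = sqdist_to_sphere(Z, model.center, model.radius, idx, model.weight)
    recon = reconstruct_original_frame(Z_hat, model.rotation, model.mean)
    return EmbeddingResult(
        reconstructed=recon,
        unit_coords=unit,
        angles=angles,
        per_point_sqdist=sq,
        total_loss=float(sq.sum()),
        degenerate=degenerate,
    )


class SphericalRotationAnalysis:
    """Sphere-based dimension reduction of a numeric data matrix.

    Parameters
    ----------
    data : array-like or DataFrame, shape (n, d)
        Observations; rows are samples.
    retained_dim : int
        Intrinsic dimension d' of the reduced representation (a circle is
        d' = 1 although it is embedded in two coordinates).
    rotation : str or RotationSpec, default "pca"
        How to rotate the data to a standard position before fitting.
    weight : array-like, optional
        Symmetric PSD d x d weight turning the loss into a Mahalanobis-type
        one; identity when omitted.
    standardize : bool, default False
        Z-score each column before fitting (recommended for mixed-unit
        features).
    """

    def __init__(self, data, retained_dim: int, rotation="pca", weight=None,
                 standardize: bool = False):
        if isinstance(data, pd.DataFrame):
            self.feature_names = list(data.columns)
            self.row_labels = [str(i) for i in data.index]
            X = data.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(data, dtype=float))
            self.feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
            self.row_labels = None
        if not np.all(np.isfinite(X)):
            raise ValueError("data contains non-finite entries")
        n, d = X.shape
        if d < 2:
            raise ValueError("need at least 2 features")
        if not 1 <= retained_dim <= d - 1:
            raise ValueError(f"retained_dim must be in [1, {d - 1}]")
        self.standardize = bool(standardize)
        self._scale = None
        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            X = (X - mu) / sd
            self._scale = (mu, sd)
        self.data = X
        self.retained_dim = int(retained_dim)
        self.rotation_spec = (rotation if isinstance(rotation, RotationSpec)
                              else RotationSpec(method=rotation))
        self.weight = validate_weight(weight, d) if weight is not None else None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, retained_dim: int, **kwargs):
        return cls(df, retained_dim, **kwargs)

    def fit(self, search: str = "auto", options: FitOptions | None = None,
            index_set=None) -> "SRCAResults":
        """Run rotate-optimize-project and return a results object.

        ``index_set`` (0-based rotated-frame coordinates) skips the subset
        search and fits that subset directly.
        """
        opts = options or FitOptions()
        if search != opts.search:
            opts.search = search
        X = self.data
        spec = self.rotation_spec
        if spec.n_components_rotated is None and spec.method not in ("pca", "identity"):
            spec = RotationSpec(method=spec.method,
                                orthomax_gamma=spec.orthomax_gamma,
                                n_components_rotated=self.retained_dim + 1,
                                seed=spec.seed)
        mean = X.mean(axis=0)
        R = compute_rotation(X, spec)
        Z = rotate_to_standard(X, R, mean)
        if index_set is not None:
            idx = geometry.validate_index_set(index_set, X.shape[1])
            c, r, loss, trace, conv = fit_fixed_subset(Z, idx, self.weight, opts)
            result = SearchResult(idx, c, r, loss, 1, conv, trace)
        else:
            result = search_subsets(Z, self.retained_dim, self.weight, opts)
        model = SphereModel(rotation=R, mean=mean, index_set=result.index_set,
                            center=result.center, radius=result.radius,
                            weight=self.weight, retained_dim=self.retained_dim,
                            seed=opts.seed)
        embedding = embed_on_sphere(Z, model)
        logger.info("fit complete: loss %.6e, mse %.6e, index set %s",
                    embedding.total_loss, embedding.mse,
                    (model.index_set + 1).tolist())
        return SRCAResults(self, model, embedding, result)


class SRCAResults:
    """Fitted sphere, embedding and diagnostics of a single fit."""

    def __init__(self, model_obj: SphericalRotationAnalysis, sphere: SphereModel,
                 embedding: EmbeddingResult, search: SearchResult):
        self.model = model_obj
        self.sphere = sphere
        self.embedding = embedding
        self.search = search

    # -- headline quantities -------------------------------------------------
    @property
    def loss(self) -> float:
        return self.embedding.total_loss

    @property
    def mse(self) -> float:
        return self.embedding.mse

    @property
    def radius(self) -> float:
        return self.sphere.radius

    @property
    def center(self) -> np.ndarray:
        return self.sphere.center

    @property
    def index_set(self) -> np.ndarray:
        return self.sphere.index_set

    @property
    def angles(self) -> np.ndarray:
        return self.embedding.angles

    def transform(self, X_new) -> EmbeddingResult:
        """Embed new observations with the stored rotation and sphere."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.sphere.mean.size:
            raise ValueError(
                f"expected {self.sphere.mean.size} columns, got {X_new.shape[1]}")
        if self.model._scale is not None:
            mu, sd = self.model._scale
            X_new = (X_new - mu) / sd
        Z = rotate_to_standard(X_new, self.sphere.rotation, self.sphere.mean)
        return embed_on_sphere(Z, self.sphere)

    def angles_frame(self) -> pd.DataFrame:
        cols = [f"angle_{k + 1}" for k in range(self.embedding.angles.shape[1])]
        idx = self.model.row_labels
        return pd.DataFrame(self.embedding.angles, columns=cols, index=idx)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        s = self.sphere
        lines = [
            "Spherical Rotation Component Analysis",
            "=" * 54,
            f"n samples            {self.model.data.shape[0]:>10}",
            f"ambient dim d        {self.model.data.shape[1]:>10}",
            f"retained dim d'      {s.retained_dim:>10}",
            f"rotation             {self.model.rotation_spec.method:>10}",
            f"index set (1-based)  {str((s.index_set + 1).tolist()):>10}",
            f"radius               {s.radius:>10.6g}",
            f"total loss           {self.loss:>10.6g}",
            f"reconstruction MSE   {self.mse:>10.6g}",
            f"subsets evaluated    {self.search.n_subsets_evaluated:>10}",
            f"converged            {str(self.search.converged):>10}",
            "=" * 54,
            "center (in-subset coordinates, rotated frame):",
            "  " + np.array2string(s.center[s.index_set], precision=6),
        ]
        return "\n".join(lines)

    def plot_angles(self, labels=None, ax=None):
        """Scatter the first two embedding angles, colored by label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        A = self.embedding.angles
        y = A[:, 1] if A.shape[1] > 1 else np.zeros(len(A))
        if labels is None:
            ax.scatter(A[:, 0], y, s=8)
        else:
            labels = np.asarray(labels)
            for lab in pd.unique(labels):
                m = labels == lab
                ax.scatter(A[m, 0], y[m], s=8, label=str(lab))
            ax.legend()
        ax.set_xlabel("angle 1 (rad)")
        ax.set_ylabel("angle 2 (rad)" if A.shape[1] > 1 else "")
        return ax

    def save(self, path) -> None:
        from .io import save_model
        save_model(self.sphere, path)


def srca_fit(X, retained_dim: int, rotation="pca", weight=None,
             options: FitOptions | None = None, standardize: bool = False,
             index_set=None) -> SRCAResults:
    """Functional one-call interface to the full pipeline."""
    mod = SphericalRotationAnalysis(X, retained_dim, rotation=rotation,
                                    weight=weight, standardize=standardize)
    opts = options or FitOptions()
    return mod.fit(search=opts.search, options=opts, index_set=index_set)


def srca_transform(X_new, sphere: SphereModel) -> EmbeddingResult:
    """Embed new data with a previously fitted sphere (no refitting)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != sphere.mean.size:
        raise ValueError(
            f"expected {sphere.mean.size} columns, got {X_new.shape[1]}")
    Z = rotate_to_standard(X_new, sphere.rotation, sphere.mean)
    return embed_on_sphere(Z, sphere)
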