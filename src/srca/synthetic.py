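"""Seeded generators of datasets with known geometric ground truth.

Each generator is a pure function of its parameters and seed, producing a
data matrix together with the planted truth (sphere parameters, plane basis,
phase labels) so parameter-recovery and dominance properties can be tested
without external data.  The cell-cycle-like generator emulates the cyclic
phase structure of proliferating cells: contiguous phase arcs on a planted
circle in a high-dimensional feature space, with phase-dependent dispersion
(G1 the most dispersed, S the least).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SphereModel

PHASES = ("G1", "S", "G2", "M")
#: default phase occupancy fractions around the cycle
DEFAULT_PHASE_FRACTIONS = (0.35, 0.25, 0.25, 0.15)
#: default per-phase isotropic noise sd; ordering Var(G1) > Var(G2) ~ Var(M) > Var(S)
DEFAULT_PHASE_DISPERSIONS = (1.0, 0.3, 0.6, 0.6)


@dataclass
class SyntheticDataset:
    """Generated data plus its ground truth."""

    X: np.ndarray
    truth: SphereModel | None = None
    labels: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    generator: str = ""
    params: dict = field(default_factory=dict)


def _random_orthogonal(d: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-distributed rotation via QR with sign correction."""
    A = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def sample_subsphere(n: int, d: int, index_set, center, radius: float,
                     noise_sd: float = 0.0, rotation: np.ndarray | None = None,
                     shift: np.ndarray | None = None, seed: int = 0,
                     heavy_tailed: bool = False, t_dof: float = 3.0) -> SyntheticDataset:
    """Uniform points on a planted sub-sphere plus isotropic noise.

    The sphere occupies the coordinates of ``index_set`` (0-based) with the
    given center and radius; the complement coordinates sit at the center.
    An optional orthogonal ``rotation`` and ``shift`` move the whole
    configuration out of standard position (the recorded truth composes
    them).  ``heavy_tailed`` swaps Gaussian noise for Student-t.
    """
    idx = np.sort(np.asarray(index_set, dtype=int))
    if idx.size < 2:
        raise ValueError("planted sphere needs at least 2 coordinates")
    if radius <= 0 or noise_sd < 0:
        raise ValueError("radius must be > 0 and noise_sd >= 0")
    c = np.asarray(center, dtype=float).ravel()
    if c.size != d or idx.max() >= d:
        raise ValueError("center/index set inconsistent with dimension d")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, idx.size))
    U = G / np.linalg.norm(G, axis=1, keepdims=True)
    Z = np.tile(c, (n, 1))
    Z[:, idx] = c[idx] + radius * U
    if noise_sd > 0:
        if heavy_tailed:
            eps = rng.standard_t(t_dof, size=(n, d))
            eps *= noise_sd / np.sqrt(t_dof / (t_dof - 2.0))
        else:
            eps = noise_sd * rng.standard_normal((n, d))
        X = Z + eps
    else:
        X = Z
    R = rotation if rotation is not None else np.eye(d)
    b = shift if shift is not None else np.zeros(d)
    X = X @ R.T + b
    truth = SphereModel(rotation=R, mean=np.asarray(b, dtype=float),
                        index_set=idx, center=c, radius=float(radius),
                        retained_dim=idx.size - 1, seed=seed)
    return SyntheticDataset(X=X, truth=truth, noise_sd=noise_sd, seed=seed,
                            generator="subsphere",
                            params=dict(n=n, d=d, radius=radius))


def sample_torus(n: int, R_major: float, r_minor: float, d: int,
                 noise_sd: float = 0.0, seed: int = 0) -> SyntheticDataset:
    """Standard torus in the first three coordinates, labels by major-angle
    quartile."""
    if not R_major > r_minor > 0:
        raise ValueError("need R_major > r_minor > 0")
    if d < 3:
        raise ValueError("torus embedding needs d >= 3")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 2.0 * np.pi, n)
    v = rng.uniform(0.0, 2.0 * np.pi, n)
    X = np.zeros((n, d))
    X[:, 0] = (R_major + r_minor * np.cos(v)) * np.cos(u)
    X[:, 1] = (R_major + r_minor * np.cos(v)) * np.sin(u)
    X[:, 2] = r_minor * np.sin(v)
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal((n, d))
    labels = np.array([f"Q{q + 1}" for q in (u // (np.pi / 2)).astype(int) % 4])
    return SyntheticDataset(X=X, labels=labels, noise_sd=noise_sd, seed=seed,
                            generator="torus",
                            params=dict(n=n, d=d, R_major=R_major,
                                        r_minor=r_minor))


def sample_plane(n: int, dprime: int, d: int, noise_sd: float = 0.0,
                 seed: int = 0, extent: float = 2.0) -> SyntheticDataset:
    """Uniform box on a random d'-dimensional affine subspace plus noise.

    The plane basis and offset are recorded in ``params``.
    """
    if not 1 <= dprime < d:
        raise ValueError("need 1 <= d' < d")
    rng = np.random.default_rng(seed)
    Q = _random_orthogonal(d, rng)[:, :dprime]
    offset = rng.uniform(-1.0, 1.0, d)
    T = rng.uniform(-extent, extent, (n, dprime))
    X = offset + T @ Q.T
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal((n, d))
    return SyntheticDataset(X=X, noise_sd=noise_sd, seed=seed,
                            generator="plane",
                            params=dict(n=n, d=d, dprime=dprime, basis=Q,
                                        offset=offset))


def sample_clustered_spheres(n: int, d: int, n_clusters: int = 3,
                             radius: float = 1.0, separation: float = 6.0,
                             noise_sd: float = 0.1, seed: int = 0) -> SyntheticDataset:
    """Several small spheres at well-separated centers, labelled by cluster."""
    rng = np.random.default_rng(seed)
    centers = separation * rng.standard_normal((n_clusters, d))
    sizes = np.full(n_clusters, n // n_clusters)
    sizes[: n % n_clusters] += 1
    rows, labels = [], []
    for k in range(n_clusters):
        G = rng.standard_normal((sizes[k], d))
        U = G / np.linalg.norm(G, axis=1, keepdims=True)
        pts = centers[k] + radius * U
        if noise_sd > 0:
            pts = pts + noise_sd * rng.standard_normal(pts.shape)
        rows.append(pts)
        labels.extend([f"C{k + 1}"] * sizes[k])
    return SyntheticDataset(X=np.vstack(rows), labels=np.array(labels),
                            noise_sd=noise_sd, seed=seed,
                            generator="clustered_spheres",
                            params=dict(n=n, d=d, n_clusters=n_clusters))


def standard_battery(seed: int = 0, n_datasets: int = 20):
    """The standard evaluation battery: a deterministic list of
    ``(SyntheticDataset, dprime)`` pairs cycling through noisy sub-spheres,
    tori, planes, clustered spheres and heavy-tailed sub-spheres.

    Sized for quick complete runs (n = 240-250, d = 6, d' in {1, 2}); the
    per-dataset seeds are derived from ``seed`` so the whole battery is a
    pure function of its arguments.
    """
    battery = []
    for i in range(n_datasets):
        s = 1000 * seed + i
        rng = np.random.default_rng(s)
        kind = i % 5
        if kind == 0:  # noisy rotated/shifted sub-sphere
            dprime = 1 + i // 5 % 2
            idx = np.sort(rng.choice(6, size=dprime + 1, replace=False))
            ds = sample_subsphere(
                250, 6, idx, center=rng.uniform(-1, 1, 6),
                radius=1.0 + rng.uniform(0.0, 1.0), noise_sd=0.1,
                rotation=_random_orthogonal(6, rng),
                shift=rng.uniform(-2, 2, 6), seed=s)
        elif kind == 1:
            dprime = 2
            ds = sample_torus(250, 2.0, 0.7, 6, noise_sd=0.05, seed=s)
        elif kind == 2:
            dprime = 1 + i // 5 % 2
            ds = sample_plane(250, dprime, 6, noise_sd=0.1, seed=s)
        elif kind == 3:
            dprime = 2
            ds = sample_clustered_spheres(240, 6, n_clusters=3, radius=1.0,
                                          separation=6.0, noise_sd=0.1,
                                          seed=s)
        else:  # heavy-tailed noise on a sub-sphere
            dprime = 2
            idx = np.sort(rng.choice(6, size=3, replace=False))
            ds = sample_subsphere(
                250, 6, idx, center=rng.uniform(-1, 1, 6),
                radius=1.0 + rng.uniform(0.0, 1.0), noise_sd=0.1,
                seed=s, heavy_tailed=True, t_dof=3.0)
        battery.append((ds, dprime))
    return battery


def sample_cell_cycle_like(n: int, d: int,
                           phase_fractions=DEFAULT_PHASE_FRACTIONS,
                           phase_dispersions=DEFAULT_PHASE_DISPERSIONS,
                           radius: float = 10.0, seed: int = 0) -> SyntheticDataset:
    """Cyclic phase structure on a planted circle in R^d.

    Phase angles are drawn uniformly from contiguous arcs in the cyclic order
    G1 -> S -> G2 -> M around a circle of the given radius, embedded in a
    random 2-dimensional subspace; each phase gets its own isotropic Gaussian
    dispersion (defaults make G1 the most dispersed and S the least, with G2
    and M intermediate).  Returns phase labels and the true phase angles in
    ``params['phase_angles']``.
    """
    fr = np.asarray(phase_fractions, dtype=float)
    disp = np.asarray(phase_dispersions, dtype=float)
    if fr.size != 4 or disp.size != 4:
        raise ValueError("need 4 phase fractions and 4 dispersions")
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("phase fractions must sum to 1")
    if np.any(disp <= 0):
        raise ValueError("dispersions must be positive")
    rng = np.random.default_rng(seed)
    counts = np.floor(fr * n).astype(int)
    counts[0] += n - counts.sum()
    bounds = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(fr)])
    angles, labels, sds = [], [], []
    for p in range(4):
        th = rng.uniform(bounds[p], bounds[p + 1], counts[p])
        angles.append(th)
        labels.extend([PHASES[p]] * counts[p])
        sds.append(np.full(counts[p], disp[p]))
    theta = np.concatenate(angles)
    sd = np.concatenate(sds)
    labels = np.array(labels)
    perm = rng.permutation(n)
    theta, sd, labels = theta[perm], sd[perm], labels[perm]
    Q = _random_orthogonal(d, rng)
    circle = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    X = circle @ Q[:, :2].T
    X = X + sd[:, None] * rng.standard_normal((n, d))
    truth = SphereModel(rotation=Q, mean=np.zeros(d),
                        index_set=np.array([0, 1]), center=np.zeros(d),
                        radius=float(radius), retained_dim=1, seed=seed)
    return SyntheticDataset(X=X, truth=truth, labels=labels,
                            noise_sd=float(disp.mean()), seed=seed,
                            generator="cell_cycle",
                            params=dict(n=n, d=d, radius=radius,
                                        phase_angles=theta,
                                        fractions=tuple(fr),
                                        dispersions=tuple(disp)))
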