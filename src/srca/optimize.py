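"""Sphere-fitting optimization: subset selection plus (center, radius) updates.

The discrete problem minimizes the geometric loss over index sets of size
d'+1 together with a center and radius.  For a fixed index set the loss is
minimized by alternating an exact radius update (the mean of in-subspace
distances) with a backtracking gradient descent on the center; the subset is
chosen either exhaustively or through an l1 relaxation over a continuous
selection vector on the capped simplex, rounded and refitted.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    geometric_loss,
    sqdist_to_sphere,
    validate_index_set,
    validate_weight,
)

logger = logging.getLogger("srca")


@dataclass
class FitOptions:
    """Knobs of the sphere-fitting optimizer.

    ``search`` picks the subset strategy; ``auto`` uses exhaustive search when
    the number of size-(d'+1) subsets is at most ``combo_budget`` and the l1
    relaxation otherwise.  ``init`` selects the starting centers for the
    alternating scheme: the column mean, the two-step spherical-PCA solution,
    or both (keeping the better fit).
    """

    search: str = "auto"
    max_outer_iters: int = 200
    center_gd_max_iters: int = 60
    backtrack_shrink: float = 0.5
    armijo: float = 1e-4
    tol_loss: float = 1e-10
    outer_stall_tol: float = 1e-6
    outer_stall_patience: int = 5
    r_max_factor: float = 1e6
    plane_init_factor: float = 1e4
    combo_budget: int = 500
    seed: int = 0
    init: str = "both"
    l1_max_iters: int = 250
    l1_starts: int = 5

    def __post_init__(self):
        if self.search not in ("exhaustive", "l1", "auto"):
            raise ValueError(f"unknown search mode {self.search!r}")
        if self.init not in ("mean", "spca", "both"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.max_outer_iters < 1 or self.center_gd_max_iters < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.tol_loss <= 0:
            raise ValueError("tol_loss must be > 0")


@dataclass
class SearchResult:
    """Outcome of a subset search: winning subset, fit and bookkeeping."""

    index_set: np.ndarray
    center: np.ndarray
    radius: float
    loss: float
    n_subsets_evaluated: int
    converged: bool
    trace: list = field(default_factory=list)


def data_diameter(X: np.ndarray) -> float:
    """Cheap upper bound on the data diameter (bounding-box diagonal)."""
    span = X.max(axis=0) - X.min(axis=0)
    return float(np.linalg.norm(span))


def _radical(X, c, idx, W):
    """Per-row sqrt((x-c)' W' I_I W (x-c))."""
    D = X - c
    if W is None:
        block = D[:, idx]
    else:
        block = (D @ W.T)[:, idx]
    return np.linalg.norm(block, axis=1)


def update_radius(X, c, index_set, W=None) -> float:
    """Exact minimizer of the loss in r: mean in-subspace distance to c."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=float).ravel()
    idx = validate_index_set(index_set, c.size)
    r = float(_radical(X, c, idx, W).mean())
    if r <= 0.0:
        raise ValueError("data collapsed to center: radius update is zero")
    return r


def _center_gradient(X, c, r, idx, W):
    """Gradient of the loss in c; rows with zero radical contribute only the
    quadratic term (subgradient convention)."""
    D = X - c
    if W is None:
        s = np.linalg.norm(D[:, idx], axis=1)
        g = -2.0 * D.sum(axis=0)
        safe = np.where(s > 0, s, 1.0)
        coef = np.where(s > 0, 2.0 * r / safe, 0.0)
        g[idx] += (coef[:, None] * D[:, idx]).sum(axis=0)
    else:
        WD = D @ W.T
        s = np.linalg.norm(WD[:, idx], axis=1)
        g = -2.0 * (WD).sum(axis=0)
        safe = np.where(s > 0, s, 1.0)
        coef = np.where(s > 0, 2.0 * r / safe, 0.0)
        M = np.zeros_like(WD)
        M[:, idx] = coef[:, None] * WD[:, idx]
        g += (M @ W).sum(axis=0)
    return g


def update_center(X, r, index_set, W=None, c_init=None, opts: FitOptions | None = None):
    """Minimize the loss in c for fixed (r, index_set).

    With the identity weight the coordinates outside the index set have the
    closed-form solution (the column means) and gradient descent runs only on
    the in-subset block; under a general weight all coordinates enter the
    gradient system.  Backtracking line search guarantees the loss never
    increases across accepted steps.
    """
    opts = opts or FitOptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    idx = validate_index_set(index_set, d)
    if r <= 0:
        raise ValueError("radius must be positive")
    c = (np.asarray(c_init, dtype=float).ravel().copy()
         if c_init is not None else X.mean(axis=0))
    if W is None:
        # complement coordinates have the closed-form optimum (column means)
        # and the off-subset loss term is then constant: descend only on the
        # in-subset block
        comp = np.setdiff1d(np.arange(d), idx)
        c[comp] = X[:, comp].mean(axis=0)
        Xi = X[:, idx]
        ci = c[idx].copy()

        def block_loss(cb):
            nm = np.linalg.norm(Xi - cb, axis=1)
            return float(((nm - r) ** 2).sum())

        loss = block_loss(ci)
        step = 1.0 / max(1.0, 2.0 * X.shape[0])
        for _ in range(opts.center_gd_max_iters):
            D = Xi - ci
            nm = np.linalg.norm(D, axis=1)
            safe = np.where(nm > 0, nm, 1.0)
            coef = np.where(nm > 0, 2.0 * r / safe, 0.0) - 2.0
            g = (coef[:, None] * D).sum(axis=0)
            gnorm2 = float(g @ g)
            if gnorm2 <= 1e-30:
                break
            t = step * 2.0
            accepted = False
            for _bt in range(60):
                c_try = ci - t * g
                new_loss = block_loss(c_try)
                if new_loss <= loss - opts.armijo * t * gnorm2:
                    accepted = True
                    break
                t *= opts.backtrack_shrink
            if not accepted:
                break
            step = t
            rel = (loss - new_loss) / max(abs(loss), 1e-30)
            ci, loss = c_try, new_loss
            if rel < opts.tol_loss:
                break
        c[idx] = ci
        return c

    loss = geometric_loss(X, c, r, idx, W)
    step = 1.0 / max(1.0, 2.0 * X.shape[0])
    for _ in range(opts.center_gd_max_iters):
        g = _center_gradient(X, c, r, idx, W)
        gnorm2 = float(g @ g)
        if gnorm2 <= 1e-30:
            break
        t = step * 2.0
        accepted = False
        for _bt in range(60):
            c_try = c - t * g
            new_loss = geometric_loss(X, c_try, r, idx, W)
            if new_loss <= loss - opts.armijo * t * gnorm2:
                accepted = True
                break
            t *= opts.backtrack_shrink
        if not accepted:
            break
        step = t
        rel = (loss - new_loss) / max(abs(loss), 1e-30)
        c, loss = c_try, new_loss
        if rel < opts.tol_loss:
            break
    return c


def _spca_init(X, idx):
    """Starting center/radius from the two-step algebraic sphere fit on the
    in-subset coordinates (complement at the column means)."""
    from .baselines import algebraic_sphere_fit

    c = X.mean(axis=0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank-deficient fits are a valid init
            c_sub, r0 = algebraic_sphere_fit(X[:, idx])
        c = c.copy()
        c[idx] = c_sub
        if not (np.all(np.isfinite(c)) and np.isfinite(r0) and r0 > 0):
            return None
        return c, float(r0)
    except (ValueError, np.linalg.LinAlgError):
        return None


def fit_fixed_subset(X, index_set, W=None, opts: FitOptions | None = None):
    """Alternating (radius, center) minimization for a fixed index set.

    Runs from each configured initialization and keeps the best.  Returns
    ``(c, r, loss, trace, converged)`` where ``trace`` is the non-increasing
    sequence of losses at accepted iterates of the winning run.
    """
    opts = opts or FitOptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    idx = validate_index_set(index_set, d)
    if W is not None:
        W = validate_weight(W, d)
    if n < idx.size:
        raise ValueError("need at least as many samples as retained coordinates")
    r_cap = opts.r_max_factor * max(data_diameter(X), 1e-300)

    starts = []
    if opts.init in ("mean", "both"):
        starts.append(("mean", X.mean(axis=0), None))
    if opts.init in ("spca", "both"):
        sp = _spca_init(X, idx)
        if sp is not None:
            starts.append(("spca", sp[0], sp[1]))
    if opts.init == "both":
        # planar-limit start: push the center far along the least-variance
        # in-subset axis so the sphere can act as a plane of the same
        # retained dimension (the large-radius limit of the model)
        c0 = X.mean(axis=0)
        block = X[:, idx] - c0[idx]
        _, _, Vt = np.linalg.svd(block, full_matrices=False)
        u = Vt[-1]
        h = opts.plane_init_factor * max(data_diameter(X), 1e-300)
        c_plane = c0.copy()
        c_plane[idx] = c0[idx] - h * u
        starts.append(("plane", c_plane, None))

    best = None
    for name, c0, r0 in starts:
        c = c0.copy()
        try:
            r = float(r0) if r0 is not None else update_radius(X, c, idx, W)
        except ValueError:
            continue
        if r > r_cap:
            logger.info("radius clamped at initialization (%s start)", name)
            r = r_cap
        loss = geometric_loss(X, c, r, idx, W)
        trace = [loss]
        converged = False
        stall = 0
        for _ in range(opts.max_outer_iters):
            try:
                r_new = update_radius(X, c, idx, W)
            except ValueError:
                break
            if r_new > r_cap:
                logger.info("radius clamped to %.3e (cap %.1e x diameter)",
                            r_cap, opts.r_max_factor)
                r_new = r_cap
            r = r_new
            c = update_center(X, r, idx, W, c_init=c, opts=opts)
            new_loss = geometric_loss(X, c, r, idx, W)
            trace.append(new_loss)
            if loss - new_loss < opts.tol_loss * max(abs(loss), 1e-30):
                loss = min(loss, new_loss)
                converged = True
                break
            # drop a start whose relative progress has flattened out; the
            # threshold is looser when an incumbent start is already ahead
            slow_tol = (1e-3 if (best is not None and new_loss > best[0])
                        else opts.outer_stall_tol)
            stall = stall + 1 if loss - new_loss < slow_tol * abs(loss) else 0
            if stall >= opts.outer_stall_patience:
                loss = new_loss
                break
            loss = new_loss
        cand = (loss, c, r, trace, converged)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise ValueError("all initializations failed (data collapsed to center?)")
    loss, c, r, trace, converged = best
    return c, r, loss, trace, converged


def auto_search_policy(d: int, dprime: int, combo_budget: int = 500) -> str:
    """'exhaustive' when C(d, d'+1) fits the budget, else 'l1'."""
    k = dprime + 1
    if not (1 <= k <= d):
        raise ValueError("need 1 <= d'+1 <= d")
    return "exhaustive" if math.comb(d, k) <= combo_budget else "l1"


def exhaustive_search(X, dprime: int, W=None, opts: FitOptions | None = None,
                      force: bool = False) -> SearchResult:
    """Fit every size-(d'+1) coordinate subset and return the best.

    Ties in loss go to the lexicographically smallest index set.  Refuses to
    run past ``opts.combo_budget`` subsets unless ``force`` is set.
    """
    opts = opts or FitOptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    k = dprime + 1
    n_combos = math.comb(d, k)
    if n_combos > opts.combo_budget and not force:
        raise ValueError(
            f"{n_combos} subsets exceed the budget of {opts.combo_budget}; "
            "use the l1 search (or force=True)")
    best = None
    for combo in itertools.combinations(range(d), k):
        idx = np.array(combo)
        try:
            c, r, loss, trace, conv = fit_fixed_subset(X, idx, W, opts)
        except ValueError:
            continue
        if best is None or loss < best.loss:
            best = SearchResult(idx, c, r, loss, n_combos, conv, trace)
    if best is None:
        raise ValueError("no subset admitted a valid sphere fit")
    logger.info("exhaustive search: %d subsets, best loss %.6e on %s",
                n_combos, best.loss, (best.index_set + 1).tolist())
    return best


def project_capped_simplex(y: np.ndarray, s: float) -> np.ndarray:
    """Euclidean projection onto {v : 0 <= v <= 1, sum(v) <= s}."""
    v = np.clip(y, 0.0, 1.0)
    if v.sum() <= s:
        return v
    lo, hi = 0.0, float(np.max(y))
    for _ in range(100):
        tau = 0.5 * (lo + hi)
        if np.clip(y - tau, 0.0, 1.0).sum() > s:
            lo = tau
        else:
            hi = tau
    return np.clip(y - hi, 0.0, 1.0)


def _relaxed_loss_terms(X, c, v, W):
    """Quadratic term and per-row radical sqrt(sum_j v_j [W(x-c)]_j^2)."""
    D = X - c
    WD = D if W is None else D @ W.T
    quad = np.einsum("ij,ij->i", D, WD)
    q = (WD ** 2) @ v
    return quad, np.sqrt(np.maximum(q, 0.0)), WD


def _relaxed_loss(X, c, r, v, W):
    quad, rad, _ = _relaxed_loss_terms(X, c, v, W)
    return float(np.sum(quad + r * r - 2.0 * r * rad))


def l1_search(X, dprime: int, W=None, opts: FitOptions | None = None) -> SearchResult:
    """Continuous relaxation of the subset choice, rounded and refitted.

    The binary selection vector is relaxed to v in [0,1]^d with an l1 budget
    of d'+1; projected gradient steps on (v, c) alternate with the exact
    radius update, from several starts (an informed variance-ordered start, a
    uniform start, and seeded random starts).  The d'+1 largest entries of v
    define the final index set, which is refitted exactly, so the returned
    loss is always a valid discrete-solution loss.
    """
    opts = opts or FitOptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    k = dprime + 1
    if not 1 <= k <= d:
        raise ValueError("need 1 <= d'+1 <= d")
    if W is not None:
        W = validate_weight(W, d)
    rng = np.random.default_rng(opts.seed)

    # candidate starting selection vectors
    col_var = X.var(axis=0)
    informed = np.zeros(d)
    informed[np.argsort(col_var)[::-1][:k]] = 1.0
    starts = [informed, np.full(d, min(1.0, k / d))]
    while len(starts) < max(opts.l1_starts, 2):
        starts.append(project_capped_simplex(rng.random(d), float(k)))

    best = None
    n_evaluated = 0
    for v0 in starts:
        v = project_capped_simplex(np.asarray(v0, dtype=float), float(k))
        c = X.mean(axis=0)
        try:
            quad, rad, _ = _relaxed_loss_terms(X, c, v, W)
            r = float(rad.mean())
            if r <= 0:
                raise ValueError
        except (ValueError, FloatingPointError):
            continue
        loss = _relaxed_loss(X, c, r, v, W)
        step_v = 1.0 / max(1.0, n)
        step_c = 1.0 / max(1.0, 2.0 * n)
        diverged = False
        for _ in range(opts.l1_max_iters):
            quad, rad, WD = _relaxed_loss_terms(X, c, v, W)
            r = float(rad.mean())
            if r <= 0 or not np.isfinite(r):
                diverged = True
                break
            loss = _relaxed_loss(X, c, r, v, W)
            # gradient in v: -r * sum_i [W(x_i-c)]_j^2 / radical_i
            safe = np.where(rad > 0, rad, 1.0)
            gv = -r * ((WD ** 2) / safe[:, None]).sum(axis=0)
            t = step_v * 2.0
            for _bt in range(40):
                v_try = project_capped_simplex(v - t * gv, float(k))
                if _relaxed_loss(X, c, r, v_try, W) <= loss + 1e-15:
                    break
                t *= 0.5
            v = v_try
            step_v = t
            # gradient in c
            coef = np.where(rad > 0, 2.0 * r / safe, 0.0)
            M = coef[:, None] * (WD * v)
            if W is not None:
                M = M @ W
            gc = -2.0 * WD.sum(axis=0) + M.sum(axis=0)
            cur = _relaxed_loss(X, c, r, v, W)
            t = step_c * 2.0
            gn2 = float(gc @ gc)
            if gn2 > 0:
                for _bt in range(40):
                    c_try = c - t * gc
                    if _relaxed_loss(X, c_try, r, v, W) <= cur - opts.armijo * t * gn2:
                        c = c_try
                        break
                    t *= 0.5
                step_c = t
            new_loss = _relaxed_loss(X, c, r, v, W)
            if abs(loss - new_loss) < opts.tol_loss * max(abs(loss), 1e-30):
                break
            loss = new_loss
        if diverged or not np.all(np.isfinite(v)):
            logger.info("l1 start discarded (diverged)")
            continue
        idx = np.sort(np.argsort(v)[::-1][:k])
        try:
            c_f, r_f, loss_f, trace, conv = fit_fixed_subset(X, idx, W, opts)
        except ValueError:
            continue
        n_evaluated += 1
        cand = SearchResult(idx, c_f, r_f, loss_f, n_evaluated, conv, trace)
        if (best is None or cand.loss < best.loss
                or (cand.loss == best.loss
                    and tuple(cand.index_set) < tuple(best.index_set))):
            best = cand
    if best is None:
        raise ValueError("all l1 starts failed")
    best.n_subsets_evaluated = n_evaluated
    logger.info("l1 search: %d rounded subsets refitted, best loss %.6e on %s",
                n_evaluated, best.loss, (best.index_set + 1).tolist())
    return best


def search_subsets(X, dprime: int, W=None, opts: FitOptions | None = None) -> SearchResult:
    """Run the subset search selected by ``opts.search`` (resolving 'auto')."""
    opts = opts or FitOptions()
    d = np.atleast_2d(np.asarray(X)).shape[1]
    mode = opts.search
    if mode == "auto":
        mode = auto_search_policy(d, dprime, opts.combo_budget)
        logger.info("auto search policy chose %s (C(%d,%d)=%d, budget %d)",
                    mode, d, dprime + 1, math.comb(d, dprime + 1),
                    opts.combo_budget)
    if mode == "exhaustive":
        return exhaustive_search(X, dprime, W, opts)
    return l1_search(X, dprime, W, opts)
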