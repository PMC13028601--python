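# Methods

This note records the model fitted by `srca`, the estimation algorithm, the
synthetic data generators used for evaluation, the numerical choices that
matter for correctness, and the known limitations.

## Model

Data are `n` observations in `R^d`. The reduced representation has intrinsic
dimension `d′` (a circle is `d′ = 1` although it is embedded in two
coordinates). The fitted object is a sphere

```
S_ℐ(c, r) = { z : ‖(z − c)_ℐ‖ = r,  z_j = c_j for j ∉ ℐ }
```

living in the coordinate subspace selected by an index set `ℐ` with
`|ℐ| = d′ + 1`, inside the rotated, centered frame `Z = (X − x̄) R` with `R`
orthogonal. The squared distance from a point `z` to the sphere is

```
d²(z, S) = (z−c)ᵀ W (z−c) + r² − 2 r √( (z−c)ᵀ Wᵀ I_ℐ W (z−c) )
```

where `I_ℐ` zeroes the coordinates outside `ℐ` and `W` is an optional
symmetric positive semidefinite weight (identity by default). With `W = I`
this is exactly the squared Euclidean distance to the nearest sphere point,
and it decomposes as

```
d²(z, S) = ‖(z − c)_ℐᶜ‖²  +  ( ‖(z − c)_ℐ‖ − r )².
```

The fit minimizes the geometric loss `L(ℐ, c, r) = Σᵢ d²(zᵢ, S)`.
Coordinates outside `ℐ` enter the loss through their deviation from `c_j`,
so with `W = I` their optimal centers are the column means in closed form.

### Estimation

For a fixed `ℐ` the loss is minimized by alternating two steps:

- **Radius.** `r* = (1/n) Σᵢ √(radicalᵢ)` is the exact minimizer of the
  loss in `r` (the mean in-subspace distance to the center); this is a
  one-line closed form, verified in the tests against a dense grid.
- **Center.** Gradient descent with backtracking line search (Armijo
  condition, shrink factor 0.5). With `W = I` the descent runs only on the
  in-subset block, since the complement has the closed-form solution; with
  a general weight all coordinates enter the gradient system. Accepted
  steps never increase the loss, so the outer loss trace is non-increasing.

The alternation runs from up to three starting centers and keeps the best:

1. the column means ("mean" start);
2. the two-step solution — an algebraic sphere fit (linear least squares on
   `‖y‖² = 2yᵀc + (r² − ‖c‖²)`) on the in-subset coordinates ("spca"
   start), which guarantees the final fit is at least as good as the
   two-step baseline on the same subset;
3. a "plane-limit" start: the center displaced far along the least-variance
   in-subset direction (10⁴ × the bounding-box diameter; see *Numerical
   choices*), from which the sphere can approach its flat limit. This
   guarantees the fit is never worse than the best `d′`-dimensional plane
   through the same subset, and hence never worse than PCA when the
   rotation is PCA and the leading subset is enumerated.

### Subset search

- **Exhaustive**: all `C(d, d′+1)` subsets when that count is within the
  budget (default 500). Ties in loss are broken toward the
  lexicographically smallest subset, so results are deterministic.
- **Relaxed (`l1`)**: the binary membership vector is relaxed to
  `v ∈ [0,1]^d` with `‖v‖₁ ≤ d′+1`; the loss with `I_ℐ` replaced by
  `diag(v)` is optimized by projected gradient steps on `(v, c)` (Euclidean
  projection onto the capped simplex by bisection) alternating with the
  exact radius update, from several starts: a variance-ordered informed
  start, a uniform start, and seeded random starts. The `d′+1` largest
  entries of `v` are then rounded to a subset and refit exactly, so the
  reported parameters always come from an exact fixed-subset fit.
- **Auto** (default): exhaustive within budget, relaxed otherwise.

### Rotations

- **PCA**: eigendecomposition of the covariance, eigenvalues descending,
  each eigenvector's largest-magnitude entry made positive (deterministic
  signs).
- **Orthomax family** (quartimax γ=0, varimax γ=1, equamax γ=m/2, parsimax
  γ=d(m−1)/(d+m−2)): SVD-based iteration on the top-`m` PCA loadings; the
  orthogonal complement is left untouched.
- **FastICA** (log-cosh contrast) with polar orthonormalization of the
  unmixing matrix so the overall transform stays orthogonal; falls back to
  PCA with a warning if it does not converge.

### Projection and angles

Each point is projected to its nearest sphere point: complement coordinates
snap to `c`, in-subset coordinates are rescaled radially to radius `r`.
Points exactly at the center have no unique nearest point; they are sent to
`c + r e_min(ℐ)` (the first in-subset axis) and flagged. Unit coordinates
are converted to hyperspherical angles: `atan2` for `d′ = 1`,
(longitude, latitude) for `d′ = 2` with poles assigned longitude 0, and the
standard recursion for `d′ ≥ 3`. Indexing is 0-based in the Python API and
1-based in files, logs and summaries.

## Evaluation metrics

- **Coranking matrix**: joint histogram of pairwise-distance ranks in the
  two spaces, ranks 1..n−1 per row, distance ties broken toward the smaller
  point index (via a stable lexicographic sort), validated against a
  brute-force double loop. From it `Q_NX(K)`, `R_NX(K)`, the flat-mean AUC
  and the `1/K`-weighted WAUC.
- **Cophenetic correlation**: Pearson correlation of the upper-triangular
  pairwise distances.
- **Cluster indices**: silhouette, Calinski-Harabasz, Davies-Bouldin
  (scikit-learn); coincident cluster centroids with nonzero scatter are
  reported as infinite Davies-Bouldin rather than scikit-learn's 0.
- **Circular (rank) correlation**: the Fisher–Lee statistic on angles, and
  its rank version which is invariant to monotone circular warps.

## Synthetic generators

All generators are pure functions of their parameters and a seed.

- `sample_subsphere`: uniform points on a planted sub-sphere (normalized
  Gaussians), optional isotropic Gaussian or Student-t noise (t noise is
  rescaled so its standard deviation matches the nominal `noise_sd`),
  optional rotation/shift out of standard position; ground-truth parameters
  are returned.
- `sample_torus`, `sample_plane`, `sample_clustered_spheres`: classic
  manifolds for the evaluation battery.
- `sample_cell_cycle_like`: a caricature of cell-cycle structure —
  contiguous arcs for G1/S/G2/M (occupancies 0.35/0.25/0.25/0.15) on a
  circle of radius 10 in a random 2-d subspace of `R^d`, with per-phase
  isotropic noise (1.0/0.3/0.6/0.6), making G1 the most dispersed phase
  and S the least. It reproduces the qualitative phenomena a circular
  embedding should capture (cyclic order, phase-dependent spread) but it is
  *not* a realistic expression model: no count noise, no library-size or
  batch effects, Gaussian rather than heavy-tailed marginals, and a
  perfectly circular backbone.
- `standard_battery`: the fixed 20-dataset evaluation battery (noisy
  rotated sub-spheres, tori, planes, clustered spheres, heavy-tailed
  sub-spheres; n = 240–250, d = 6, d′ ∈ {1, 2}), a pure function of its
  seed. The sizes keep a complete battery run within a few CPU-minutes
  while covering every generator family at both retained dimensions.

## Numerical choices

- **Stable distance form.** With `W = I` the squared distance is computed
  as `‖(z−c)_ℐᶜ‖² + (‖(z−c)_ℐ‖ − r)²`, never as the expanded
  `q + r² − 2r√q`: at the plane limit (`r ~ 10⁴` × data scale) the expanded
  form loses ~8 digits to cancellation; the stable form is exact. Under a
  general weight the expanded form is the definition and small negative
  round-off is clipped at zero.
- **Plane-limit initialization.** The displaced start uses
  `10⁴ ×` the bounding-box diagonal: far enough that the sphere through the
  data is flat to ~10⁻⁸ relative curvature, small enough that `r²` stays
  comfortably inside double precision.
- **Optimizer budgets.** Center descent uses at most 60 inner iterations
  per alternation (the alternation itself re-enters the center step, so a
  large inner budget mostly duplicates work); the outer loop stops after
  200 iterations, on a relative improvement below 10⁻¹⁰, or after 5
  consecutive outer iterations improving by less than 10⁻⁶ relative (a
  looser 10⁻³ stall threshold applies when the current start already trails
  the incumbent across starts, since polishing a losing start is wasted
  work). These caps were chosen for responsiveness; monotonicity of the
  trace is unaffected, and the acceptance suite verifies that accuracy
  targets hold under them.
- **Determinism.** Every stochastic component (random starts, generators,
  FastICA) is driven by explicit seeds; subset ties break
  lexicographically; PCA signs are fixed. Two runs with the same inputs
  and seeds produce byte-identical outputs.

## Limitations

- The loss is non-convex in `(c, r)`; the optimizer guarantees monotone
  descent to a stationary point, not a global optimum. Multiple starts
  mitigate but do not eliminate this.
- The relaxed subset search is a heuristic: it matches exhaustive search on
  the tested instances, but has no optimality guarantee out of budget
  range.
- A single global sphere is fitted. Data on several spheres, or on
  manifolds that are not spheres (e.g. a torus), are approximated by the
  best single sphere; the reconstruction error reflects the model mismatch.
- The weighted loss with eigenvalues of `W` above 1 is a model definition,
  not a Euclidean distance; its value can only be interpreted relative to
  the same `W`.
- Hyperspherical angles have coordinate singularities at the poles
  (`d′ ≥ 2`); angle-space Euclidean metrics (silhouette, coranking on
  angles) ignore the 2π wrap unless the caller embeds angles on the unit
  circle first, as `scripts/acceptance.py` does.
- The cell-cycle-like generator supports qualitative claims about cyclic
  structure recovery only; no claims about real single-cell data are made
  or tested here.
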