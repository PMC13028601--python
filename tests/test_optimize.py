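"""Radius/center updates, fixed-subset fits and the two subset searches."""

import itertools

import numpy as np
import pytest

from srca import synthetic
from srca.geometry import geometric_loss
from srca.model import srca_fit, srca_transform
from srca.optimize import (
    FitOptions,
    auto_search_policy,
    exhaustive_search,
    fit_fixed_subset,
    l1_search,
    project_capped_simplex,
    update_center,
    update_radius,
)
from conftest import random_orthogonal


class TestUpdateRadius:
    def test_mean_of_in_subset_distances(self):
        X = np.array([[2.0, 0, 5], [0, 4.0, -1]])
        assert update_radius(X, np.zeros(3), [0, 1]) == pytest.approx(3.0)

    def test_exact_on_sphere(self, planted_sphere):
        t = planted_sphere.truth
        r = update_radius(planted_sphere.X, t.center, t.index_set)
        assert r == pytest.approx(t.radius, abs=1e-12)

    def test_beats_dense_grid(self, rng):
        for _ in range(5):
            X = rng.normal(size=(40, 4), scale=2.0)
            c = rng.normal(size=4)
            idx = [0, 2]
            r_star = update_radius(X, c, idx)
            loss_star = geometric_loss(X, c, r_star, idx)
            dmax = np.linalg.norm((X - c)[:, idx], axis=1).max()
            grid = np.linspace(1e-9, 2 * dmax, 10_001)
            losses = [geometric_loss(X, c, g, idx) for g in grid]
            assert loss_star <= min(losses) + 1e-12

    def test_collapsed_data_raises(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        with pytest.raises(ValueError):
            update_radius(X, np.array([1.0, 2.0, 3.0]), [0, 1])


class TestUpdateCenter:
    def test_symmetric_data_pulls_center_to_origin(self, rng):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        X = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(60)])
        c0 = np.array([0.05, -0.03, 0.0])
        c = update_center(X, 1.0, [0, 1], c_init=c0,
                          opts=FitOptions(center_gd_max_iters=500))
        assert np.linalg.norm(c[:2]) < 1e-6

    def test_complement_coordinates_are_column_means(self, rng):
        X = rng.normal(size=(25, 5), loc=3.0)
        c = update_center(X, 1.0, [1, 2], c_init=rng.normal(size=5))
        means = X.mean(axis=0)
        np.testing.assert_allclose(c[[0, 3, 4]], means[[0, 3, 4]], atol=1e-14)

    def test_beats_center_grid_oracle(self, rng):
        X = rng.normal(size=(10, 2), scale=1.5)
        idx = [0, 1]
        r = 1.0
        c = update_center(X, r, idx, c_init=X.mean(axis=0),
                          opts=FitOptions(center_gd_max_iters=2000,
                                          tol_loss=1e-14))
        loss = geometric_loss(X, c, r, idx)
        m = X.mean(axis=0)
        g1 = np.linspace(m[0] - 1.5, m[0] + 1.5, 101)
        g2 = np.linspace(m[1] - 1.5, m[1] + 1.5, 101)
        grid_losses = [geometric_loss(X, np.array([a, b]), r, idx)
                       for a in g1 for b in g2]
        assert loss <= min(grid_losses) + 1e-9

    def test_weighted_gradient_matches_finite_differences(self, rng):
        from srca.optimize import _center_gradient

        X = rng.normal(size=(15, 4))
        A = rng.normal(size=(4, 4))
        W = A @ A.T + 0.5 * np.eye(4)
        # keep the spectrum in (0, 1] so the per-point squared distance
        # stays nonnegative and its clipping never binds
        W /= np.linalg.eigvalsh(W).max()
        c = rng.normal(size=4)
        idx = np.array([0, 2])
        r = 1.3
        g = _center_gradient(X, c, r, idx, W)
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            num = (geometric_loss(X, c + e, r, idx, W)
                   - geometric_loss(X, c - e, r, idx, W)) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-4)

    def test_weighted_descent_never_increases_loss(self, rng):
        X = rng.normal(size=(30, 4))
        A = rng.normal(size=(4, 4))
        W = A @ A.T + 0.5 * np.eye(4)
        c0 = X.mean(axis=0)
        r = 1.0
        idx = np.array([1, 3])
        c = update_center(X, r, idx, W, c_init=c0)
        assert (geometric_loss(X, c, r, idx, W)
                <= geometric_loss(X, c0, r, idx, W) + 1e-12)


class TestFitFixedSubset:
    def test_noiseless_sphere_recovered(self, planted_sphere):
        t = planted_sphere.truth
        c, r, loss, trace, conv = fit_fixed_subset(planted_sphere.X, t.index_set)
        assert loss < 1e-12
        assert np.linalg.norm(c - t.center) < 1e-6
        assert abs(r - t.radius) < 1e-6

    def test_trace_monotone_on_random_instances(self, rng):
        for k in range(50):
            n = int(rng.integers(10, 40))
            d = int(rng.integers(3, 6))
            X = rng.normal(size=(n, d), scale=rng.uniform(0.5, 3))
            sub = np.sort(rng.choice(d, size=2, replace=False))
            _, _, _, trace, _ = fit_fixed_subset(X, sub)
            diffs = np.diff(trace)
            assert np.all(diffs <= 1e-12 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_matches_three_parameter_grid_oracle(self):
        rng = np.random.default_rng(21)
        c0 = np.array([0.5, -0.3, 0.0])
        ds = synthetic.sample_subsphere(15, 3, [0, 1], c0, 1.2,
                                        noise_sd=0.15, seed=21)
        X = ds.X
        c, r, loss, _, _ = fit_fixed_subset(X, [0, 1])
        # coarse 3-d grid + local refinement around the winner
        best = np.inf
        for a in np.linspace(c0[0] - 0.5, c0[0] + 0.5, 25):
            for b in np.linspace(c0[1] - 0.5, c0[1] + 0.5, 25):
                cc = np.array([a, b, X[:, 2].mean()])
                rr = update_radius(X, cc, [0, 1])
                best = min(best, geometric_loss(X, cc, rr, [0, 1]))
        assert loss <= best + 1e-4


class TestExhaustiveSearch:
    def test_planted_subset_wins_over_all_candidates(self):
        ds = synthetic.sample_subsphere(80, 4, [0, 1], np.zeros(4), 1.0,
                                        noise_sd=0.0, seed=5)
        X = ds.X + 0.01 * np.random.default_rng(5).normal(size=ds.X.shape)
        res = exhaustive_search(X, 1)
        assert list(res.index_set) == [0, 1]
        assert res.n_subsets_evaluated == 6
        # the winner is strictly better than every other subset
        for combo in itertools.combinations(range(4), 2):
            if list(combo) == [0, 1]:
                continue
            _, _, other_loss, _, _ = fit_fixed_subset(X, np.array(combo))
            assert res.loss < other_loss

    def test_full_index_set_equals_fixed_fit(self, noisy_sphere):
        X = noisy_sphere.X
        res = exhaustive_search(X, X.shape[1] - 1)
        assert res.n_subsets_evaluated == 1
        _, _, loss, _, _ = fit_fixed_subset(X, np.arange(X.shape[1]))
        assert res.loss == pytest.approx(loss, rel=1e-12)

    def test_tie_broken_lexicographically(self):
        # three identical columns: every size-2 subset sees the same data,
        # so all losses tie exactly and the first subset must win
        x = np.random.default_rng(3).normal(size=60)
        X = np.column_stack([x, x, x])
        res = exhaustive_search(X, 1)
        assert list(res.index_set) == [0, 1]

    def test_budget_enforced(self, rng):
        X = rng.normal(size=(30, 12))
        with pytest.raises(ValueError, match="budget"):
            exhaustive_search(X, 2, opts=FitOptions(combo_budget=100))


class TestCappedSimplexProjection:
    def test_feasible_point_unchanged(self):
        v = np.array([0.2, 0.3, 0.1])
        np.testing.assert_allclose(project_capped_simplex(v, 2.0), v)

    def test_projection_is_feasible_and_closest(self, rng):
        for _ in range(20):
            y = rng.normal(size=6, scale=2)
            s = 3.0
            v = project_capped_simplex(y, s)
            assert np.all(v >= -1e-12) and np.all(v <= 1 + 1e-12)
            assert v.sum() <= s + 1e-9
            # no feasible random point is closer
            for _ in range(50):
                w = rng.uniform(0, 1, 6)
                if w.sum() > s:
                    w *= s / w.sum()
                assert (np.sum((y - v) ** 2)
                        <= np.sum((y - w) ** 2) + 1e-9)


class TestL1Search:
    def test_matches_exhaustive_on_planted_noiseless(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            idx0 = np.sort(rng.choice(10, 3, replace=False))
            c0 = rng.uniform(-1, 1, 10)
            ds = synthetic.sample_subsphere(120, 10, idx0, c0, 2.0,
                                            noise_sd=0.0, seed=seed)
            res = l1_search(ds.X, 2, opts=FitOptions(seed=seed))
            assert list(res.index_set) == list(idx0)
            assert res.loss < 1e-10

    def test_never_beats_exhaustive(self, noisy_sphere):
        X = noisy_sphere.X
        ex = exhaustive_search(X, 2)
        l1 = l1_search(X, 2, opts=FitOptions(seed=0))
        assert l1.loss >= ex.loss - 1e-9

    def test_deterministic_given_seed(self, noisy_sphere):
        a = l1_search(noisy_sphere.X, 1, opts=FitOptions(seed=4))
        b = l1_search(noisy_sphere.X, 1, opts=FitOptions(seed=4))
        assert list(a.index_set) == list(b.index_set)
        assert a.loss == b.loss
        np.testing.assert_array_equal(a.center, b.center)


class TestAutoPolicy:
    @pytest.mark.parametrize("d, dprime, budget, expected", [
        (10, 2, 500, "exhaustive"),   # C(10,3) = 120
        (40, 2, 500, "l1"),           # C(40,3) = 9880
        (7, 6, 500, "exhaustive"),    # single subset
    ])
    def test_policy(self, d, dprime, budget, expected):
        assert auto_search_policy(d, dprime, budget) == expected

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            auto_search_policy(3, 3, 500)


class TestPipeline:
    def test_recovery_after_planted_rotation(self):
        rng = np.random.default_rng(1)
        Q = random_orthogonal(5, seed=17)
        c0 = rng.uniform(-1, 1, 5)
        ds = synthetic.sample_subsphere(150, 5, [0, 1, 2], c0, 1.8,
                                        noise_sd=0.0, rotation=Q, seed=1)
        res = srca_fit(ds.X, 2, rotation="pca")
        assert res.mse < 1e-10
        assert abs(res.radius - 1.8) < 1e-6

    def test_rigid_motion_equivariance(self):
        ds = synthetic.sample_subsphere(100, 4, [0, 1, 2],
                                        np.zeros(4), 1.0, noise_sd=0.05,
                                        seed=2)
        Q = random_orthogonal(4, seed=8)
        b = np.array([5.0, -2.0, 1.0, 0.5])
        r1 = srca_fit(ds.X, 2, rotation="pca")
        r2 = srca_fit(ds.X @ Q.T + b, 2, rotation="pca")
        assert abs(r1.mse - r2.mse) < 1e-8

    def test_forced_full_index_set(self, noisy_sphere):
        X = noisy_sphere.X
        res = srca_fit(X, X.shape[1] - 1, rotation="identity")
        _, _, loss, _, _ = fit_fixed_subset(X - X.mean(axis=0),
                                            np.arange(X.shape[1]))
        assert res.loss == pytest.approx(loss, rel=1e-10)

    def test_transform_reproduces_training_embedding(self, noisy_sphere):
        res = srca_fit(noisy_sphere.X, 1, rotation="pca")
        emb = srca_transform(noisy_sphere.X, res.sphere)
        np.testing.assert_allclose(emb.reconstructed,
                                   res.embedding.reconstructed, atol=1e-12)
        np.testing.assert_allclose(emb.per_point_sqdist,
                                   res.embedding.per_point_sqdist, atol=1e-12)

    def test_transform_single_point_and_on_sphere_points(self, planted_sphere):
        res = srca_fit(planted_sphere.X, 2, rotation="identity")
        one = srca_transform(planted_sphere.X[:1], res.sphere)
        assert one.reconstructed.shape == (1, 6)
        assert one.per_point_sqdist[0] < 1e-10  # training point lies on sphere
        with pytest.raises(ValueError):
            srca_transform(np.zeros((2, 3)), res.sphere)

    def test_feature_permutation_permutes_index_set(self, noisy_sphere):
        X = noisy_sphere.X
        res1 = srca_fit(X, 1, rotation="identity")
        perm = np.array([4, 2, 0, 1, 3])
        res2 = srca_fit(X[:, perm], 1, rotation="identity")
        mapped = np.sort([list(perm).index(j) for j in res1.index_set])
        assert list(res2.index_set) == list(mapped)
        assert res2.loss == pytest.approx(res1.loss, rel=1e-9)
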