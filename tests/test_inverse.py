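"""Inverse solvers: Tikhonov closed forms, L1/ADMM, spatiotemporal objective,
direct spectral solve, and the dipole multiplicative update."""

import numpy as np
import pytest

from strecg.inverse import (
    L1Inverse,
    STREInverse,
    TikhonovInverse,
    solve_l1_first_order,
    solve_stre_dipole_mu,
    solve_stre_direct,
    solve_tikhonov,
    stre_objective,
)


def random_instance(rng, n=12, t=6):
    R = rng.normal(size=(n, n)) / np.sqrt(n)
    L = rng.normal(size=(n, n)) / np.sqrt(n)
    Y = rng.normal(size=(n, t))
    return R, L, Y


class TestTikhonov:
    def test_scalar_closed_form(self):
        y = np.array([2.0, -4.0, 1.0])
        x = solve_tikhonov(np.eye(3), y, None, lam=3.0, order=0)
        np.testing.assert_allclose(x, y / 4.0)

    def test_large_lambda_shrinks_to_zero(self, rng):
        R = rng.normal(size=(8, 8))
        x = solve_tikhonov(R, rng.normal(size=8), None, lam=1e12)
        assert np.abs(x).max() < 1e-9

    def test_matches_svd_filter_factors(self, rng):
        R = rng.normal(size=(10, 10))
        y = rng.normal(size=10)
        lam = 0.37
        u, s, vt = np.linalg.svd(R)
        filt = s / (s**2 + lam)
        expected = vt.T @ (filt * (u.T @ y))
        np.testing.assert_allclose(
            solve_tikhonov(R, y, None, lam=lam), expected, atol=1e-10)

    def test_matches_stacked_least_squares_oracle(self, rng):
        # independent route: augmented least squares [R; sqrt(lam) G]
        R = rng.normal(size=(9, 7))
        G = rng.normal(size=(6, 7))
        y = rng.normal(size=9)
        lam = 0.11
        aug = np.vstack([R, np.sqrt(lam) * G])
        rhs = np.concatenate([y, np.zeros(6)])
        expected, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
        np.testing.assert_allclose(
            solve_tikhonov(R, y, G, lam=lam, order=1), expected, atol=1e-8)

    def test_rank_deficient_at_zero_lambda_warns(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            solve_tikhonov(R, np.array([1.0, 1.0]), None, lam=0.0)


class TestL1FirstOrder:
    def test_zero_lambda_gives_least_squares(self, rng):
        R, _, Y = random_instance(rng)
        res = solve_l1_first_order(R, Y, np.eye(12), lam=0.0)
        np.testing.assert_allclose(res.x, np.linalg.solve(R, Y), atol=1e-6)

    def test_large_lambda_annihilates_constraint(self, rng):
        R, _, Y = random_instance(rng)
        G = np.eye(12)
        res = solve_l1_first_order(R, Y, G, lam=1e4)
        assert np.abs(G @ res.x).max() < 1e-6

    def test_matches_ista_oracle(self, rng):
        # independent proximal-gradient solver on a tiny instance
        R = rng.normal(size=(6, 5))
        G = np.eye(5)
        y = rng.normal(size=6)
        lam = 0.3
        step = 1.0 / (2 * np.linalg.norm(R, 2) ** 2)
        x = np.zeros(5)
        for _ in range(20000):
            g = 2 * R.T @ (R @ x - y)
            z = x - step * g
            x = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0)
        obj_oracle = np.sum((R @ x - y) ** 2) + lam * np.abs(x).sum()
        res = solve_l1_first_order(R, y, G, lam=lam, max_iter=5000)
        obj = np.sum((R @ res.x - y) ** 2) + lam * np.abs(res.x).sum()
        assert obj == pytest.approx(obj_oracle, rel=1e-6, abs=1e-9)

    def test_nonconvergence_reported_not_raised(self, rng):
        R, _, Y = random_instance(rng)
        res = solve_l1_first_order(R, Y, np.eye(12), lam=0.1, max_iter=3)
        assert not res.converged and res.n_iter == 3


class TestObjective:
    def test_trivial_values(self, rng):
        R, L, Y = random_instance(rng)
        assert stre_objective(R, 0 * Y, L, 1.0, 1.0, 2, 0 * Y) == 0.0
        X = rng.normal(size=Y.shape)
        assert stre_objective(R, Y, L, 0.0, 0.0, 2, X) == pytest.approx(
            np.sum((Y - R @ X) ** 2))

    def test_hand_expanded_two_node_instance(self):
        # N=2, T=2, w=1: every term written out by hand
        R = np.array([[1.0, 0.0], [0.0, 2.0]])
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        resid = (1 - 1) ** 2 + (0 - 2) ** 2 + (0 - 6) ** 2 + (1 - 8) ** 2
        lap = (1 - 3) ** 2 + (3 - 1) ** 2 + (2 - 4) ** 2 + (4 - 2) ** 2
        temporal = (1 - 2) ** 2 + (3 - 4) ** 2
        expected = resid + 0.5 * lap + 2.0 * temporal
        assert stre_objective(R, Y, L, 0.5, 2.0, 1, X) == pytest.approx(expected)


class TestDirectSolve:
    def test_gradient_vanishes_at_solution(self, rng):
        R, L, Y = random_instance(rng)
        ls, lt, w = 0.2, 0.4, 2
        X = solve_stre_direct(R, Y, L, ls, lt, w)
        from strecg.operators import temporal_coupling
        A = R.T @ R + ls * L.T @ L
        grad = 2 * (A @ X + lt * X @ temporal_coupling(Y.shape[1], w).coupling_matrix()
                    - R.T @ Y)
        assert np.linalg.norm(grad) / np.linalg.norm(2 * R.T @ Y) < 1e-10

    def test_zero_temporal_weight_decouples_to_tikhonov(self, rng):
        R, L, Y = random_instance(rng)
        X = solve_stre_direct(R, Y, L, 0.3, 0.0, 2)
        np.testing.assert_allclose(
            X, solve_tikhonov(R, Y, L, lam=0.3, order=1), atol=1e-9)

    def test_infinite_temporal_weight_gives_time_constant_field(self, rng):
        R, L, Y = random_instance(rng)
        X = solve_stre_direct(R, Y, L, 0.1, 1e10, 2)
        assert np.abs(X - X.mean(axis=1, keepdims=True)).max() < 1e-6


class TestDipoleMultiplicativeUpdate:
    def test_recovers_nonnegative_truth_without_penalties(self, rng):
        # well-conditioned R, x_true >= 0, no regularization
        n, t = 10, 4
        R = np.eye(n) + 0.1 * rng.normal(size=(n, n))
        X_true = rng.uniform(0.5, 2.0, size=(n, t))
        Y = R @ X_true
        res = solve_stre_dipole_mu(R, Y, np.zeros((n, n)), 0.0, 0.0, 1,
                                   max_iter=20000, tol=1e-14)
        assert np.linalg.norm(res.x - X_true) / np.linalg.norm(X_true) < 1e-4

    def test_split_parts_stay_nonnegative(self, rng):
        R, L, Y = random_instance(rng)
        res = solve_stre_dipole_mu(R, Y, L, 0.1, 0.2, 2, max_iter=50)
        assert (res.x_pos >= 0).all() and (res.x_neg >= 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_monotone_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        R, L, Y = random_instance(rng)
        res = solve_stre_dipole_mu(R, Y, L, 0.05, 0.3, 2, init_seed=seed,
                                   max_iter=300, tol=0.0)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-9 * np.abs(res.objective_trace[:-1]) + 1e-12).all()

    def test_solution_matches_direct_oracle(self, rng):
        R, L, Y = random_instance(rng, n=15, t=8)
        Xd = solve_stre_direct(R, Y, L, 0.1, 0.3, 2)
        res = solve_stre_dipole_mu(R, Y, L, 0.1, 0.3, 2, max_iter=30000,
                                   tol=1e-14)
        assert np.linalg.norm(res.x - Xd) / np.linalg.norm(Xd) < 1e-5

    def test_init_seed_only_affects_iteration_count(self, rng):
        R, L, Y = random_instance(rng)
        a = solve_stre_dipole_mu(R, Y, L, 0.1, 0.3, 2, init_seed=0,
                                 max_iter=30000, tol=1e-14)
        b = solve_stre_dipole_mu(R, Y, L, 0.1, 0.3, 2, init_seed=99,
                                 max_iter=30000, tol=1e-14)
        assert np.linalg.norm(a.x - b.x) / np.linalg.norm(a.x) < 1e-4

    def test_node_relabeling_invariance(self, rng):
        R, L, Y = random_instance(rng)
        perm = rng.permutation(12)
        X = solve_stre_dipole_mu(R, Y, L, 0.1, 0.3, 2, max_iter=20000,
                                 tol=1e-13).x
        Xp = solve_stre_dipole_mu(R[:, perm], Y, L[np.ix_(perm, perm)],
                                  0.1, 0.3, 2, max_iter=20000, tol=1e-13).x
        assert np.linalg.norm(Xp - X[perm]) / np.linalg.norm(X) < 1e-4


class TestEstimators:
    def test_sklearn_params_round_trip(self):
        est = STREInverse(lambda_s=0.1, lambda_t=0.2, window=3)
        params = est.get_params()
        assert params["lambda_s"] == 0.1
        est.set_params(lambda_s=0.9)
        assert est.lambda_s == 0.9

    def test_fit_predict_shapes(self, rng):
        R, L, Y = random_instance(rng)
        est = STREInverse(lambda_s=0.1, lambda_t=0.2, window=2,
                          laplacian=L).fit(R, Y)
        assert est.X_.shape == Y.shape
        assert est.predict().shape == Y.shape
        tik = TikhonovInverse(lam=0.1).fit(R, Y)
        l1 = L1Inverse(lam=0.1, operator=np.eye(12), max_iter=50).fit(R, Y)
        assert tik.X_.shape == Y.shape and l1.X_.shape == Y.shape

    def test_mu_and_direct_estimators_agree(self, rng):
        R, L, Y = random_instance(rng)
        kw = dict(lambda_s=0.1, lambda_t=0.2, window=2, laplacian=L)
        d = STREInverse(method="direct", **kw).fit(R, Y)
        m = STREInverse(method="mu", max_iter=30000, tol=1e-14, **kw).fit(R, Y)
        assert np.linalg.norm(d.X_ - m.X_) / np.linalg.norm(d.X_) < 1e-5

    def test_shape_mismatch_rejected(self, rng):
        R, L, Y = random_instance(rng)
        with pytest.raises(ValueError, match="rows"):
            TikhonovInverse().fit(R, Y[:5])
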