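"""HB-PLS component extraction, deflation, accumulation, and full fits."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from hbpls.losses import berhu_value, default_shape_parameter, huber_value
from hbpls.pls import (
    accumulate,
    cross_product,
    deflate,
    extract_component,
    fit_hb_pls,
    initialize_weights,
    inner_objective,
    load_model,
    save_model,
    solve_weights,
    standardize,
    update_u,
    update_v,
)


def angle_deg(x, ref):
    c = abs(x @ ref) / (np.linalg.norm(x) * np.linalg.norm(ref))
    return np.degrees(np.arccos(min(1.0, c)))


class TestStandardize:
    def test_idempotent_on_standardized_input(self, rng):
        X = rng.standard_normal((30, 4))
        X = (X - X.mean(0)) / X.std(0)
        Y = rng.standard_normal((30, 2))
        Y = (Y - Y.mean(0)) / Y.std(0)
        Xs, Ys, _ = standardize(X, Y)
        np.testing.assert_allclose(Xs, X, atol=1e-12)
        np.testing.assert_allclose(Ys, Y, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0
        with pytest.warns(RuntimeWarning, match="constant"):
            Xs, _, scaler = standardize(X, rng.standard_normal((20, 2)))
        assert Xs.shape[1] == 2
        np.testing.assert_array_equal(scaler.x_kept, [True, False, True])

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            standardize(np.ones((10, 2)), np.random.default_rng(0).standard_normal((10, 2)))

    def test_round_trip_back_transform(self, rng):
        Y = 5 + 3 * rng.standard_normal((25, 3))
        _, Ys, scaler = standardize(rng.standard_normal((25, 2)), Y)
        np.testing.assert_allclose(scaler.inverse_transform_y(Ys), Y, atol=1e-10)


class TestCrossProduct:
    def test_hand_computed_toy_product(self):
        Xs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        Ys = np.array([[2.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(cross_product(Xs, Ys), Xs.T @ Ys)

    def test_gram_matrix_is_psd(self, rng):
        X = rng.standard_normal((20, 5))
        G = cross_product(X, X)
        np.testing.assert_allclose(G, G.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(G) > -1e-10)

    def test_orthogonal_columns_give_zero_entries(self):
        Xs = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        Ys = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        assert cross_product(Xs, Ys)[0, 0] == 0.0

    def test_sample_mismatch(self):
        with pytest.raises(ValueError):
            cross_product(np.ones((3, 2)), np.ones((4, 2)))


class TestInitializeWeights:
    def test_rank_one_matrix_recovers_factors(self, rng):
        a = rng.standard_normal(6)
        a /= np.linalg.norm(a)
        b = rng.standard_normal(3) * 2
        u, v = initialize_weights(np.outer(a, b))
        assert angle_deg(u, a) < 1e-6
        assert angle_deg(v, b) < 1e-6
        assert np.linalg.norm(u) == pytest.approx(1.0)
        # v carries the singular value: u v' reconstructs the matrix
        np.testing.assert_allclose(np.outer(u, v), np.outer(a, b), atol=1e-10)

    def test_sign_convention(self, rng):
        Mmat = rng.standard_normal((5, 4))
        u, _ = initialize_weights(Mmat)
        assert u[np.argmax(np.abs(u))] > 0

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            initialize_weights(np.zeros((3, 2)))


class TestWeightUpdates:
    def test_huge_lambda_shrinks_u_to_zero(self, rng):
        Mmat = rng.standard_normal((6, 4))
        u, v = initialize_weights(Mmat)
        u_new, _ = update_u(Mmat, u, v, lam=1e9, M=0.5)
        np.testing.assert_array_equal(u_new, 0.0)

    def test_scalar_case_matches_per_coordinate_minimizer(self):
        # p = q = 1: repeated prox steps must reach the 1-D optimum of
        # H(m - u v) + lam B(u), found independently by bracketed search
        m, v, lam, M = 3.0, 1.5, 0.8, 0.6
        Mmat = np.array([[m]])
        u = np.array([0.0])
        t = 1.0
        for _ in range(500):
            u, t = update_u(Mmat, u, np.array([v]), lam, M, t)
        res = minimize_scalar(
            lambda z: huber_value(m - z * v, M) + lam * berhu_value(z, M),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert u[0] == pytest.approx(res.x, abs=1e-5)

    def test_fixed_point_is_stable(self, rng):
        # run to convergence, then one more step must not move u (within tol)
        Mmat = rng.standard_normal((8, 5))
        M = default_shape_parameter(Mmat.ravel())
        u, v, _, conv = solve_weights(Mmat, lam=0.3, M=M, inner_max_iter=5000)
        assert conv
        u2, _ = update_u(Mmat, u, v, 0.3, M, 1.0)
        assert np.linalg.norm(u2 - u) <= 1e-3 * max(np.linalg.norm(u), 1.0)

    def test_update_v_mirrors_update_u(self, rng):
        Mmat = rng.standard_normal((4, 6))
        u, v = initialize_weights(Mmat)
        v_new, _ = update_v(Mmat, u, v, lam=1e9, M=0.5)
        np.testing.assert_array_equal(v_new, 0.0)
        # transposing the problem swaps the roles of u and v exactly
        v_mirror, _ = update_u(Mmat.T, v, u, lam=0.2, M=0.5, t=1.0)
        v_direct, _ = update_v(Mmat, u, v, lam=0.2, M=0.5, t=1.0)
        np.testing.assert_allclose(v_mirror, v_direct, atol=1e-12)


class TestExtractComponent:
    def test_svd_limit(self, rng):
        X = rng.standard_normal((60, 12))
        Y = X[:, :3] @ rng.standard_normal((3, 4)) + 0.1 * rng.standard_normal((60, 4))
        Xs, Ys, _ = standardize(X, Y)
        Mmat = cross_product(Xs, Ys)
        comp = extract_component(Xs, Ys, lam=0.0, M=1e6 * np.abs(Mmat).max())
        U = np.linalg.svd(Mmat)[0]
        assert angle_deg(comp.u, U[:, 0]) < np.degrees(1e-3)

    def test_over_penalized_component_rejected(self, rng):
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 3))
        Xs, Ys, _ = standardize(X, Y)
        assert extract_component(Xs, Ys, lam=1e12) is None

    def test_robust_to_gross_outlier_cells(self):
        # planted rank-1 cross-product with 5% cells replaced by gross
        # outliers at 50x the cell-noise scale: the Huber fit recovers the
        # planted direction far better than the plain SVD
        r = np.random.default_rng(7)
        p, q = 40, 8
        a = r.standard_normal(p)
        a /= np.linalg.norm(a)
        b = r.standard_normal(q) * 3
        S = np.outer(a, b)
        noise_sd = 0.05 * np.abs(S).mean()
        Mmat = S + noise_sd * r.standard_normal((p, q))
        mask = r.random((p, q)) < 0.05
        Mmat[mask] = 50 * noise_sd * r.choice([-1.0, 1.0], mask.sum())
        u_hb, _, _, _ = solve_weights(Mmat, lam=0.0, inner_max_iter=2000)
        u_svd = np.linalg.svd(Mmat)[0][:, 0]
        assert angle_deg(u_hb, a) < angle_deg(u_svd, a)

    def test_inner_objective_nonincreasing_across_alternations(self, rng):
        Mmat = rng.standard_normal((10, 6)) * 2
        M = default_shape_parameter(Mmat.ravel())
        lam = 0.5
        u, v = initialize_weights(Mmat)
        t_u = t_v = 1.0
        prev = inner_objective(Mmat, u, v, lam, M)
        for _ in range(50):
            u, t_u = update_u(Mmat, u, v, lam, M, t_u)
            v, t_v = update_v(Mmat, u, v, lam, M, t_v)
            cur = inner_objective(Mmat, u, v, lam, M)
            assert cur <= prev + 1e-10
            prev = cur


class TestAccumulateDeflate:
    def test_first_component_gives_rank_one_A(self, rng):
        p, q = 5, 3
        u, c, d = rng.standard_normal(p), rng.standard_normal(p), rng.standard_normal(q)
        A, cF = accumulate(np.zeros((p, q)), np.eye(p), u, c, d)
        np.testing.assert_allclose(A, np.outer(u, d))
        np.testing.assert_allclose(cF, np.eye(p) - np.outer(u, c))

    def test_zero_u_leaves_everything_unchanged(self, rng):
        p, q = 4, 2
        A0 = rng.standard_normal((p, q))
        A, cF = accumulate(A0, np.eye(p), np.zeros(p), rng.standard_normal(p), rng.standard_normal(q))
        np.testing.assert_allclose(A, A0)
        np.testing.assert_allclose(cF, np.eye(p))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            accumulate(np.zeros((3, 2)), np.eye(4), np.zeros(3), np.zeros(3), np.zeros(2))

    def test_deflation_orthogonalizes_score(self, rng):
        X = rng.standard_normal((40, 8))
        Y = rng.standard_normal((40, 3))
        Xs, Ys, _ = standardize(X, Y)
        comp = extract_component(Xs, Ys, lam=0.1)
        Xd, Yd = deflate(Xs, Ys, comp)
        assert np.max(np.abs(comp.xi @ Xd)) < 1e-8
        # idempotent: deflating again with the same component changes nothing
        Xd2, Yd2 = deflate(Xd, Yd, comp)
        np.testing.assert_allclose(Xd2, Xd, atol=1e-10)

    def test_rank_one_X_fully_explained(self, rng):
        xi = rng.standard_normal(30)
        c = rng.standard_normal(4)
        X = np.outer(xi, c)
        Y = np.outer(xi, rng.standard_normal(2))
        Xs, Ys, _ = standardize(X, Y)
        comp = extract_component(Xs, Ys, lam=0.0, M=1e6 * np.abs(cross_product(Xs, Ys)).max())
        Xd, _ = deflate(Xs, Ys, comp)
        assert np.linalg.norm(Xd) < 1e-6 * np.linalg.norm(Xs)


class TestFitHBPLS:
    def test_scores_mutually_orthogonal(self, rng):
        X = rng.standard_normal((50, 10))
        Y = X[:, :4] @ rng.standard_normal((4, 3)) + 0.2 * rng.standard_normal((50, 3))
        m = fit_hb_pls(X, Y, lam=0.3, K=3)
        xis = np.array([c.xi for c in m.components])
        G = xis @ xis.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(G))

    def test_A_reproduces_score_space_predictions(self, rng):
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 3))
        m = fit_hb_pls(X, Y, lam=0.2, K=3)
        Xs, Ys, _ = standardize(X, Y)
        direct = Xs @ m.A
        seq = sum(np.outer(c.xi, c.d) for c in m.components)
        assert np.linalg.norm(direct - seq) <= 1e-6 * np.linalg.norm(Ys)

    def test_pls_limit_matches_reference_pls_predictions(self, rng):
        # lam = 0, huge shape parameter: HB-PLS is ordinary PLS; compare
        # predictions against an independent NIPALS implementation (sklearn)
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((60, 8))
        Y = X[:, :3] @ rng.standard_normal((3, 4)) + 0.1 * rng.standard_normal((60, 4))
        K = 4
        m = fit_hb_pls(X, Y, lam=0.0, K=K, M=1e9)
        ref = PLSRegression(n_components=K, scale=True).fit(X, Y)
        mine = m.predict(X)
        theirs = ref.predict(X)
        denom = np.linalg.norm(Y - Y.mean(0))
        assert np.linalg.norm(mine - theirs) <= 1e-3 * denom

    def test_planted_regulators_have_largest_rows(self, planted_dataset):
        from hbpls.model_selection import pls_lambda_max

        d = planted_dataset
        X, Y = d.X.to_numpy(), d.Y.to_numpy()
        lam = pls_lambda_max(X, Y) / 200
        m = fit_hb_pls(X, Y, lam, K=3, tf_ids=list(d.X.columns), gene_ids=list(d.Y.columns))
        row_norms = np.abs(m.A).sum(axis=1)
        top10 = {m.tf_ids[j] for j in np.argsort(-row_norms)[:10]}
        # correlated block-mates of true regulators may interleave, but all
        # planted regulators must dominate the 97 decoys
        assert set(d.true_regulators) <= top10

    def test_single_response_sign_consistent(self, rng):
        X = rng.standard_normal((80, 10))
        beta = np.zeros(10)
        beta[2] = 2.0  # single positive planted effect
        Y = (X @ beta + 0.3 * rng.standard_normal(80)).reshape(-1, 1)
        m = fit_hb_pls(X, Y, lam=0.5, K=1)
        j = int(np.argmax(np.abs(m.A[:, 0])))
        assert j == 2 and m.A[j, 0] > 0

    def test_sparsity_nondecreasing_in_lambda_on_average(self):
        frac_lo, frac_hi = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 12))
            Y = X[:, :2] @ r.standard_normal((2, 3)) + r.standard_normal((40, 3))
            Xs, Ys, _ = standardize(X, Y)
            Mmat = cross_product(Xs, Ys)
            from hbpls.model_selection import pls_lambda_max

            lmax = pls_lambda_max(X, Y)
            for lam, acc in ((lmax / 100, frac_lo), (lmax / 10, frac_hi)):
                u, _, _, _ = solve_weights(Mmat, lam=lam)
                acc.append(np.mean(u == 0.0))
        assert np.mean(frac_hi) >= np.mean(frac_lo)

    def test_component_rejection_truncates_with_warning(self, rng):
        # Y is exactly rank one in a combination of X columns, so after one
        # component the residual cross-product is tiny and any moderate
        # penalty rejects the second component
        X = rng.standard_normal((40, 6))
        w = rng.standard_normal(6)
        Y = np.outer(X @ w, rng.standard_normal(3))
        from hbpls.model_selection import pls_lambda_max

        lam = pls_lambda_max(X, Y) / 50
        with pytest.warns(RuntimeWarning, match="rejected"):
            m = fit_hb_pls(X, Y, lam, K=3)
        assert 1 <= m.n_components < 3

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 2))
        m = fit_hb_pls(X, Y, lam=0.1, K=2, tf_ids=list("abcde"), gene_ids=["g1", "g2"])
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_allclose(m2.A, m.A)
        assert m2.tf_ids == m.tf_ids and m2.K == m.K
        np.testing.assert_allclose(m2.predict(X), m.predict(X))
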