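"""PLSR/SVR calibration: oracle equivalence, selection procedures, contracts."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold

import phycospec as ps
from phycospec.calibration import (
    DEFAULT_C_GRID,
    DEFAULT_G_GRID,
    plsr_predict_factor_form,
)
from phycospec.errors import (
    ConvergenceError,
    DegenerateTargetError,
    InvalidArgumentError,
)
from phycospec.preprocess import make_preset

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def nipals_oracle_predict(X, y, n_comp, X_new):
    """Textbook NIPALS PLS1 with unit-normalized scores (an independently
    coded variant of the algorithm); returns predictions for X_new."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm, ym = X.mean(0), y.mean()
    E, f = X - xm, y - ym
    weights, loadings, q_list, t_norms = [], [], [], []
    for _ in range(n_comp):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t_raw = E @ w
        t_norm = np.linalg.norm(t_raw)
        t = t_raw / t_norm
        p = E.T @ t
        q = f @ t
        E = E - np.outer(t, p)
        f = f - q * t
        weights.append(w), loadings.append(p), q_list.append(q), t_norms.append(t_norm)
    En = np.atleast_2d(X_new) - xm
    yhat = np.full(En.shape[0], ym)
    for w, p, q, tn in zip(weights, loadings, q_list, t_norms):
        t_new = En @ w / tn
        En = En - np.outer(t_new, p)
        yhat = yhat + q * t_new
    return yhat


def solve_svr_dual_qp(K, ys, C, eps):
    """Generic QP solve of the epsilon-SVR dual (SLSQP on [alpha; alpha*]).

    Returns (beta, bias, dual_objective); bias from the free-SV KKT
    conditions.
    """
    n = ys.size

    def neg_dual(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + eps * z.sum() - ys @ beta

    def jac(z):
        beta = z[:n] - z[n:]
        Kb = K @ beta
        return np.concatenate([Kb + eps - ys, -Kb + eps + ys])

    res = minimize(
        neg_dual,
        np.zeros(2 * n),
        jac=jac,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[{"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum()}],
        method="SLSQP",
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    assert res.success
    beta = res.x[:n] - res.x[n:]
    free = np.where((np.abs(beta) > 1e-6) & (np.abs(beta) < C - 1e-6))[0]
    assert free.size > 0, "oracle problem should have free support vectors"
    Kb = K @ beta
    bias = float(np.mean([ys[i] - Kb[i] - np.sign(beta[i]) * eps for i in free]))
    return beta, bias, -res.fun


@pytest.fixture(scope="module")
def problem_12x5():
    rng = np.random.default_rng(99)
    X = rng.normal(size=(12, 5))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(0, 0.1, 12)
    return X, y


@pytest.fixture(scope="module")
def svr_6pt():
    rng = np.random.default_rng(42)
    X = np.linspace(-1, 1, 6).reshape(-1, 1) + rng.normal(0, 0.05, size=(6, 1))
    y = np.sin(1.5 * X[:, 0]) + rng.normal(0, 0.05, 6)
    return X, y


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------


class TestSplit:
    def test_default_96_gives_79_17(self, lab_samples):
        train, test = ps.split_train_test(lab_samples, seed=0)
        assert (train.n, test.n) == (79, 17)
        assert train.split_tag == "train" and test.split_tag == "test"

    def test_partition_law(self, lab_samples):
        a_tr, a_te = ps.split_train_test(lab_samples, seed=5)
        b_tr, b_te = ps.split_train_test(lab_samples, seed=5)
        assert a_tr.ids == b_tr.ids and a_te.ids == b_te.ids
        assert set(a_tr.ids) | set(a_te.ids) == set(lab_samples.ids)
        assert set(a_tr.ids) & set(a_te.ids) == set()
        c_tr, _ = ps.split_train_test(lab_samples, seed=6)
        assert c_tr.ids != a_tr.ids

    def test_boundary_split(self, noiseless_small_samples):
        train, test = ps.split_train_test(
            noiseless_small_samples, n_test=noiseless_small_samples.n - 1
        )
        assert train.n == 1

    def test_out_of_range_rejected(self, noiseless_small_samples):
        n = noiseless_small_samples.n
        for bad in (0, n):
            with pytest.raises(InvalidArgumentError):
                ps.split_train_test(noiseless_small_samples, n_test=bad)


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


class TestPLSR:
    def test_rank_one_exact_recovery(self):
        # orthogonal design: the single informative band is uncorrelated with
        # the rest, so one latent variable suffices for exact recovery
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 6))
        A -= A.mean(axis=0)
        X, _ = np.linalg.qr(A)  # centered orthonormal columns
        y = 3.0 * X[:, 2] + 1.0
        model = ps.plsr_fit(X, y, 1)
        np.testing.assert_allclose(ps.plsr_predict(model, X), y, atol=1e-8)

    def test_equals_ols_at_full_rank(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.2, 30)
        model = ps.plsr_fit(X, y, 5)
        Xc = np.column_stack([np.ones(30), X])
        ols = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(model.coef, ols[1:], rtol=1e-6)
        np.testing.assert_allclose(model.intercept, ols[0], rtol=1e-6)

    def test_matches_nipals_oracle(self, problem_12x5):
        X, y = problem_12x5
        model = ps.plsr_fit(X, y, 2)
        expected = nipals_oracle_predict(X, y, 2, X)
        np.testing.assert_allclose(ps.plsr_predict(model, X), expected, atol=1e-8)

    def test_matches_sklearn_cross_check(self, problem_12x5):
        from sklearn.cross_decomposition import PLSRegression

        X, y = problem_12x5
        model = ps.plsr_fit(X, y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ps.plsr_predict(model, X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_factor_and_vector_forms_agree(self, problem_12x5):
        X, y = problem_12x5
        model = ps.plsr_fit(X, y, 4)
        np.testing.assert_allclose(
            ps.plsr_predict(model, X), plsr_predict_factor_form(model, X), atol=1e-8
        )

    def test_predicting_train_mean_gives_y_center(self, problem_12x5):
        X, y = problem_12x5
        model = ps.plsr_fit(X, y, 3)
        pred = ps.plsr_predict(model, X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_prediction_is_affine(self, problem_12x5):
        X, y = problem_12x5
        model = ps.plsr_fit(X, y, 3)
        x1, x2, alpha = X[0], X[5], 0.3
        mix = ps.plsr_predict(model, (alpha * x1 + (1 - alpha) * x2)[None, :])[0]
        parts = ps.plsr_predict(model, np.vstack([x1, x2]))
        assert mix == pytest.approx(alpha * parts[0] + (1 - alpha) * parts[1], abs=1e-10)

    def test_training_rmse_non_increasing_in_n_lv(self, problem_12x5):
        X, y = problem_12x5
        errs = []
        for k in range(1, 6):
            model = ps.plsr_fit(X, y, k)
            errs.append(np.sqrt(np.mean((ps.plsr_predict(model, X) - y) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_invalid_arguments(self, problem_12x5):
        X, y = problem_12x5
        with pytest.raises(InvalidArgumentError):
            ps.plsr_fit(X, y, 12)  # > n-1
        with pytest.raises(DegenerateTargetError):
            ps.plsr_fit(X, np.ones(12), 2)


class TestLOOCV:
    def test_matches_bruteforce_refit(self, problem_12x5):
        X, y = problem_12x5
        best, curve = ps.select_n_lv_loocv(X, y, max_lv=5)
        n = X.shape[0]
        cap = curve.size
        preds = np.empty((n, cap))
        for i in range(n):
            keep = np.arange(n) != i
            for k in range(1, cap + 1):
                m = ps.plsr_fit(X[keep], y[keep], k)
                preds[i, k - 1] = ps.plsr_predict(m, X[i][None, :])[0]
        expected = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        np.testing.assert_allclose(curve, expected, atol=1e-10)
        assert best == int(np.argmin(expected)) + 1

    def test_bruteforce_with_fold_preprocessing(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 12)) + 0.2
        y = X[:, 4] * 2 + rng.normal(0, 0.05, 10)
        spec = make_preset("sg_standardize")
        best, curve = ps.select_n_lv_loocv(X, y, max_lv=3, preprocess=spec)
        n = X.shape[0]
        preds = np.empty((n, curve.size))
        for i in range(n):
            keep = np.arange(n) != i
            for k in range(1, curve.size + 1):
                pipe = make_preset("sg_standardize")
                Xt = pipe.fit_transform(X[keep])
                m = ps.plsr_fit(Xt, y[keep], k)
                preds[i, k - 1] = ps.plsr_predict(m, pipe.transform(X[i][None, :]))[0]
        expected = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        np.testing.assert_allclose(curve, expected, atol=1e-10)

    def test_exact_rank_limit(self):
        rng = np.random.default_rng(4)
        basis = rng.normal(size=(3, 20))
        scores = rng.normal(size=(15, 3))
        X = scores @ basis
        y = scores @ np.array([1.0, -1.0, 2.0])  # exactly rank-3 signal
        best, curve = ps.select_n_lv_loocv(X, y, max_lv=6)
        assert best <= 3
        assert curve[2] < 1e-8
        assert curve[0] >= curve[1] >= curve[2]

    def test_candidate_cap(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 100))
        y = rng.normal(size=20)
        _, curve = ps.select_n_lv_loocv(X, y, max_lv=50)
        assert curve.size == 18  # min(50, n-2, B)
        _, curve5 = ps.select_n_lv_loocv(X, y, max_lv=5)
        assert curve5.size == 5


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------


class TestSVR:
    def test_flat_target(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        model = ps.svr_fit(X, np.full(6, 2.5), c=1.0, g=0.5, epsilon=0.1)
        assert model.n_support == 0
        assert model.bias == pytest.approx(2.5)
        np.testing.assert_allclose(ps.svr_predict(model, X), 2.5)

    def test_matches_qp_oracle(self, svr_6pt):
        X, y = svr_6pt
        C, g, eps = 10.0, 0.5, 0.1
        model = ps.svr_fit(X, y, C, g, eps)
        Xs = (X - model.x_center) / model.x_scale
        ys = (y - model.y_center) / model.y_scale
        K = np.exp(-g * cdist(Xs, Xs, "sqeuclidean"))
        beta, bias, obj = solve_svr_dual_qp(K, ys, C, eps)
        pred_oracle = model.y_center + model.y_scale * (K @ beta + bias)
        np.testing.assert_allclose(ps.svr_predict(model, X), pred_oracle, atol=1e-5)
        # dual objective of the libsvm solution matches the QP optimum
        beta_lib = np.zeros(len(y))
        for coef, sv in zip(model.dual_coef, model.support_vectors):
            beta_lib[np.argmin(np.abs(Xs - sv).sum(axis=1))] = coef
        obj_lib = -(
            0.5 * beta_lib @ K @ beta_lib
            + eps * np.abs(beta_lib).sum()
            - ys @ beta_lib
        )
        assert obj_lib == pytest.approx(obj, abs=1e-5)

    def test_kkt_conditions(self, svr_6pt):
        X, y = svr_6pt
        C, g, eps = 10.0, 0.5, 0.1
        model = ps.svr_fit(X, y, C, g, eps)
        assert np.all(np.abs(model.dual_coef) <= C + 1e-9)
        ys = (y - model.y_center) / model.y_scale
        Xs = (X - model.x_center) / model.x_scale
        preds_scaled = (
            np.exp(-g * cdist(Xs, model.support_vectors, "sqeuclidean"))
            @ model.dual_coef
            + model.intercept
        )
        sv_rows = {
            int(np.argmin(np.abs(Xs - sv).sum(axis=1)))
            for sv in model.support_vectors
        }
        for i in range(len(y)):
            resid = abs(ys[i] - preds_scaled[i])
            if i not in sv_rows:  # zero dual coefficient -> inside the tube
                assert resid <= eps + 1e-6
        # free support vectors sit on the tube boundary
        for coef, sv in zip(model.dual_coef, model.support_vectors):
            if 1e-6 < abs(coef) < C - 1e-6:
                i = int(np.argmin(np.abs(Xs - sv).sum(axis=1)))
                assert abs(ys[i] - preds_scaled[i]) == pytest.approx(eps, abs=1e-6)

    def test_duplicating_points_keeps_predictions(self, svr_6pt):
        # C large enough that no dual coefficient sits at the box bound, so
        # the solution function is unique and duplication cannot shift it
        X, y = svr_6pt
        a = ps.svr_fit(X, y, 50.0, 0.5, 0.1)
        b = ps.svr_fit(np.vstack([X, X]), np.concatenate([y, y]), 50.0, 0.5, 0.1)
        np.testing.assert_allclose(
            ps.svr_predict(a, X), ps.svr_predict(b, X), atol=1e-6
        )

    def test_vanishing_gamma_limit(self, svr_6pt):
        X, y = svr_6pt
        model = ps.svr_fit(X, y, 10.0, 1e-12, 0.1)
        preds = ps.svr_predict(model, X)
        assert np.ptp(preds) < 1e-3

    def test_iteration_cap_raises(self, svr_6pt):
        X, y = svr_6pt
        with pytest.raises(ConvergenceError):
            ps.svr_fit(X, y, 10.0, 0.5, 0.0, max_iter=1)

    def test_invalid_arguments(self, svr_6pt):
        X, y = svr_6pt
        for c, g, eps in [(-1, 0.5, 0.1), (1, 0, 0.1), (1, 0.5, -0.1)]:
            with pytest.raises(InvalidArgumentError):
                ps.svr_fit(X, y, c, g, eps)


class TestGridSearch:
    def test_single_pair_grid(self, svr_6pt):
        X, y = svr_6pt
        c, g, table = ps.grid_search_svr(
            X, y, c_grid=[4.0], g_grid=[0.25], k_folds=3
        )
        assert (c, g) == (4.0, 0.25)
        assert len(table) == 1

    def test_cv_table_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 4))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.1, 15)
        c_grid, g_grid = [1.0, 8.0], [0.1, 1.0]
        _, _, table = ps.grid_search_svr(
            X, y, c_grid=c_grid, g_grid=g_grid, k_folds=3, seed=7,
            epsilon=0.1, tol=1e-3, max_iter=100_000,
        )
        kf = KFold(n_splits=3, shuffle=True, random_state=7)
        for _, row in table.iterrows():
            preds = np.empty(len(y))
            for tr, te in kf.split(X):
                m = ps.svr_fit(
                    X[tr], y[tr], row["c"], row["g"], epsilon=0.1,
                    tol=1e-3, max_iter=100_000, strict=False,
                )
                preds[te] = ps.svr_predict(m, X[te])
            expected = np.sqrt(np.mean((preds - y) ** 2))
            assert row["rmse_cv"] == pytest.approx(expected, abs=1e-10)

    def test_default_grids_cover_published_optima(self):
        assert 128.0 in DEFAULT_C_GRID
        assert 2_097_152.0 in DEFAULT_C_GRID  # 2^21
        assert 0.0078125 in DEFAULT_G_GRID  # 2^-7
        assert 2.0**-18 in DEFAULT_G_GRID  # ~3.8147e-6

    def test_tie_breaks_toward_smaller_parameters(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        y = np.full(10, 1.0)
        # constant target: every pair predicts the fold mean -> all RMSE tie
        c, g, table = ps.grid_search_svr(
            X, y, c_grid=[2.0, 1.0], g_grid=[1.0, 0.5], k_folds=2
        )
        assert len(set(table["rmse_cv"])) == 1
        assert (c, g) == (1.0, 0.5)


# ---------------------------------------------------------------------------
# end-to-end per-pigment calibration
# ---------------------------------------------------------------------------


class TestFitPigmentModel:
    def test_noiseless_plsr_recovers_ground_truth(self, noiseless_small_samples):
        train, test = ps.split_train_test(noiseless_small_samples, seed=0)
        model = ps.fit_pigment_model(train, "pe", "sg_snv", "plsr")
        yhat = model.predict(test.spectra)
        assert ps.r_squared(test.y("pe"), yhat) >= 0.999

    def test_repeat_prediction_identical(self, noiseless_small_samples):
        train, _ = ps.split_train_test(noiseless_small_samples, seed=0)
        model = ps.fit_pigment_model(train, "chla", "sg_d1", "plsr")
        a = model.predict(train.spectra)
        b = model.predict(train.spectra)
        np.testing.assert_array_equal(a, b)

    def test_svr_path_with_small_grids(self, noiseless_small_samples):
        train, test = ps.split_train_test(noiseless_small_samples, seed=0)
        model = ps.fit_pigment_model(
            train, "pe", "sg_snv", "svr",
            c_grid=2.0 ** np.arange(0, 14), g_grid=2.0 ** np.arange(-10, 0),
        )
        assert model.hyperparams["c"] in 2.0 ** np.arange(0, 14)
        yhat = model.predict(test.spectra)
        assert ps.r_squared(test.y("pe"), yhat) > 0.95

    @pytest.mark.parametrize("model_type", ["plsr", "svr"])
    def test_model_archive_round_trip(
        self, tmp_path, noiseless_small_samples, model_type
    ):
        train, test = ps.split_train_test(noiseless_small_samples, seed=0)
        kwargs = {}
        if model_type == "svr":
            kwargs = {"c_grid": [8.0], "g_grid": [0.01]}
        model = ps.fit_pigment_model(train, "pc", "msc", model_type, **kwargs)
        path = tmp_path / "model.json"
        model.save(path)
        back = ps.CalibrationModel.load(path)
        np.testing.assert_allclose(
            back.predict(test.spectra), model.predict(test.spectra), atol=1e-12
        )
        assert back.hyperparams == model.hyperparams
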