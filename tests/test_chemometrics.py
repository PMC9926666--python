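import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eemferm.alignment import RegressionDataset
from eemferm.chemometrics import (
    LVScanResult,
    PLSModel,
    lv_scan,
    pca_fit,
    pls_apply,
    predict_trajectories,
    relative_rmse,
    rmse,
    select_n_lv,
    simpls_fit,
)
from eemferm.data_model import CultureCondition, EEMGrid, EEMeasurement, SpectrumSeries
from eemferm.preprocess import FeatureIndex

from .oracles import nipals_pls1, pca_eig


class TestSimpls:
    def test_exact_linear_recovery_at_full_rank(self, rng):
        X = rng.normal(size=(30, 5))
        b = rng.normal(size=5)
        y = X @ b
        model = simpls_fit(X, y, 5)
        resid = pls_apply(model, X) - y
        assert np.max(np.abs(resid)) < 1e-10

    def test_matches_nipals_at_every_lv(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        for n_lv in range(1, 8):
            model = simpls_fit(X, y, n_lv)
            B = nipals_pls1(X, y, n_lv)
            yhat_nipals = (X - X.mean(axis=0)) @ B + y.mean()
            assert np.max(np.abs(pls_apply(model, X) - yhat_nipals)) < 1e-8

    def test_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        for n_lv in (1, 3, 5):
            ours = pls_apply(simpls_fit(X, y, n_lv), X)
            ref = sklearn.PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            assert np.max(np.abs(ours - ref.predict(X).ravel())) < 1e-8

    @pytest.mark.parametrize("shape", [(20, 8), (6, 10)])
    def test_full_rank_equals_minimum_norm_least_squares(self, shape, rng):
        X = rng.normal(size=shape)
        y = rng.normal(size=shape[0])
        X0 = X - X.mean(axis=0)
        max_lv = min(shape[0] - 1, np.linalg.matrix_rank(X0))
        model = simpls_fit(X, y, max_lv)
        coef_ls = np.linalg.pinv(X0) @ (y - y.mean())
        assert np.max(np.abs(model.coef - coef_ls)) < 1e-8

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(40, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=40)
        model = simpls_fit(X, y, 6)
        T = (X - model.x_mean) @ model.weights
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_coef_identity(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = simpls_fit(X, y, 3)
        assert np.allclose(model.coef, model.weights @ model.y_loadings)

    def test_rank_exhaustion_reports_usable_maximum(self, rng):
        X = np.column_stack([rng.normal(size=10)] * 4)  # rank 1
        y = X[:, 0].copy()
        with pytest.raises(ValueError, match="usable maximum is 1"):
            simpls_fit(X, y, 3)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            simpls_fit(rng.normal(size=(10, 3)), np.ones(10), 1)

    def test_training_rmse_monotone_in_lv(self, rng):
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + 0.3 * rng.normal(size=30)
        errs = [
            rmse(y, pls_apply(simpls_fit(X, y, a), X)) for a in range(1, 9)
        ]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_simpls_nipals_prediction_equivalence_property(seed):
    """SIMPLS and NIPALS PLS1 give identical predictions for univariate y."""
    rng = np.random.default_rng(seed)
    n, p = rng.integers(6, 25), rng.integers(2, 12)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    n_lv = int(min(n - 2, p, 1 + rng.integers(0, 5)))
    model = simpls_fit(X, y, n_lv)
    B = nipals_pls1(X, y, n_lv)
    yhat = (X - X.mean(axis=0)) @ B + y.mean()
    assert np.max(np.abs(pls_apply(model, X) - yhat)) < 1e-8


class TestPlsApply:
    def test_row_at_center_predicts_mean(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = simpls_fit(X, y, 2)
        assert abs(pls_apply(model, model.x_mean[None, :])[0] - model.y_mean) < 1e-12

    def test_negative_predictions_pass_through(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 0] * 10.0  # spans negative values under extrapolation
        model = simpls_fit(X, y, 1)
        probe = model.x_mean - 50.0 * np.std(X, axis=0)
        assert pls_apply(model, probe[None, :])[0] < 0

    def test_feature_mismatch_rejected(self, rng):
        model = simpls_fit(rng.normal(size=(10, 4)), rng.normal(size=10), 1)
        with pytest.raises(ValueError, match="feature count"):
            pls_apply(model, np.zeros((2, 5)))


class TestPca:
    def test_rank_one_explains_everything(self, rng):
        u = rng.normal(size=15)
        v = rng.normal(size=6)
        X = np.outer(u, v)
        model = pca_fit(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(15, 6))
        model = pca_fit(X, 4)
        evr, V = pca_eig(X, 4)
        assert np.max(np.abs(model.explained_variance_ratio - evr)) < 1e-8
        for k in range(4):  # loadings equal up to sign
            dot = abs(model.loadings[:, k] @ V[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal_and_variance_ordered(self, rng):
        X = rng.normal(size=(30, 8))
        model = pca_fit(X, 5)
        G = model.loadings.T @ model.loadings
        assert np.max(np.abs(G - np.eye(5))) < 1e-10
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-15)
        assert np.all((evr >= 0) & (evr <= 1)) and evr.sum() <= 1 + 1e-12

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(10, 6))
        model = pca_fit(X, 6)
        recon = model.mean + model.scores @ model.loadings.T
        assert np.max(np.abs(recon - X)) < 1e-8 * np.max(np.abs(X))

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(12, 5))
        m1, m2 = pca_fit(X, 3), pca_fit(X.copy(), 3)
        assert np.array_equal(m1.loadings, m2.loadings)
        for k in range(3):
            j = np.argmax(np.abs(m1.loadings[:, k]))
            assert m1.loadings[j, k] > 0

    def test_n_pc_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(5, 10)), 5)


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert abs(rmse(a, b) - np.sqrt(acc / 50)) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_relative_rmse_scale_invariant(self, rng):
        ref = rng.uniform(0, 12, 30)
        r = 0.57
        assert relative_rmse(r, ref) == pytest.approx(relative_rmse(3 * r, 3 * ref))

    def test_relative_rmse_full_range_is_100pct(self):
        ref = np.array([0.0, 11.98])
        assert relative_rmse(11.98, ref) == pytest.approx(100.0)

    def test_relative_rmse_zero_range_rejected(self):
        with pytest.raises(ValueError):
            relative_rmse(1.0, np.ones(5))


def _mini_dataset(X, y, conditions, index):
    n = X.shape[0]
    meta = pd.DataFrame(
        {"well": ["W"] * n, "condition": conditions, "time": np.arange(n, dtype=float)}
    )
    return RegressionDataset(
        X=X, y=y, meta=meta, parameter="glycerol", schedule="full", feature_index=index
    )


def _index(p):
    return FeatureIndex(
        ex_nm=np.arange(p, dtype=float),
        em_nm=np.arange(p, dtype=float),
        grid_shape=(1, p),
        flat_positions=np.arange(p),
    )


class TestLvScan:
    def test_noise_free_curves_hit_zero_at_true_rank(self, rng):
        p, rank = 10, 3
        basis = rng.normal(size=(rank, p))
        def make_X(n):
            return rng.normal(size=(n, rank)) @ basis
        b = rng.normal(size=p)
        Xc, Xp = make_X(30), make_X(20)
        idx = _index(p)
        yc, yp = Xc @ b, Xp @ b
        cal_sparse = _mini_dataset(Xc, yc, ["a"] * 30, idx)
        cal_full = _mini_dataset(Xc, yc, ["a"] * 30, idx)
        pred = _mini_dataset(Xp, yp, ["b"] * 20, idx)
        scan = lv_scan(cal_sparse, cal_full, pred, None, L_max=rank)
        for curve in (
            scan.rmse_cal_sparse,
            scan.rmse_cal_full,
            scan.rmse_pred_full,
            scan.rmse_pred_full_m100,
        ):
            assert curve[rank - 1] < 1e-8

    def test_m100_equals_full_without_supplemented_condition(self, rng):
        p = 6
        idx = _index(p)
        Xc = rng.normal(size=(15, p))
        yc = Xc @ rng.normal(size=p)
        Xp = rng.normal(size=(10, p))
        yp = Xp @ rng.normal(size=p)
        cal = _mini_dataset(Xc, yc, ["a"] * 15, idx)
        pred = _mini_dataset(Xp, yp, ["b"] * 10, idx)
        scan = lv_scan(cal, cal, pred, ["not-present"], L_max=4)
        assert np.array_equal(scan.rmse_pred_full, scan.rmse_pred_full_m100)

    def test_cells_match_independent_recomputation(self, rng):
        p = 8
        idx = _index(p)
        Xc = rng.normal(size=(20, p))
        yc_s = Xc @ rng.normal(size=p) + 0.1 * rng.normal(size=20)
        yc_f = yc_s + 0.05 * rng.normal(size=20)
        Xp = rng.normal(size=(12, p))
        yp = Xp @ rng.normal(size=p)
        conds_p = ["full100"] * 4 + ["low"] * 8
        cal_s = _mini_dataset(Xc, yc_s, ["a"] * 20, idx)
        cal_f = _mini_dataset(Xc, yc_f, ["a"] * 20, idx)
        pred = _mini_dataset(Xp, yp, conds_p, idx)
        scan = lv_scan(cal_s, cal_f, pred, ["full100"], L_max=5)
        for i, a in enumerate(scan.n_lv_values):
            # independent recomputation: fresh fit + plain loop RMSE
            model = simpls_fit(Xc, yc_s, int(a))
            yhat_c = pls_apply(model, Xc)
            yhat_p = pls_apply(model, Xp)
            mask = np.array([c != "full100" for c in conds_p])
            assert abs(scan.rmse_cal_sparse[i] - rmse(yc_s, yhat_c)) < 1e-10
            assert abs(scan.rmse_cal_full[i] - rmse(yc_f, yhat_c)) < 1e-10
            assert abs(scan.rmse_pred_full[i] - rmse(yp, yhat_p)) < 1e-10
            assert abs(scan.rmse_pred_full_m100[i] - rmse(yp[mask], yhat_p[mask])) < 1e-10


def _scan(cal_full, cal_sparse, pred_m100=None):
    L = len(cal_full)
    return LVScanResult(
        n_lv_values=np.arange(1, L + 1),
        rmse_cal_sparse=np.array(cal_sparse, dtype=float),
        rmse_cal_full=np.array(cal_full, dtype=float),
        rmse_pred_full=np.full(L, np.nan),
        rmse_pred_full_m100=np.array(
            pred_m100 if pred_m100 is not None else [np.nan] * L, dtype=float
        ),
    )


class TestSelectNLv:
    def test_divergence_rule_first_index(self):
        n_lv, rule = select_n_lv(_scan(cal_full=(5, 4, 6, 7), cal_sparse=(5, 4, 3, 2)))
        assert (n_lv, rule) == (2, "divergence")

    def test_fallback_to_heldout_minimum(self):
        n_lv, rule = select_n_lv(
            _scan(cal_full=(5, 4, 3, 2), cal_sparse=(5, 4, 3, 2), pred_m100=(4, 3, 2, 2.5))
        )
        assert (n_lv, rule) == (3, "min_pred_m100")

    def test_fallback_tie_prefers_fewer_lvs(self):
        n_lv, rule = select_n_lv(
            _scan(cal_full=(5, 4, 3, 2), cal_sparse=(5, 4, 3, 2), pred_m100=(4, 2, 2, 3))
        )
        assert (n_lv, rule) == (2, "min_pred_m100")


class TestTrajectories:
    def _flat_series(self, tiny_grid, rng):
        from .conftest import make_measurement

        conds = [
            CultureCondition("c1", 1.0, 295.8, 0.06, ["W1"]),
            CultureCondition("blank", 1.0, 295.8, 0.0, ["W9"], "blank"),
        ]
        series = [
            SpectrumSeries(
                "W1",
                [make_measurement(tiny_grid, rng, "W1", t) for t in (0.0, 1.0, 2.0)],
                condition_id="c1",
            ),
            SpectrumSeries(
                "W9",
                [make_measurement(tiny_grid, rng, "W9", t) for t in (0.0, 1.0)],
                condition_id="blank",
            ),
        ]
        return conds, series

    def test_zero_coefficients_give_flat_mean_trajectory(self, tiny_grid, rng):
        conds, series = self._flat_series(tiny_grid, rng)
        p = int(np.prod(tiny_grid.shape))
        model = PLSModel(
            n_lv=1,
            x_mean=np.zeros(p),
            y_mean=3.3,
            weights=np.zeros((p, 1)),
            x_loadings=np.zeros((p, 1)),
            y_loadings=np.zeros(1),
        )
        traj = predict_trajectories(model, series, conds, "cdw")
        assert np.allclose(traj.prediction, 3.3)
        assert set(traj.well) == {"W1"}  # blanks excluded

    def test_trajectory_matches_fitted_values_on_calibration_rows(self, tiny_grid, rng):
        conds, series = self._flat_series(tiny_grid, rng)
        from eemferm.preprocess import unfold_to_features

        X = np.vstack([unfold_to_features(m)[0] for m in series[0].measurements])
        y = np.array([1.0, 2.0, 4.0])
        model = simpls_fit(X, y, 2)
        traj = predict_trajectories(model, series, conds, "cdw")
        fitted = pls_apply(model, X)
        assert np.allclose(traj.prediction.to_numpy(), fitted)
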