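"""From-scratch SIMPLS partial least squares, PCA diagnostics, RMSE metrics,
the latent-variable scan, and the dual-RMSE LV-selection criterion.

The regression core is de Jong's SIMPLS for a univariate response (PLS1):
weight vectors are extracted to maximise covariance between the mean-centred
spectral matrix X and the response y, deflating the cross-product vector
against an orthonormal basis of x-loadings.  Features are mean-centred only,
never variance-scaled: all features share intensity units and autoscaling
would inflate noise-floor pixels.

Model complexity (the LV count) is chosen by the dual-RMSE divergence
criterion: fit on the sparsely interpolated offline schedule and watch the
error against the *densely* interpolated schedule.  The first LV count at
which the sparse calibration error still falls while the full calibration
error rises marks the onset of overfitting to the sparse interpolation
artefacts; one stops there.  If the two curves never diverge, fall back to
the minimum of the held-out prediction error excluding the fully supplemented
condition (which lies outside the calibration span).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import RegressionDataset
from .data_model import CultureCondition, SpectrumSeries
from .preprocess import unfold_to_features

__all__ = [
    "PLSModel",
    "PCAModel",
    "LVScanResult",
    "simpls_fit",
    "pls_apply",
    "pca_fit",
    "rmse",
    "relative_rmse",
    "lv_scan",
    "select_n_lv",
    "predict_trajectories",
]


@dataclass
class PLSModel:
    """Fitted SIMPLS regression state for one offline parameter."""

    n_lv: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    weights: np.ndarray  # (p, n_lv); X-side weight vectors R
    x_loadings: np.ndarray  # (p, n_lv)
    y_loadings: np.ndarray  # (n_lv,)
    parameter: str | None = None

    @property
    def coef(self) -> np.ndarray:
        """Regression vector: coef = R q, so yhat = (X - x_mean) coef + y_mean."""
        return self.weights @ self.y_loadings


@dataclass
class PCAModel:
    """Mean-centred PCA state (SVD-based, deterministic sign convention)."""

    n_pc: int
    mean: np.ndarray
    loadings: np.ndarray  # (p, n_pc), orthonormal columns
    scores: np.ndarray  # (n, n_pc)
    explained_variance_ratio: np.ndarray  # (n_pc,)


@dataclass
class LVScanResult:
    """RMSE curves over LV counts 1..L plus the selected model size."""

    n_lv_values: np.ndarray
    rmse_cal_sparse: np.ndarray
    rmse_cal_full: np.ndarray
    rmse_pred_full: np.ndarray
    rmse_pred_full_m100: np.ndarray
    selected_n_lv: int | None = None
    selection_rule_used: str | None = None  # divergence | min_pred_m100

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "n_lv": self.n_lv_values,
                "rmse_cal_sparse": self.rmse_cal_sparse,
                "rmse_cal_full": self.rmse_cal_full,
                "rmse_pred_full": self.rmse_pred_full,
                "rmse_pred_full_m100": self.rmse_pred_full_m100,
            }
        )
        df["selected"] = df["n_lv"] == self.selected_n_lv
        return df


def simpls_fit(X: np.ndarray, y: np.ndarray, n_lv: int, parameter: str | None = None) -> PLSModel:
    """Fit a univariate-response PLS model with the SIMPLS algorithm.

    X and y are mean-centred internally (no variance scaling).  Weight
    vectors maximise covariance with y; the cross-product vector is deflated
    via an orthonormal basis of the x-loadings, which makes the score vectors
    mutually orthogonal by construction.  Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("X rows and y length disagree")
    if n < 2:
        raise ValueError("need at least two rows")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response; nothing to regress on")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0 = X - x_mean
    y0 = y - y_mean

    s = X0.T @ y0  # cross-product vector, deflated in place
    R = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    V = np.zeros((p, n_lv))  # orthonormal basis of x-loadings
    scale = np.linalg.norm(X0.T @ y0) + np.finfo(float).eps
    for a in range(n_lv):
        r = s.copy()  # univariate response: the dominant direction IS s
        t = X0 @ r
        tnorm = np.linalg.norm(t)
        if tnorm <= 1e-12 * scale:
            raise ValueError(
                f"rank exhausted after {a} latent variables; "
                f"requested {n_lv}, usable maximum is {a}"
            )
        r /= tnorm
        t /= tnorm
        P[:, a] = X0.T @ t
        q[a] = float(y0 @ t)
        R[:, a] = r
        v = P[:, a].copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ v)
        vnorm = np.linalg.norm(v)
        if vnorm <= 1e-14 * (np.linalg.norm(P[:, a]) + np.finfo(float).eps):
            raise ValueError(
                f"loading basis degenerate after {a + 1} latent variables"
            )
        v /= vnorm
        V[:, a] = v
        s = s - v * (v @ s)
    return PLSModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=R,
        x_loadings=P,
        y_loadings=q,
        parameter=parameter,
    )


def pls_apply(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response for new spectra: yhat = (X - x_mean) coef + y_mean.

    Predictions are never clipped to physical bounds: a regression can and
    does produce, say, negative concentrations, and that is reported as-is.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature count {X_new.shape[1]} does not match model ({model.x_mean.size})"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def pca_fit(X: np.ndarray, n_pc: int) -> PCAModel:
    """Mean-centred PCA via SVD.

    Sign convention for reproducibility: each loading's largest-magnitude
    element is made positive (scores flipped accordingly).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two rows")
    if n_pc > min(n - 1, p):
        raise ValueError(f"n_pc {n_pc} exceeds min(rows-1, features) = {min(n - 1, p)}")
    mean = X.mean(axis=0)
    X0 = X - mean
    U, S, Vt = np.linalg.svd(X0, full_matrices=False)
    total = float(np.sum(S**2))
    loadings = Vt[:n_pc].T
    scores = U[:, :n_pc] * S[:n_pc]
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_pc)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    evr = (S[:n_pc] ** 2) / total if total > 0 else np.zeros(n_pc)
    return PCAModel(
        n_pc=n_pc,
        mean=mean,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=evr,
    )


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def relative_rmse(rmse_value: float, y_reference: np.ndarray) -> float:
    """RMSE as a percentage of the measured range of the offline parameter.

    The reference range is max - min over the experiment's *measured* offline
    values for that parameter.
    """
    y_reference = np.asarray(y_reference, dtype=float).ravel()
    rng = float(np.max(y_reference) - np.min(y_reference))
    if rng <= 0:
        raise ValueError("zero range in reference values")
    return 100.0 * float(rmse_value) / rng


def lv_scan(
    cal_sparse: RegressionDataset,
    cal_full: RegressionDataset,
    pred_full: RegressionDataset,
    full_supplementation_condition_ids: list[str] | str | None,
    L_max: int,
) -> LVScanResult:
    """Fit on the sparse calibration data for each LV count and collect four RMSEs.

    Per LV count: rmse_cal_sparse (fit vs the sparse-interpolated y),
    rmse_cal_full (same spectra vs the fully-interpolated y), rmse_pred_full
    (held-out conditions), and rmse_pred_full_m100 (held-out minus the rows of
    the fully supplemented condition(s), which extrapolate beyond the
    calibration span).
    """
    if L_max < 2:
        raise ValueError("L_max must be >= 2")
    if cal_sparse.feature_index != cal_full.feature_index or (
        cal_sparse.feature_index != pred_full.feature_index
    ):
        raise ValueError("datasets do not share one feature index")
    if isinstance(full_supplementation_condition_ids, str):
        full_supplementation_condition_ids = [full_supplementation_condition_ids]
    excl = set(full_supplementation_condition_ids or ())
    keep_m100 = ~pred_full.meta["condition"].isin(excl).to_numpy()

    lvs = np.arange(1, L_max + 1)
    r_cs = np.empty(L_max)
    r_cf = np.empty(L_max)
    r_pf = np.empty(L_max)
    r_pm = np.empty(L_max)
    for i, a in enumerate(lvs):
        model = simpls_fit(cal_sparse.X, cal_sparse.y, int(a), cal_sparse.parameter)
        yhat_cal = pls_apply(model, cal_sparse.X)
        yhat_pred = pls_apply(model, pred_full.X)
        r_cs[i] = rmse(cal_sparse.y, yhat_cal)
        r_cf[i] = rmse(cal_full.y, yhat_cal)
        r_pf[i] = rmse(pred_full.y, yhat_pred)
        r_pm[i] = (
            rmse(pred_full.y[keep_m100], yhat_pred[keep_m100])
            if keep_m100.any()
            else np.nan
        )
    scan = LVScanResult(
        n_lv_values=lvs,
        rmse_cal_sparse=r_cs,
        rmse_cal_full=r_cf,
        rmse_pred_full=r_pf,
        rmse_pred_full_m100=r_pm,
    )
    scan.selected_n_lv, scan.selection_rule_used = select_n_lv(scan)
    return scan


def select_n_lv(scan: LVScanResult) -> tuple[int, str]:
    """Choose the LV count from a scan by the dual-RMSE divergence criterion.

    Divergence rule: the smallest n_lv such that going to n_lv + 1 the full
    calibration RMSE rises while the sparse calibration RMSE still falls —
    the model has started fitting the sparse interpolation rather than the
    underlying spectral dynamics.  If no such index exists, fall back to the
    minimum of rmse_pred_full_m100 (ties toward fewer LVs).
    """
    if scan.n_lv_values.size < 2:
        raise ValueError("scan must cover at least two LV counts")
    cf = scan.rmse_cal_full
    cs = scan.rmse_cal_sparse
    for i in range(scan.n_lv_values.size - 1):
        if cf[i + 1] > cf[i] and cs[i + 1] < cs[i]:
            return int(scan.n_lv_values[i]), "divergence"
    pm = scan.rmse_pred_full_m100
    if np.all(np.isnan(pm)):
        pm = scan.rmse_pred_full
    best = int(np.nanargmin(pm))  # argmin returns the first index: fewer LVs on ties
    return int(scan.n_lv_values[best]), "min_pred_m100"


def predict_trajectories(
    model: PLSModel,
    spectra: list[SpectrumSeries],
    conditions: list[CultureCondition],
    parameter: str,
    t_max_model: float | None = None,
) -> pd.DataFrame:
    """Apply a fitted model to every spectrum of every non-blank well.

    Returns a tidy frame (well, condition, time, parameter, prediction); no
    clipping of out-of-range predictions.
    """
    blank_ids = {c.condition_id for c in conditions if c.role == "blank"}
    rows = []
    for s in sorted(spectra, key=lambda s: (s.condition_id or "", s.well_id)):
        if s.condition_id in blank_ids:
            continue
        for m in s.measurements:
            if t_max_model is not None and m.time > t_max_model + 1e-9:
                continue
            vec, fi = unfold_to_features(m)
            if len(fi) != model.x_mean.size:
                raise ValueError("spectrum feature count does not match model")
            rows.append(
                (
                    s.well_id,
                    s.condition_id,
                    m.time,
                    parameter,
                    float(pls_apply(model, vec[None, :])[0]),
                )
            )
    return pd.DataFrame(
        rows, columns=["well", "condition", "time", "parameter", "prediction"]
    )
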