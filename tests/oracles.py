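"""Independent brute-force / textbook oracles used by the test suite.

These deliberately avoid the package's own code paths: plain loops for
windowed means and pixel counts, NIPALS (not SIMPLS) for PLS1, an explicit
covariance eigendecomposition for PCA.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    """Classic NIPALS PLS1 regression vector B (centered): yhat = (X-mx)B + my."""
    X0 = X - X.mean(axis=0)
    y0 = y - y.mean()
    W = np.zeros((X.shape[1], n_lv))
    P = np.zeros((X.shape[1], n_lv))
    q = np.zeros(n_lv)
    Xd, yd = X0.copy(), y0.copy()
    for a in range(n_lv):
        w = Xd.T @ yd
        w /= np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        qa = (yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * qa
        W[:, a], P[:, a], q[a] = w, p, qa
    return W @ np.linalg.solve(P.T @ W, q)


def moving_average_truncated(row: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Loop implementation of the mask-aware truncated-window moving average."""
    n = row.size
    half = window // 2
    out = row.astype(float).copy()
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals = [row[j] for j in range(lo, hi) if valid[j]]
        if vals:
            out[i] = sum(vals) / len(vals)
    return out


def bin_average(em: np.ndarray, row: np.ndarray, valid: np.ndarray, step: float):
    """Loop implementation of emission bin-averaging from the first wavelength.

    Bins are half-open: [center - step/2, center + step/2).
    """
    n_out = int(np.floor((em[-1] - em[0]) / step + 1e-9)) + 1
    centers = em[0] + step * np.arange(n_out)
    vals = np.zeros(n_out)
    ok = np.zeros(n_out, dtype=bool)
    for k, c in enumerate(centers):
        members = [
            row[j]
            for j in range(em.size)
            if valid[j] and (c - step / 2 - 1e-9) <= em[j] < (c + step / 2 - 1e-9)
        ]
        if members:
            vals[k] = float(np.mean(members))
            ok[k] = True
    return centers, vals, ok


def count_in_band(ex: float, em: np.ndarray, low: float, high: float) -> int:
    """Pixels whose emission offset relative to excitation lies in [low, high]."""
    return sum(1 for e in em if low <= e - ex <= high)


def pca_eig(X: np.ndarray, n_pc: int):
    """PCA via eigendecomposition of the sample covariance: (evr, loadings)."""
    X0 = X - X.mean(axis=0)
    C = X0.T @ X0 / (X.shape[0] - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    total = float(np.trace(C))
    return w[order][:n_pc] / total, V[:, order][:, :n_pc]
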