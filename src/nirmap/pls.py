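"""Single-response NIPALS partial least squares regression and error metrics.

PLS1 projects mean-centred predictors X onto latent components chosen to
maximise covariance with the mean-centred response y.  Each component a is
extracted by the NIPALS recursion

    w_a = X_a' y_a / ||X_a' y_a||        (weights, unit length)
    t_a = X_a w_a                        (scores)
    p_a = X_a' t_a / (t_a' t_a)          (x loadings)
    q_a = y_a' t_a / (t_a' t_a)          (y loading)
    X_{a+1} = X_a - t_a p_a',   y_{a+1} = y_a - q_a t_a

For a single response the inner NIPALS loop converges in one pass, so no
iteration tolerance is involved.  Collapsed regression coefficients are
b_k = W_k (P_k' W_k)^{-1} q_k for each component count k; predictions via the
latent route and the coefficient route agree to numerical precision.

Columns are mean-centred but not variance-scaled, the standard chemometric
convention for spectral predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["PlsModel", "fit_nipals", "predict", "rmse", "spearman_rho"]


@dataclass
class PlsModel:
    """Fitted NIPALS PLS1 model with coefficient paths for all component counts.

    ``coef_path[:, k-1]`` holds the collapsed coefficients using k components,
    so cross-validation over component counts needs a single fit.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # channels x n_comp (W)
    x_loadings: np.ndarray  # channels x n_comp (P)
    y_loadings: np.ndarray  # n_comp (q)
    coef_path: np.ndarray  # channels x n_comp
    n_comp: int

    @property
    def coef(self) -> np.ndarray:
        """Collapsed coefficients at the full component count."""
        return self.coef_path[:, self.n_comp - 1]

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Latent scores T = (X - x_mean) W (P'W)^{-1} for new data."""
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return (np.asarray(X, dtype=float) - self.x_mean) @ R

    def to_json(self, path: str | Path) -> None:
        doc = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef_path": self.coef_path.tolist(),
            "n_comp": self.n_comp,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlsModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["x_mean"]),
            float(d["y_mean"]),
            np.array(d["weights"]),
            np.array(d["x_loadings"]),
            np.array(d["y_loadings"]),
            np.array(d["coef_path"]),
            int(d["n_comp"]),
        )


def fit_nipals(X: np.ndarray, y: np.ndarray, n_comp: int) -> PlsModel:
    """Fit a PLS1 model with ``n_comp`` latent components by NIPALS deflation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X/y contain missing or non-finite values")
    if not 1 <= n_comp <= min(n - 1, p):
        raise ValueError(f"n_comp must be in [1, {min(n - 1, p)}], got {n_comp}")
    if y.std() == 0:
        raise ValueError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean

    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    for a in range(n_comp):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            # residual covariance exhausted; truncate the model here
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_comp = a
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t) / tt
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        Xr -= np.outer(t, p_a)
        yr -= q_a * t
    if n_comp == 0:
        raise ValueError("no extractable component: X'y is zero")

    # coefficient path: b_k = W_k (P_k' W_k)^{-1} q_k ; P'W is unit upper
    # triangular for NIPALS so solve_triangular would also do
    coef_path = np.zeros((p, n_comp))
    PtW = P.T @ W
    for k in range(1, n_comp + 1):
        coef_path[:, k - 1] = W[:, :k] @ np.linalg.solve(PtW[:k, :k], q[:k])

    return PlsModel(x_mean, y_mean, W, P, q, coef_path, n_comp)


def predict(model: PlsModel, X: np.ndarray, n_comp: int | None = None) -> np.ndarray:
    """Predict responses: yhat = (X - x_mean) b_k + y_mean."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"channel mismatch: model has {model.x_mean.size}, X has {X.shape[1]}"
        )
    k = model.n_comp if n_comp is None else n_comp
    if not 1 <= k <= model.n_comp:
        raise ValueError(f"n_comp must be in [1, {model.n_comp}]")
    return (X - model.x_mean) @ model.coef_path[:, k - 1] + model.y_mean


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise ValueError("rmse needs two equal-length vectors of size >= 2")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def spearman_rho(y: np.ndarray, yhat: np.ndarray) -> float:
    """Spearman rank correlation with average ranks on ties."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 3:
        raise ValueError("spearman_rho needs two equal-length vectors of size >= 3")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("spearman_rho undefined for a constant vector")
    return float(stats.spearmanr(y, yhat).statistic)
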