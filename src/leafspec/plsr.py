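"""NIPALS partial least squares regression for a single response.

Mean-centering only (no scaling or smoothing), components extracted one
at a time with deflation, leave-one-out cross-validation for component
selection, and the model expressed both in the latent (W, P, q) basis and
as a single regression-coefficient vector over wavelengths:

    y_hat = beta0 + X . beta,   beta = W (P' W)^-1 q

Outlier screening follows the usual chemometric practice: leverage from
the latent scores with the 3(A+1)/n rule, and Hotelling's T-squared on
the scores with an F-distribution control limit at the 5% level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted centered NIPALS decomposition plus the beta-vector form."""

    n_components: int
    x_mean: np.ndarray      # (bands,)
    y_mean: float
    W: np.ndarray           # (bands, A) unit-norm weight vectors
    P: np.ndarray           # (bands, A) X-loadings
    q: np.ndarray           # (A,) y-loadings
    score_norms: np.ndarray  # (A,) t_a' t_a on the training data
    beta0: float
    beta: np.ndarray        # (bands,)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """y_hat = beta0 + X . beta."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta0 + X @ self.beta

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Latent scores (n, A) of new rows, via sequential deflation."""
        Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        t = np.empty((Xc.shape[0], self.n_components))
        for a in range(self.n_components):
            t[:, a] = Xc @ self.W[:, a]
            Xc = Xc - np.outer(t[:, a], self.P[:, a])
        return t

    def predict_from_scores(self, X: np.ndarray) -> np.ndarray:
        """Equivalent prediction through the latent basis (internal check)."""
        return self.y_mean + self.scores(X) @ self.q

    def to_json(self) -> str:
        doc = {
            "format": "leafspec-pls-model",
            "version": 1,
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "score_norms": self.score_norms.tolist(),
            "beta0": float(self.beta0),
            "beta": self.beta.tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        doc = json.loads(text)
        if doc.get("format") != "leafspec-pls-model":
            raise ValueError("not a leafspec PLS model document")
        return cls(
            n_components=doc["n_components"],
            x_mean=np.asarray(doc["x_mean"], float),
            y_mean=doc["y_mean"],
            W=np.asarray(doc["W"], float),
            P=np.asarray(doc["P"], float),
            q=np.asarray(doc["q"], float),
            score_norms=np.asarray(doc["score_norms"], float),
            beta0=doc["beta0"],
            beta=np.asarray(doc["beta"], float),
        )


def fit_nipals(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a univariate-response PLS model with the NIPALS algorithm.

    Per component: initialise u with the (deflated) response, iterate
    w = X'u / u'u normalised, t = X w until t stabilises (one pass for a
    univariate y), then q_a = y't/t't, p_a = X't/t't and deflate both
    blocks.  Components beyond the effective rank of X are dropped with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if n < n_components + 2:
        raise ValueError("need n_samples >= n_components + 2")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaNs in X or y")
    if np.allclose(y, y[0]):
        raise ValueError("zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    x_scale = float(np.abs(Xc).max()) or 1.0

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    score_norms = np.zeros(n_components)

    a = 0
    for _ in range(n_components):
        u = yc
        t_old = None
        for _it in range(_NIPALS_MAX_ITER):
            w = Xc.T @ u / (u @ u)
            norm_w = np.linalg.norm(w)
            if norm_w < _NIPALS_TOL * x_scale:
                break
            w = w / norm_w
            t = Xc @ w
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * (
                np.linalg.norm(t) + _NIPALS_TOL
            ):
                break
            t_old = t
            u = yc  # univariate response: u never changes, loop exits next pass
        else:  # pragma: no cover - univariate NIPALS converges immediately
            warnings.warn("NIPALS did not converge within max iterations")
        tt = float(t @ t) if norm_w >= _NIPALS_TOL * x_scale else 0.0
        if tt <= (_NIPALS_TOL * x_scale) ** 2:
            warnings.warn(
                f"rank exhausted after {a} components; "
                f"requested {n_components}, truncating"
            )
            break
        W[:, a] = w
        P[:, a] = Xc.T @ t / tt
        q[a] = yc @ t / tt
        score_norms[a] = tt
        Xc = Xc - np.outer(t, P[:, a])
        yc = yc - q[a] * t
        a += 1

    W, P, q, score_norms = W[:, :a], P[:, :a], q[:a], score_norms[:a]
    if a == 0:
        raise ValueError("X has no usable variance")
    beta = W @ np.linalg.solve(P.T @ W, q)
    beta0 = y_mean - float(x_mean @ beta)
    return PLSModel(
        n_components=a, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q,
        score_norms=score_norms, beta0=beta0, beta=beta,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PLSModel.predict`."""
    return model.predict(X)


def loo_cross_validate(
    X: np.ndarray, y: np.ndarray, max_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out cross-validation over 1..max_components.

    Returns ``(predictions, rmse_cv)`` where ``predictions`` has shape
    (n, max_components): column a-1 holds the held-out prediction of each
    sample from an a-component model fitted on the remaining n-1.
    Fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 5:
        raise ValueError("leave-one-out needs at least 5 samples")
    if max_components > n - 3:
        # the inner fits see n-1 samples and need two spare degrees of freedom
        warnings.warn("max_components too large for leave-one-out; truncating")
        max_components = n - 3

    preds = np.empty((n, max_components))
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_nipals(X[keep], y[keep], max_components)
        xi = X[i]
        # nested sub-models: the first a NIPALS components of the full fit
        # are exactly the a-component fit, so rebuild each truncated beta
        for a in range(1, max_components + 1):
            a_eff = min(a, model.n_components)
            Wa, Pa, qa = model.W[:, :a_eff], model.P[:, :a_eff], model.q[:a_eff]
            beta = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
            beta0 = model.y_mean - float(model.x_mean @ beta)
            preds[i, a - 1] = beta0 + xi @ beta
    rmse_cv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return preds, rmse_cv


def select_components(rmse_cv: np.ndarray, n_samples: int, cap: int = 10) -> int:
    """Smallest-index argmin of the CV error curve, capped at min(cap, n/3)."""
    rmse_cv = np.asarray(rmse_cv, dtype=float)
    limit = min(cap, max(1, n_samples // 3), rmse_cv.size)
    curve = rmse_cv[:limit]
    return int(np.argmin(curve)) + 1


@dataclass
class OutlierReport:
    leverage: np.ndarray
    hotelling_t2: np.ndarray
    leverage_limit: float
    t2_limit: float
    flags: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def outlier_diagnostics(model: PLSModel, X: np.ndarray) -> OutlierReport:
    """Leverage and Hotelling T-squared screening of calibration samples.

    leverage  h_i = 1/n + sum_a t_ia^2 / (t_a' t_a),  limit 3(A+1)/n
    T^2_i     = sum_a t_ia^2 / var(t_a),  limit A(n-1)/(n-A) F_0.95(A, n-A)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    A = model.n_components
    if n <= A:
        raise ValueError("need more samples than components for diagnostics")
    t = model.scores(X)
    leverage = 1.0 / n + np.sum(t**2 / model.score_norms, axis=1)
    var_t = model.score_norms / (n - 1)
    t2 = np.sum(t**2 / var_t, axis=1)
    leverage_limit = 3.0 * (A + 1) / n
    t2_limit = A * (n - 1) / (n - A) * stats.f.ppf(0.95, A, n - A)
    flags = (leverage > leverage_limit) | (t2 > t2_limit)
    return OutlierReport(
        leverage=leverage, hotelling_t2=t2,
        leverage_limit=float(leverage_limit), t2_limit=float(t2_limit),
        flags=flags,
    )


def beta_spectrum(model: PLSModel, grid) -> "pd.DataFrame":
    """The model as a (wavelength, beta) table for plotting/export."""
    import pandas as pd

    return pd.DataFrame({
        "wavelength_nm": grid.wavelengths(),
        "beta": model.beta,
    })
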