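"""PLS calibration, AIC scoring, leaf-level prediction, chip subsets.

The calibration model is single-response partial least squares (PLS1):
latent variables (LVs) maximize covariance between the reflectance
channels and chlorophyll, and the sole hyperparameter is the LV count k.
Predictors are mean-centered but not variance-scaled by default
(reflectances share units); at k equal to the channel count on full-rank
data, PLS1 predictions coincide with ordinary least squares.

Model complexity is scored with Akaike's information criterion,

    AIC = n * ln(RSS / n) + 2 k,

where n counts leaf-level predictions on the evaluation set (leaf
predictions are the mean of the leaf's replicate predictions) and RSS is
their residual sum of squares.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .errors import PerfectFitError
from .sensors import SensorLayout

__all__ = [
    "FitScore",
    "score",
    "aic",
    "PLSCalibrator",
    "fit_pls",
    "predict_leaf",
    "leaf_means",
    "chip_subset",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitScore:
    """R2, MAE (ug/cm2), RSS and sample count of one evaluation."""

    r2: float
    mae: float
    rss: float
    n: int


def score(y_true, y_pred) -> FitScore:
    """Coefficient of determination, mean absolute error and RSS."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations to score")
    resid = y_true - y_pred
    rss = float(resid @ resid)
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    return FitScore(r2=r2, mae=float(np.abs(resid).mean()), rss=rss, n=y_true.size)


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion n*ln(RSS/n) + 2k; lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if rss <= 0:
        raise PerfectFitError("AIC undefined for RSS <= 0 (perfect fit)")
    return n * math.log(rss / n) + 2.0 * k


def leaf_means(values, leaf_ids):
    """Average per-spectrum values within each leaf.

    Returns ``(labels, means)`` with labels in sorted-unique order.
    """
    values = np.asarray(values, dtype=float)
    leaf_ids = np.asarray(leaf_ids)
    labels, inverse = np.unique(leaf_ids, return_inverse=True)
    sums = np.bincount(inverse, weights=values, minlength=len(labels))
    counts = np.bincount(inverse, minlength=len(labels))
    return labels, sums / counts


# ---------------------------------------------------------------------------
# the calibrator
# ---------------------------------------------------------------------------

class PLSCalibrator(RegressorMixin, BaseEstimator):
    """Single-response PLS calibration of chlorophyll against reflectance.

    Parameters
    ----------
    n_components : int
        Number of latent variables k (1 <= k <= min(n_features,
        n_samples - 1)).
    scale : bool
        If True, also scale channels to unit variance; off by default
        since all channels share reflectance units.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray (n_features,)
        Regression coefficients on the original scale, so that
        ``predict(X) = X @ coef_ + intercept_``.
    intercept_ : float
    x_mean_, x_std_, y_mean_, y_std_ : training statistics.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one y value per row")
        n, p = X.shape
        k = int(self.n_components)
        if not 1 <= k <= min(p, n - 1):
            raise ValueError(
                f"n_components={k} outside [1, min(n_features={p}, n_samples-1={n - 1})]"
            )
        if np.all(X.std(axis=0) == 0):
            raise ValueError("X is degenerate: zero variance in every column")
        with warnings.catch_warnings():
            # high-order components on near-exact fits trigger benign
            # convergence chatter from NIPALS
            warnings.simplefilter("ignore", UserWarning)
            pls = PLSRegression(n_components=k, scale=self.scale)
            pls.fit(X, y)
        self.pls_ = pls
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            self.x_std_ = sd
            ysd = y.std(ddof=1)
            self.y_std_ = float(ysd) if ysd > 0 else 1.0
        else:
            self.x_std_ = np.ones(p)
            self.y_std_ = 1.0
        # sklearn centers X inside predict; express the model as a plain
        # affine map predict(X) = X @ coef_ + intercept_ instead
        self.coef_ = np.asarray(pls.coef_).reshape(-1)
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1]} features, model expects {self.n_features_in_}"
            )
        return X @ self.coef_ + self.intercept_

    # -- coefficient path ---------------------------------------------

    def coefficient_path(self, ks):
        """Coefficients/intercepts for truncations of this model.

        For PLS1, the first k weight/loading vectors of a model fitted
        with K >= k components are exactly those of a k-component fit, and
        P'W is upper triangular, so the k-component rotation is
        ``W_k (P_k' W_k)^{-1}`` using leading blocks.  Returns a list of
        ``(coef, intercept)`` pairs on the original data scale.
        """
        check_is_fitted(self, "pls_")
        W = self.pls_.x_weights_          # (p, K)
        P = self.pls_.x_loadings_         # (p, K)
        Q = self.pls_.y_loadings_         # (1, K)
        K = W.shape[1]
        out = []
        for k in ks:
            if not 1 <= k <= K:
                raise ValueError(f"k={k} outside [1, {K}]")
            Rk = W[:, :k] @ np.linalg.inv(P[:, :k].T @ W[:, :k])
            b_scaled = (Rk @ Q[:, :k].T).reshape(-1)
            coef = b_scaled * self.y_std_ / self.x_std_
            intercept = self.y_mean_ - float(self.x_mean_ @ coef)
            out.append((coef, intercept))
        return out

    # -- persistence ---------------------------------------------------

    def to_json(self, *, layout: str | None = None,
                channel_subset: str | None = None) -> str:
        """Serialize the fitted model to a small JSON document."""
        check_is_fitted(self, "coef_")
        doc = {
            "model": "pls1",
            "layout": layout,
            "channel_subset": channel_subset,
            "n_components": int(self.n_components),
            "scale": bool(self.scale),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "x_mean": self.x_mean_.tolist(),
            "x_std": self.x_std_.tolist(),
            "y_mean": self.y_mean_,
            "y_std": self.y_std_,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PLSCalibrator":
        """Rebuild a predictor from :meth:`to_json` output."""
        doc = json.loads(text)
        model = cls(n_components=doc["n_components"], scale=doc["scale"])
        model.coef_ = np.asarray(doc["coef"], dtype=float)
        model.intercept_ = float(doc["intercept"])
        model.x_mean_ = np.asarray(doc["x_mean"], dtype=float)
        model.x_std_ = np.asarray(doc["x_std"], dtype=float)
        model.y_mean_ = float(doc["y_mean"])
        model.y_std_ = float(doc["y_std"])
        model.n_features_in_ = model.coef_.shape[0]
        return model


def fit_pls(X, y, n_lv: int, *, scale: bool = False) -> PLSCalibrator:
    """Fit a PLS calibration with ``n_lv`` latent variables."""
    return PLSCalibrator(n_components=n_lv, scale=scale).fit(X, y)


def predict_leaf(model: PLSCalibrator, X, leaf_ids) -> pd.Series:
    """Leaf-level predictions: mean of the leaf's replicate predictions.

    Predictions are reported unclipped (negative values pass through).
    """
    labels, means = leaf_means(model.predict(X), leaf_ids)
    return pd.Series(means, index=pd.Index(labels, name="leaf_id"), name="chl_pred")


def chip_subset(X, layout: SensorLayout, chip_id: str):
    """Restrict an 18-channel matrix to one chip's 6 channels.

    Returns ``(X_subset, sub_layout)`` with column order preserved.
    """
    mask = layout.chip_mask(chip_id)
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != layout.n_channels:
        raise ValueError(
            f"X has {X.shape[-1]} columns, layout {layout.name!r} has "
            f"{layout.n_channels} channels"
        )
    return X[..., mask], layout.chip_layout(chip_id)
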