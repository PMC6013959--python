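"""Comparison models: maxout networks, penalized logistic regression with
|weight| feature importance, and a thin gradient-boosting adapter.

Maxout networks are reimplemented here (they share the SGD-momentum
training loop with the DUNs module, and the pieces=1 equivalence to a
plain feed-forward net is a tested property). Logistic regression
delegates to scikit-learn; gradient boosting wraps xgboost when it is
importable and is skipped otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from ._nn import MomentumSGD, bce_loss, dropout_mask, minibatches, sigmoid

__all__ = ["MaxoutClassifier", "LogisticBaseline", "gbm_factory"]


def _init_maxout(n_layers, n_neurons, n_pieces, input_dim, rng):
    """Per layer: W of shape (pieces, in_dim, m) and b of shape (pieces, m)."""
    params = {}
    in_dim = input_dim
    for k in range(1, n_layers + 1):
        params[f"W{k}"] = rng.uniform(-1, 1, (n_pieces, in_dim, n_neurons)) / np.sqrt(in_dim)
        params[f"b{k}"] = np.zeros((n_pieces, n_neurons))
        in_dim = n_neurons
    params["w"] = rng.uniform(-1, 1, in_dim) / np.sqrt(in_dim)
    params["b"] = np.zeros(1)
    return params


def maxout_forward(params, X, n_layers, *, dropout_input=0.0, dropout_inner=0.0,
                   train_mode=False, rng=None):
    """Forward pass of a maxout network; each neuron outputs the maximum of
    its affine pieces. Returns ``(y_hat, cache)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xm = dropout_mask(rng, X.shape, dropout_input) if train_mode else None
    h = X * xm if xm is not None else X
    cache = {"inputs": [], "argmax": [], "masks_in": xm, "masks": []}
    for k in range(1, n_layers + 1):
        cache["inputs"].append(h)
        # pieces: (n, pieces, m)
        z = np.einsum("ni,pim->npm", h, params[f"W{k}"]) + params[f"b{k}"][None]
        amax = z.argmax(axis=1)
        h = np.take_along_axis(z, amax[:, None, :], axis=1)[:, 0, :]
        mk = dropout_mask(rng, h.shape, dropout_inner) if train_mode else None
        if mk is not None:
            h = h * mk
        cache["argmax"].append(amax)
        cache["masks"].append(mk)
    y_hat = sigmoid(h @ params["w"] + params["b"][0])
    cache["h_out"] = h
    cache["y_hat"] = y_hat
    return y_hat, cache


def _maxout_backward(params, cache, y, n_layers, n_pieces):
    n = cache["y_hat"].shape[0]
    grads = {}
    ds = (cache["y_hat"] - y) / n
    grads["w"] = cache["h_out"].T @ ds
    grads["b"] = np.array([ds.sum()])
    dh = ds[:, None] * params["w"][None, :]
    for k in range(n_layers, 0, -1):
        mk = cache["masks"][k - 1]
        if mk is not None:
            dh = dh * mk
        amax = cache["argmax"][k - 1]          # (n, m): winning piece per neuron
        hin = cache["inputs"][k - 1]           # (n, in_dim)
        m = dh.shape[1]
        dz = np.zeros((n, n_pieces, m))
        np.put_along_axis(dz, amax[:, None, :], dh[:, None, :], axis=1)
        grads[f"W{k}"] = np.einsum("ni,npm->pim", hin, dz)
        grads[f"b{k}"] = dz.sum(axis=0)
        dh = np.einsum("npm,pim->ni", dz, params[f"W{k}"])
    return grads


class MaxoutClassifier(ClassifierMixin, BaseEstimator):
    """Maxout network binary classifier trained with SGD + momentum.

    With ``n_pieces=1`` the hidden layers are purely affine, so the
    forward pass coincides with a plain feed-forward network carrying the
    same weights.
    """

    def __init__(self, n_layers=2, n_neurons=100, n_pieces=2,
                 dropout_input=0.0, dropout_inner=0.0, learning_rate=0.01,
                 momentum=0.9, batch_size=100, n_epochs=50, random_state=None):
        self.n_layers = n_layers
        self.n_neurons = n_neurons
        self.n_pieces = n_pieces
        self.dropout_input = dropout_input
        self.dropout_inner = dropout_inner
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("binary labels with both classes present required")
        yb = (y == classes[-1]).astype(float)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.params_ = _init_maxout(self.n_layers, self.n_neurons,
                                    self.n_pieces, X.shape[1], rng)
        opt = MomentumSGD(self.learning_rate, self.momentum)
        history = []
        for epoch in range(self.n_epochs):
            losses = []
            for idx in minibatches(X.shape[0], self.batch_size, rng):
                yh, cache = maxout_forward(
                    self.params_, X[idx], self.n_layers,
                    dropout_input=self.dropout_input,
                    dropout_inner=self.dropout_inner,
                    train_mode=True, rng=rng)
                loss = bce_loss(yh, yb[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "try a smaller learning_rate")
                grads = _maxout_backward(self.params_, cache, yb[idx],
                                         self.n_layers, self.n_pieces)
                opt.step(self.params_, grads)
                losses.append(loss)
            history.append(float(np.mean(losses)) if losses else np.nan)
        self.history_ = history
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        yh, _ = maxout_forward(self.params_, np.asarray(X, dtype=float),
                               self.n_layers)
        return np.column_stack([1.0 - yh, yh])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]


class LogisticBaseline(ClassifierMixin, BaseEstimator):
    """L1/L2-penalized logistic regression with |weight| feature importance.

    ``lam`` is the coefficient of the weight-norm penalty (searched
    log-uniformly over [e^-15, 1]); it maps to scikit-learn's inverse
    regularization strength as C = 1/(lam * n_samples).
    """

    def __init__(self, penalty="l2", lam=1e-4, random_state=None, max_iter=2000):
        self.penalty = penalty
        self.lam = lam
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if np.unique(y).size != 2:
            raise ValueError("binary labels with both classes present required")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        C = 1.0 / (self.lam * X.shape[0])
        pen = self.penalty.lower()
        if pen not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        self._clf = LogisticRegression(
            l1_ratio=1.0 if pen == "l1" else 0.0, C=C, solver="liblinear",
            random_state=self.random_state, max_iter=self.max_iter)
        self._clf.fit(X, y)
        self.classes_ = self._clf.classes_
        self.coef_ = self._clf.coef_.ravel()
        self.intercept_ = float(self._clf.intercept_[0])
        self.feature_importance_ = np.abs(self.coef_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        return self._clf.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._clf.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def importance_table(self, feature_names=None) -> pd.DataFrame:
        """Features ranked by |weight|, descending (ties by column order)."""
        check_is_fitted(self, "feature_importance_")
        names = (list(feature_names) if feature_names is not None
                 else [f"x{j}" for j in range(self.coef_.size)])
        order = np.argsort(-self.feature_importance_, kind="stable")
        return pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "feature": [names[j] for j in order],
            "weight": self.coef_[order],
            "importance": self.feature_importance_[order],
        })


def gbm_factory(random_state=None, **hyperparams):
    """Construct an xgboost classifier under the tuned hyper-parameter
    ranges (learning_rate, max_depth, n_estimators, min_child_weight,
    gamma, alpha, lambda, subsample, colsample_bytree, ...).

    Returns ``None`` with a warning when xgboost is unavailable, so model
    comparisons can proceed without the boosting baseline.
    """
    try:
        from xgboost import XGBClassifier
    except ImportError:  # pragma: no cover
        warnings.warn("xgboost unavailable; skipping the gradient-boosting baseline")
        return None
    hyperparams.setdefault("n_estimators", 100)
    hyperparams.setdefault("max_depth", 5)
    if "lambda" in hyperparams:
        hyperparams["reg_lambda"] = hyperparams.pop("lambda")
    if "alpha" in hyperparams:
        hyperparams["reg_alpha"] = hyperparams.pop("alpha")
    return XGBClassifier(random_state=random_state, n_jobs=1,
                         eval_metric="logloss", **hyperparams)
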