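"""Deep unified networks (DUNs): a mesh-structured deep classifier for
tabular risk prediction.

The network is *vertically deep, horizontally shallow*: a stack of K
"data units" h_1..h_K (each of m neurons) is produced by "harmonizing
units" that fuse the raw input with the previous data unit,

    h_1 = act(V_1 x + c_1),
    h_k = act(U_k h_{k-1} + V_k x + c_k),   k = 2..K,

a per-sample "attention unit" places a probability weight on each layer,

    a(x) = softmax(W_a x + b_a),    sum_k a_k = 1,  a_k in [0, 1],

and the "decision unit" scores the attention-mixed representation,

    z = sum_k a_k h_k,    y_hat = sigmoid(w . z + b).

Every data unit therefore sits exactly two hops (mix, decide) from the
output regardless of depth, so all layers receive strong gradient; the
attention unit lets each sample draw on the layer whose feature
complexity matches it (lower layers ~ near-linear structure, upper
layers ~ higher-order interactions). Training is mini-batch SGD with
classical momentum on the mean binary cross-entropy, with inverted
dropout on the input and on each data unit.

Gradients are analytic (hand-derived backpropagation through the mix
and the vertical chain); see ``loss_and_gradients``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import MomentumSGD, bce_loss, dropout_mask, get_activation, minibatches, sigmoid

__all__ = ["DUNsClassifier", "init_duns", "layer_importance"]


def init_duns(n_layers: int, n_neurons: int, input_dim: int,
              rng: np.random.Generator) -> dict:
    """Symmetric-uniform, fan-in-scaled initial parameters.

    Keys: ``V{k}`` (input->layer), ``U{k}`` (layer k-1 -> k, k >= 2),
    ``c{k}`` (bias), ``Wa``/``ba`` (attention), ``w``/``b`` (decision).
    """
    K, m, p = n_layers, n_neurons, input_dim
    if p < 1 or m < 1 or K < 1:
        raise ValueError("n_layers, n_neurons and input_dim must be positive")

    def u(shape, fan_in):
        return rng.uniform(-1.0, 1.0, size=shape) / np.sqrt(fan_in)

    params = {"Wa": u((p, K), p), "ba": np.zeros(K),
              "w": u(m, m), "b": np.zeros(1)}
    for k in range(1, K + 1):
        fan = p if k == 1 else p + m
        params[f"V{k}"] = u((p, m), fan)
        params[f"c{k}"] = np.zeros(m)
        if k > 1:
            params[f"U{k}"] = u((m, m), fan)
    return params


def _softmax(g):
    e = np.exp(g - g.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def _forward(params, X, K, act, *, dropout_input=0.0, dropout_inner=0.0,
             train_mode=False, rng=None):
    """Forward pass; returns (y_hat, attention, cache)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xm = dropout_mask(rng, X.shape, dropout_input) if train_mode else None
    xd = X * xm if xm is not None else X
    f, _ = act
    pre, h, hd, masks = [], [], [], []
    for k in range(1, K + 1):
        pk = xd @ params[f"V{k}"] + params[f"c{k}"]
        if k > 1:
            pk = pk + hd[-1] @ params[f"U{k}"]
        hk = f(pk)
        mk = dropout_mask(rng, hk.shape, dropout_inner) if train_mode else None
        pre.append(pk)
        h.append(hk)
        masks.append(mk)
        hd.append(hk * mk if mk is not None else hk)
    A = _softmax(xd @ params["Wa"] + params["ba"])
    Z = sum(A[:, k][:, None] * hd[k] for k in range(K))
    y_hat = sigmoid(Z @ params["w"] + params["b"][0])
    cache = {"X": X, "xd": xd, "xm": xm, "pre": pre, "h": h, "hd": hd,
             "masks": masks, "A": A, "Z": Z, "y_hat": y_hat}
    return y_hat, A, cache


def _backward(params, cache, y, K, act):
    """Analytic gradients of mean BCE w.r.t. every parameter."""
    _, df = act
    X, xd, A, Z, y_hat = cache["X"], cache["xd"], cache["A"], cache["Z"], cache["y_hat"]
    h, hd, pre, masks = cache["h"], cache["hd"], cache["pre"], cache["masks"]
    n = X.shape[0]
    grads = {}
    ds = (y_hat - y) / n  # d loss / d decision pre-activation
    grads["w"] = Z.T @ ds
    grads["b"] = np.array([ds.sum()])
    dZ = ds[:, None] * params["w"][None, :]
    dA = np.stack([(dZ * hd[k]).sum(axis=1) for k in range(K)], axis=1)
    dG = A * (dA - (A * dA).sum(axis=1, keepdims=True))  # softmax backprop
    grads["Wa"] = xd.T @ dG
    grads["ba"] = dG.sum(axis=0)
    dxd = dG @ params["Wa"].T
    dhd_next = None  # gradient reaching hd[k] from layer k+1
    for k in range(K, 0, -1):
        i = k - 1
        dhd = A[:, i][:, None] * dZ
        if dhd_next is not None:
            dhd = dhd + dhd_next
        dh = dhd * masks[i] if masks[i] is not None else dhd
        dpre = dh * df(pre[i], h[i])
        grads[f"V{k}"] = xd.T @ dpre
        grads[f"c{k}"] = dpre.sum(axis=0)
        dxd = dxd + dpre @ params[f"V{k}"].T
        if k > 1:
            grads[f"U{k}"] = hd[i - 1].T @ dpre
            dhd_next = dpre @ params[f"U{k}"].T
        else:
            dhd_next = None
    return grads


class DUNsClassifier(ClassifierMixin, BaseEstimator):
    """Deep unified networks binary classifier (scikit-learn API).

    Parameters
    ----------
    n_layers : number of data units K (depth), typically 2–5.
    n_neurons : neurons m per data unit, typically 100–1000.
    activation : "sigmoid" | "tanh" | "softplus" | "softsign".
    dropout_input, dropout_inner : inverted-dropout rates for the input
        and each data unit, applied during training only.
    learning_rate, momentum, batch_size : SGD-with-momentum settings
        (defaults 0.01 / 0.9 / 100).
    n_epochs : training epochs.
    random_state : seed controlling initialization, shuffling and dropout.

    Attributes
    ----------
    params_ : dict of weight arrays (see :func:`init_duns`).
    history_ : per-epoch mean training loss.
    classes_, n_features_in_ : standard fitted metadata.
    """

    def __init__(self, n_layers=3, n_neurons=100, activation="sigmoid",
                 dropout_input=0.0, dropout_inner=0.0, learning_rate=0.01,
                 momentum=0.9, batch_size=100, n_epochs=50, random_state=None):
        self.n_layers = n_layers
        self.n_neurons = n_neurons
        self.activation = activation
        self.dropout_input = dropout_input
        self.dropout_inner = dropout_inner
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state

    # -- estimator API ---------------------------------------------------

    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be a 2-D matrix with at least one column")
        if y is None:
            return X
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("binary labels with both classes present required")
        return X, (y == classes[-1]).astype(float), classes

    def fit(self, X, y):
        X, yb, classes = self._validate(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.params_ = init_duns(self.n_layers, self.n_neurons, X.shape[1], rng)
        act = get_activation(self.activation)
        opt = MomentumSGD(self.learning_rate, self.momentum)
        history = []
        for epoch in range(self.n_epochs):
            losses = []
            for idx in minibatches(X.shape[0], self.batch_size, rng):
                yh, _, cache = _forward(
                    self.params_, X[idx], self.n_layers, act,
                    dropout_input=self.dropout_input,
                    dropout_inner=self.dropout_inner,
                    train_mode=True, rng=rng)
                loss = bce_loss(yh, yb[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "try a smaller learning_rate or lower dropout")
                grads = _backward(self.params_, cache, yb[idx], self.n_layers, act)
                opt.step(self.params_, grads)
                losses.append(loss)
            history.append(float(np.mean(losses)) if losses else np.nan)
        self.history_ = history
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = self._validate(X)
        yh, _, _ = _forward(self.params_, X, self.n_layers,
                            get_activation(self.activation))
        return np.column_stack([1.0 - yh, yh])

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return self.classes_[(proba >= 0.5).astype(int)]

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    # -- architecture introspection ---------------------------------------

    def forward(self, X, train_mode: bool = False, rng=None):
        """Raw forward pass: ``(y_hat, attention)`` with attention of shape
        (n_samples, n_layers); rows lie on the probability simplex."""
        check_is_fitted(self, "params_")
        if train_mode and rng is None:
            rng = np.random.default_rng(self.random_state)
        yh, A, _ = _forward(self.params_, self._validate(X), self.n_layers,
                            get_activation(self.activation),
                            dropout_input=self.dropout_input,
                            dropout_inner=self.dropout_inner,
                            train_mode=train_mode, rng=rng)
        return yh, A

    def attention(self, X) -> np.ndarray:
        return self.forward(X)[1]

    def loss_and_gradients(self, X, y, params=None):
        """Mean BCE and its analytic gradients at ``params`` (default: the
        fitted weights); dropout disabled. Exposed for gradient checking."""
        check_is_fitted(self, "params_")
        params = self.params_ if params is None else params
        X, yb, _ = self._validate(X, y)
        act = get_activation(self.activation)
        yh, _, cache = _forward(params, X, self.n_layers, act)
        return bce_loss(yh, yb), _backward(params, cache, yb, self.n_layers, act)

    def layer_importance(self, X):
        """Per-layer summary (mean, sd, quartiles) of the attention weights
        over the samples in ``X``; the means sum to 1 across layers."""
        return layer_importance(self, X)


def layer_importance(model: DUNsClassifier, X):
    import pandas as pd

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("X must contain at least one sample")
    A = model.attention(X)
    return pd.DataFrame({
        "layer": np.arange(1, A.shape[1] + 1),
        "mean": A.mean(axis=0),
        "sd": A.std(axis=0),
        "q25": np.percentile(A, 25, axis=0),
        "median": np.percentile(A, 50, axis=0),
        "q75": np.percentile(A, 75, axis=0),
    })
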