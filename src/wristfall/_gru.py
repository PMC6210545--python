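"""Minimal many-to-one GRU network in NumPy.

Architecture: 3 input nodes (raw ax, ay, az), one GRU layer whose candidate
state uses a rectified-linear activation, a fully connected ReLU layer, and
a 2-way softmax head.  Training is backpropagation through time over
fixed-length windows with cross-entropy loss and the Adam update.

Everything is float64 and driven by a single ``numpy.random.Generator``, so
initialization, shuffling and hence the final parameters are bit-reproducible
for a given seed.

Gate equations (batch B, time T, input D, hidden H)::

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)        # update gate
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)        # reset gate
    c_t = relu(x_t Wc + (r_t * h_{t-1}) Uc + bc)   # candidate state
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t

Head::

    a = relu(h_T W1 + b1);  p = softmax(a W2 + b2)

The analytic gradients are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

PARAM_NAMES = (
    "Wz", "Uz", "bz", "Wr", "Ur", "br", "Wc", "Uc", "bc",
    "W1", "b1", "W2", "b2",
)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_params(n_in: int, n_hidden: int, n_fc: int,
                rng: np.random.Generator) -> dict:
    """Uniform fan-in scaled initialization; biases start at zero."""

    def u(fan_in, shape):
        s = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-s, s, size=shape)

    p = {
        "Wz": u(n_in, (n_in, n_hidden)),
        "Uz": u(n_hidden, (n_hidden, n_hidden)),
        "bz": np.zeros(n_hidden),
        "Wr": u(n_in, (n_in, n_hidden)),
        "Ur": u(n_hidden, (n_hidden, n_hidden)),
        "br": np.zeros(n_hidden),
        "Wc": u(n_in, (n_in, n_hidden)),
        "Uc": u(n_hidden, (n_hidden, n_hidden)),
        "bc": np.zeros(n_hidden),
        "W1": u(n_hidden, (n_hidden, n_fc)),
        "b1": np.zeros(n_fc),
        "W2": u(n_fc, (n_fc, 2)),
        "b2": np.zeros(2),
    }
    return p


def forward(params: dict, X: np.ndarray, cache: bool = False):
    """Class probabilities for a batch of windows X of shape (B, T, 3).

    Returns (B, 2) softmax probabilities, column 1 being P(fall); with
    ``cache=True`` also returns the intermediates needed by ``backward``.
    """
    B, T, _ = X.shape
    H = params["bz"].shape[0]
    h = np.zeros((B, H))
    caches = []
    for t in range(T):
        x = X[:, t, :]
        z = _sigmoid(x @ params["Wz"] + h @ params["Uz"] + params["bz"])
        r = _sigmoid(x @ params["Wr"] + h @ params["Ur"] + params["br"])
        rh = r * h
        cb = x @ params["Wc"] + rh @ params["Uc"] + params["bc"]
        c = np.maximum(cb, 0.0)
        h_new = (1.0 - z) * h + z * c
        if cache:
            caches.append((x, h, z, r, rh, cb, c))
        h = h_new
    pre1 = h @ params["W1"] + params["b1"]
    a = np.maximum(pre1, 0.0)
    logits = a @ params["W2"] + params["b2"]
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    if cache:
        return probs, (caches, h, pre1, a)
    return probs


def loss_and_grads(params: dict, X: np.ndarray, y: np.ndarray,
                   sample_weight: np.ndarray | None = None):
    """Weighted cross-entropy loss and analytic gradients (BPTT).

    y is a (B,) 0/1 vector (1 = fall).  The loss is the weighted mean of
    per-window cross-entropies.
    """
    B = X.shape[0]
    w = np.ones(B) if sample_weight is None else np.asarray(sample_weight)
    wsum = w.sum()
    probs, (caches, hT, pre1, a) = forward(params, X, cache=True)
    eps = 1e-12
    p_true = probs[np.arange(B), y]
    loss = float(-(w * np.log(p_true + eps)).sum() / wsum)

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / wsum)[:, None]

    grads["W2"] = a.T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    da = dlogits @ params["W2"].T
    dpre1 = da * (pre1 > 0)
    grads["W1"] = hT.T @ dpre1
    grads["b1"] = dpre1.sum(axis=0)
    dh = dpre1 @ params["W1"].T

    for t in range(len(caches) - 1, -1, -1):
        x, h_prev, z, r, rh, cb, c = caches[t]
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)
        dcb = dc * (cb > 0)
        grads["Wc"] += x.T @ dcb
        grads["Uc"] += rh.T @ dcb
        grads["bc"] += dcb.sum(axis=0)
        drh = dcb @ params["Uc"].T
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r
        drb = dr * r * (1.0 - r)
        grads["Wr"] += x.T @ drb
        grads["Ur"] += h_prev.T @ drb
        grads["br"] += drb.sum(axis=0)
        dzb = dz * z * (1.0 - z)
        grads["Wz"] += x.T @ dzb
        grads["Uz"] += h_prev.T @ dzb
        grads["bz"] += dzb.sum(axis=0)
        dh = dh_prev + dzb @ params["Uz"].T + drb @ params["Ur"].T
    return loss, grads


class Adam:
    """Standard adaptive-moment optimizer with global-norm gradient clipping."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        if self.clip_norm is not None:
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if gnorm > self.clip_norm:
                scale = self.clip_norm / (gnorm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
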