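"""Minimal NumPy neural-network core: a GRU token-sequence network and an
MLP binary classifier, both with hand-derived backpropagation and Adam.

No deep-learning framework is assumed at run time, so the recurrent policy
and the feed-forward predictor are implemented directly on NumPy arrays.
Gate conventions follow the usual GRU formulation with separate input/hidden
biases (the hidden bias of the candidate gate is modulated by the reset
gate), which keeps the reset gate differentiable through the bias term:

    r = sigmoid(x Wx_r + bx_r + h Wh_r + bh_r)
    z = sigmoid(x Wx_z + bx_z + h Wh_z + bh_z)
    n = tanh(x Wx_n + bx_n + r * (h Wh_n + bh_n))
    h' = (1 - z) * n + z * h

All arithmetic is float64 by default so analytic gradients can be checked
against central finite differences to tight relative error.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_softmax(x: np.ndarray) -> np.ndarray:
    shifted = x - x.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def softmax(x: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(x))


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            self.params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan: int,
                  dtype: np.dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class GRUNetwork:
    """Embedding -> stacked GRU -> linear projection onto the vocabulary.

    ``params`` maps names to arrays: ``E`` (V x D), per layer ``Wx{l}``
    (Din x 3H), ``Wh{l}`` (H x 3H), ``bx{l}``, ``bh{l}`` (3H), and the
    output head ``Wo`` (H x V), ``bo`` (V).  Gate column order is [r, z, n].
    """

    def __init__(self, vocab_size: int, embed_dim: int = 128,
                 hidden_dim: int = 512, n_layers: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype: type = np.float64):
        if rng is None:
            rng = np.random.default_rng(0)
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.dtype = np.dtype(dtype)
        H = hidden_dim
        p: dict[str, np.ndarray] = {}
        p["E"] = rng.normal(0.0, 0.1, size=(vocab_size, embed_dim)).astype(self.dtype)
        for l in range(n_layers):
            din = embed_dim if l == 0 else H
            p[f"Wx{l}"] = _uniform_init(rng, (din, 3 * H), H, self.dtype)
            p[f"Wh{l}"] = _uniform_init(rng, (H, 3 * H), H, self.dtype)
            p[f"bx{l}"] = np.zeros(3 * H, dtype=self.dtype)
            p[f"bh{l}"] = np.zeros(3 * H, dtype=self.dtype)
        p["Wo"] = _uniform_init(rng, (H, vocab_size), H, self.dtype)
        p["bo"] = np.zeros(vocab_size, dtype=self.dtype)
        self.params = p

    # -- bookkeeping ---------------------------------------------------

    def copy(self) -> "GRUNetwork":
        clone = GRUNetwork.__new__(GRUNetwork)
        clone.vocab_size = self.vocab_size
        clone.embed_dim = self.embed_dim
        clone.hidden_dim = self.hidden_dim
        clone.n_layers = self.n_layers
        clone.dtype = self.dtype
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def param_vector(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_hidden(self, batch: int) -> list[np.ndarray]:
        return [np.zeros((batch, self.hidden_dim), dtype=self.dtype)
                for _ in range(self.n_layers)]

    # -- forward -------------------------------------------------------

    def _cell_forward(self, l: int, x: np.ndarray, h: np.ndarray):
        H = self.hidden_dim
        p = self.params
        gi = x @ p[f"Wx{l}"] + p[f"bx{l}"]
        gh = h @ p[f"Wh{l}"] + p[f"bh{l}"]
        r = sigmoid(gi[:, :H] + gh[:, :H])
        z = sigmoid(gi[:, H:2 * H] + gh[:, H:2 * H])
        ghn = gh[:, 2 * H:]
        n = np.tanh(gi[:, 2 * H:] + r * ghn)
        h_new = (1.0 - z) * n + z * h
        return h_new, (x, h, r, z, n, ghn)

    def step(self, tokens: np.ndarray, hidden: list[np.ndarray]):
        """One sampling step: token indices (B,) -> (logits (B,V), new hidden)."""
        x = self.params["E"][tokens]
        new_hidden = []
        for l in range(self.n_layers):
            h_new, _ = self._cell_forward(l, x, hidden[l])
            new_hidden.append(h_new)
            x = h_new
        logits = x @ self.params["Wo"] + self.params["bo"]
        return logits, new_hidden

    def step_probs(self, tokens: np.ndarray, hidden: list[np.ndarray]):
        logits, new_hidden = self.step(tokens, hidden)
        return softmax(logits), new_hidden

    # -- teacher-forced loss and gradients -----------------------------

    def loss_and_grads(self, inputs: np.ndarray, targets: np.ndarray,
                       mask: np.ndarray,
                       seq_weights: np.ndarray | None = None,
                       compute_grads: bool = True):
        """Weighted teacher-forced negative log likelihood and its gradients.

        inputs, targets: int arrays (B, T); mask: (B, T) with 1 where the
        target position is real.  The scalar objective is
        ``sum_b w_b * NLL_b`` with ``NLL_b = -sum_t mask log p(target)``;
        ``seq_weights`` defaults to 1/B (mean per-sequence NLL).  Returns
        ``(objective, per_seq_nll, grads)``.
        """
        B, T = inputs.shape
        H = self.hidden_dim
        p = self.params
        if seq_weights is None:
            seq_weights = np.full(B, 1.0 / B, dtype=self.dtype)
        hidden = self.init_hidden(B)
        caches: list[list[tuple]] = []
        xs_emb: list[np.ndarray] = []
        logps = np.zeros((B, T), dtype=self.dtype)
        dlogits_all = np.zeros((B, T, self.vocab_size), dtype=self.dtype) if compute_grads else None
        tops = np.zeros((B, T, H), dtype=self.dtype) if compute_grads else None

        for t in range(T):
            x = p["E"][inputs[:, t]]
            xs_emb.append(x)
            step_cache = []
            for l in range(self.n_layers):
                hidden[l], cache = self._cell_forward(l, x, hidden[l])
                step_cache.append(cache)
                x = hidden[l]
            caches.append(step_cache)
            logits = x @ p["Wo"] + p["bo"]
            lsm = log_softmax(logits)
            logps[:, t] = lsm[np.arange(B), targets[:, t]]
            if compute_grads:
                tops[:, t] = x
                sm = np.exp(lsm)
                sm[np.arange(B), targets[:, t]] -= 1.0
                dlogits_all[:, t] = sm * (mask[:, t] * seq_weights)[:, None]

        per_seq_nll = -(logps * mask).sum(axis=1)
        objective = float((per_seq_nll * seq_weights).sum())
        if not compute_grads:
            return objective, per_seq_nll, None

        grads = self.zero_grads()
        dh_next = [np.zeros((B, H), dtype=self.dtype) for _ in range(self.n_layers)]
        for t in range(T - 1, -1, -1):
            dlog = dlogits_all[:, t]
            grads["Wo"] += tops[:, t].T @ dlog
            grads["bo"] += dlog.sum(axis=0)
            d_from_above = dlog @ p["Wo"].T
            for l in range(self.n_layers - 1, -1, -1):
                dh = dh_next[l] + d_from_above
                x, h_prev, r, z, n, ghn = caches[t][l]
                dz = dh * (h_prev - n) * z * (1.0 - z)
                dn = dh * (1.0 - z) * (1.0 - n * n)
                dr = dn * ghn * r * (1.0 - r)
                dgi = np.concatenate([dr, dz, dn], axis=1)
                dgh = np.concatenate([dr, dz, dn * r], axis=1)
                grads[f"Wx{l}"] += x.T @ dgi
                grads[f"bx{l}"] += dgi.sum(axis=0)
                grads[f"Wh{l}"] += h_prev.T @ dgh
                grads[f"bh{l}"] += dgh.sum(axis=0)
                d_from_above = dgi @ p[f"Wx{l}"].T  # grad w.r.t. this layer's input
                dh_next[l] = dh * z + dgh @ p[f"Wh{l}"].T
            np.add.at(grads["E"], inputs[:, t], d_from_above)
        return objective, per_seq_nll, grads

    def sequence_log_probs(self, inputs: np.ndarray, targets: np.ndarray,
                           mask: np.ndarray) -> np.ndarray:
        """Per-sequence log likelihood (sum of realized-token log probs)."""
        _, per_seq_nll, _ = self.loss_and_grads(inputs, targets, mask,
                                                compute_grads=False)
        return -per_seq_nll


class MLPClassifier:
    """Feed-forward binary classifier: ReLU hidden layers, sigmoid output,
    inverted dropout on hidden activations, binary cross-entropy, Adam."""

    def __init__(self, n_features: int, hidden: tuple[int, ...] = (8000, 4000, 2000),
                 dropout: float = 0.2, lr: float = 1e-3, epochs: int = 100,
                 batch_size: int = 128, seed: int = 0):
        self.n_features = n_features
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = [n_features, *hidden, 1]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            self.params[f"W{i}"] = (rng.normal(0, 1, (dims[i], dims[i + 1]))
                                    * np.sqrt(2.0 / dims[i]))
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self._rng = rng
        self.n_layers = len(dims) - 1

    def _forward(self, X: np.ndarray, train: bool):
        acts = [X]
        masks = []
        a = X
        for i in range(self.n_layers - 1):
            a = np.maximum(a @ self.params[f"W{i}"] + self.params[f"b{i}"], 0.0)
            if train and self.dropout > 0:
                m = (self._rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(a)
        i = self.n_layers - 1
        logits = (a @ self.params[f"W{i}"] + self.params[f"b{i}"]).ravel()
        return logits, acts, masks

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        opt = Adam(self.params, lr=self.lr)
        n = X.shape[0]
        idx_rng = np.random.default_rng(self.seed + 1)
        for _ in range(self.epochs):
            order = idx_rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                Xb, yb = X[sel], y[sel]
                logits, acts, masks = self._forward(Xb, train=True)
                prob = sigmoid(logits)
                dlogits = (prob - yb) / len(sel)  # BCE w.r.t. logits
                grads: dict[str, np.ndarray] = {}
                delta = dlogits[:, None]
                for i in range(self.n_layers - 1, -1, -1):
                    grads[f"W{i}"] = acts[i].T @ delta
                    grads[f"b{i}"] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.params[f"W{i}"].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                opt.step(grads)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        logits, _, _ = self._forward(X, train=False)
        p1 = sigmoid(logits)
        return np.column_stack([1.0 - p1, p1])


def finite_difference_grads(loss_fn: Callable[[], float],
                            params: dict[str, np.ndarray],
                            eps: float = 1e-5) -> dict[str, np.ndarray]:
    """Central-finite-difference gradients of ``loss_fn`` w.r.t. ``params``.

    Independent oracle for gradient checks; O(#params) loss evaluations, so
    only usable on toy models.
    """
    grads = {}
    for name, arr in params.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lo_plus = loss_fn()
            flat[i] = orig - eps
            lo_minus = loss_fn()
            flat[i] = orig
            gflat[i] = (lo_plus - lo_minus) / (2.0 * eps)
        grads[name] = g
    return grads
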