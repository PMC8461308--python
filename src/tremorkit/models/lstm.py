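"""A small LSTM sequence classifier implemented in NumPy.

Architecture: a stack of LSTM layers (default two layers of 100 hidden
units) followed by a time-distributed dense layer with softmax
activation, trained with Adam (learning rate 0.001) on the categorical
cross-entropy, one prediction per timestep. Sequences are split into
fixed-length chunks with the recurrent state reset at chunk boundaries;
the trailing chunk is zero-padded and masked out of the loss.

The implementation is deliberately self-contained (no deep-learning
framework is assumed at run time) and is validated against numerical
gradients in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMClassifier:
    """Multiclass per-timestep sequence classifier.

    Parameters
    ----------
    n_features : int
        Input dimensionality per timestep.
    n_classes : int
        Number of output classes.
    hidden : int
        Hidden units per LSTM layer.
    n_layers : int
        Number of stacked LSTM layers.
    lr : float
        Adam learning rate.
    epochs, batch_size, chunk_len : int
        Training protocol: chunks of ``chunk_len`` timesteps, shuffled
        into batches of ``batch_size`` chunks, for ``epochs`` passes.
    seed : int
        Seeds weight initialization and batch shuffling.
    """

    def __init__(
        self,
        n_features: int,
        n_classes: int = 5,
        hidden: int = 100,
        n_layers: int = 2,
        lr: float = 1e-3,
        epochs: int = 60,
        batch_size: int = 8,
        chunk_len: int = 60,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.n_classes = n_classes
        self.hidden = hidden
        self.n_layers = n_layers
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.chunk_len = chunk_len
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._init_params()
        self._init_adam()
        self.fitted_ = False

    # -- parameters ---------------------------------------------------------

    def _glorot(self, fan_in, fan_out, shape):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self._rng.uniform(-limit, limit, size=shape)

    def _init_params(self):
        H = self.hidden
        self.W = []  # per layer: (in_dim + H, 4H), gate order i, f, g, o
        self.b = []
        for layer in range(self.n_layers):
            in_dim = self.n_features if layer == 0 else H
            self.W.append(self._glorot(in_dim + H, 4 * H, (in_dim + H, 4 * H)))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            self.b.append(bias)
        self.Wy = self._glorot(H, self.n_classes, (H, self.n_classes))
        self.by = np.zeros(self.n_classes)

    def _params(self):
        return self.W + self.b + [self.Wy, self.by]

    def _init_adam(self):
        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    def _adam_update(self, grads):
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self._params()
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            mhat = self._adam_m[i] / (1 - b1**self._adam_t)
            vhat = self._adam_v[i] / (1 - b2**self._adam_t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # -- forward / backward -------------------------------------------------

    def _forward(self, X):
        """X: (B, T, F). Returns logits (B, T, C) and per-layer caches."""
        B, T, _ = X.shape
        H = self.hidden
        caches = []
        inp = X
        for layer in range(self.n_layers):
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            cache = {"x": inp, "h_prev": [], "c_prev": [], "gates": [], "c": [], "tanh_c": []}
            hs = np.empty((B, T, H))
            for t in range(T):
                z = np.concatenate([h, inp[:, t, :]], axis=1) @ self.W[layer] + self.b[layer]
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                cache["h_prev"].append(h)
                cache["c_prev"].append(c)
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                cache["gates"].append((i, f, g, o))
                cache["c"].append(c)
                cache["tanh_c"].append(tc)
                hs[:, t, :] = h
            cache["hs"] = hs
            caches.append(cache)
            inp = hs
        logits = inp @ self.Wy + self.by
        return logits, caches

    def _backward(self, caches, dlogits):
        """Backpropagation through time; returns gradients in _params() order."""
        B, T, _ = dlogits.shape
        H = self.hidden
        top_h = caches[-1]["hs"]
        dWy = top_h.reshape(-1, H).T @ dlogits.reshape(-1, self.n_classes)
        dby = dlogits.sum(axis=(0, 1))
        dh_out = dlogits @ self.Wy.T  # gradient into top layer's h at every t

        dW = [np.zeros_like(w) for w in self.W]
        db = [np.zeros_like(b) for b in self.b]
        for layer in range(self.n_layers - 1, -1, -1):
            cache = caches[layer]
            in_dim = cache["x"].shape[2]
            dx_all = np.zeros((B, T, in_dim))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o = cache["gates"][t]
                c = cache["c"][t]
                tc = cache["tanh_c"][t]
                dh = dh_out[:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1 - tc * tc) + dc_next
                di = dc * g
                df = dc * cache["c_prev"][t]
                dg = dc * i
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - g * g),
                        do * o * (1 - o),
                    ],
                    axis=1,
                )
                hx = np.concatenate([cache["h_prev"][t], cache["x"][:, t, :]], axis=1)
                dW[layer] += hx.T @ dz
                db[layer] += dz.sum(axis=0)
                dhx = dz @ self.W[layer].T
                dh_next = dhx[:, :H]
                dx_all[:, t, :] = dhx[:, H:]
                dc_next = dc * f
            dh_out = dx_all  # feeds the layer below
        return dW + db + [dWy, dby]

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def loss_and_grads(self, X, y, mask):
        """Mean masked cross-entropy and gradients; exposed for gradient checks."""
        logits, caches = self._forward(X)
        probs = self._softmax(logits)
        n_valid = max(int(mask.sum()), 1)
        onehot = np.zeros_like(probs)
        B, T = y.shape
        onehot[np.repeat(np.arange(B), T), np.tile(np.arange(T), B), y.ravel()] = 1.0
        logp = np.log(np.clip(probs, 1e-12, None))
        loss = -np.sum(mask[..., None] * onehot * logp) / n_valid
        dlogits = (probs - onehot) * mask[..., None] / n_valid
        grads = self._backward(caches, dlogits)
        return loss, grads

    # -- training / inference ----------------------------------------------

    def _chunk(self, sequences):
        """Split (X, y) sequences into padded fixed-length chunks."""
        chunks = []
        L = self.chunk_len
        for X, y in sequences:
            for s in range(0, len(X), L):
                xs = X[s : s + L]
                ys = y[s : s + L]
                pad = L - len(xs)
                mask = np.ones(L, dtype=bool)
                if pad:
                    xs = np.vstack([xs, np.zeros((pad, X.shape[1]))])
                    ys = np.concatenate([ys, np.zeros(pad, dtype=int)])
                    mask[len(X) - s :] = False
                chunks.append((xs, ys, mask))
        return chunks

    def fit(self, sequences):
        """Train on a list of ``(X, y)`` per-patient chronological sequences.

        ``X`` is ``(T, n_features)`` (teacher forcing: the observed
        previous class is simply one of the input features), ``y`` is
        ``(T,)`` integer classes.
        """
        chunks = self._chunk(sequences)
        n = len(chunks)
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            for s in range(0, n, self.batch_size):
                batch = [chunks[j] for j in order[s : s + self.batch_size]]
                X = np.stack([b[0] for b in batch])
                y = np.stack([b[1] for b in batch])
                mask = np.stack([b[2] for b in batch])
                _, grads = self.loss_and_grads(X, y, mask)
                self._adam_update(grads)
        self.fitted_ = True
        return self

    def predict_sequence(self, X) -> np.ndarray:
        """Per-timestep class predictions for one full sequence (T, F).

        The recurrent state is reset every ``chunk_len`` steps, matching
        the training protocol (the network never learns dynamics beyond
        the chunk horizon, and carrying state further drifts).
        """
        X = np.asarray(X, dtype=float)
        preds = []
        for s in range(0, len(X), self.chunk_len):
            logits, _ = self._forward(X[None, s : s + self.chunk_len, :])
            preds.append(np.argmax(logits[0], axis=-1))
        return np.concatenate(preds)

    def begin_sequence(self) -> "LSTMStepper":
        """Stateful one-step-at-a-time interface (for closed-loop control)."""
        return LSTMStepper(self)


class LSTMStepper:
    """Carries (h, c) per layer across single-step calls, resetting the
    state every ``chunk_len`` steps to match the training protocol."""

    def __init__(self, model: LSTMClassifier):
        self.model = model
        self._steps = 0
        self._reset()

    def _reset(self):
        H = self.model.hidden
        self.h = [np.zeros((1, H)) for _ in range(self.model.n_layers)]
        self.c = [np.zeros((1, H)) for _ in range(self.model.n_layers)]

    def step(self, x: np.ndarray) -> int:
        m = self.model
        if self._steps and self._steps % m.chunk_len == 0:
            self._reset()
        self._steps += 1
        H = m.hidden
        inp = np.asarray(x, dtype=float)[None, :]
        for layer in range(m.n_layers):
            z = np.concatenate([self.h[layer], inp], axis=1) @ m.W[layer] + m.b[layer]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            self.c[layer] = f * self.c[layer] + i * g
            self.h[layer] = o * np.tanh(self.c[layer])
            inp = self.h[layer]
        logits = inp @ m.Wy + m.by
        return int(np.argmax(logits[0]))


__all__ = ["LSTMClassifier", "LSTMStepper"]
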