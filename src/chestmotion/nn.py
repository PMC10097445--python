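"""Minimal numpy LSTM stack used by the movement classifier.

The network is tiny (3 input channels, 20 + 30 hidden units, 6 outputs), so a
plain numpy implementation with hand-written backpropagation through time is
fast and fully deterministic.  Architecture: sequence input -> LSTM(H1, full
sequence) -> dropout -> LSTM(H2, last output) -> dense -> softmax, trained
with cross-entropy loss and SGD with momentum.

Gate layout in the fused weight matrices is ``[input, forget, cell, output]``;
forget-gate biases start at 1, all other weights Glorot-uniform.
"""

from __future__ import annotations

import numpy as np

#: All computation runs in single precision: the network is tiny, gradients
#: are well-conditioned, and float32 roughly halves training time.
DTYPE = np.float32


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class LstmNet:
    """Two stacked LSTM layers with inter-layer dropout and a dense softmax head."""

    def __init__(self, n_in: int, h1: int, h2: int, n_out: int, dropout_p: float, seed: int):
        if not 0 <= dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        self.n_in, self.h1, self.h2, self.n_out = n_in, h1, h2, n_out
        self.dropout_p = dropout_p
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for name, (rows, h) in {"1": (n_in, h1), "2": (h1, h2)}.items():
            self.params["W" + name] = _glorot(rng, (rows, 4 * h))
            self.params["U" + name] = _glorot(rng, (h, 4 * h))
            b = np.zeros(4 * h, dtype=DTYPE)
            b[h : 2 * h] = 1.0  # forget gate bias
            self.params["b" + name] = b
        self.params["Wd"] = _glorot(rng, (h2, n_out))
        self.params["bd"] = np.zeros(n_out, dtype=DTYPE)

    # ---- forward -----------------------------------------------------------

    def _lstm_forward(self, X: np.ndarray, layer: str, h: int):
        """Run one LSTM layer over (B, T, in); returns outputs and caches.

        The input contribution and bias are applied in one batched matmul;
        gate sigmoids use the stable identity sigmoid(x) = (1 + tanh(x/2))/2
        so the whole 4h gate block needs a single tanh call.
        """
        W, U, b = self.params["W" + layer], self.params["U" + layer], self.params["b" + layer]
        B, T, _ = X.shape
        Z_in = X.reshape(B * T, -1) @ W
        Z_in += b
        Z_in = Z_in.reshape(B, T, 4 * h)
        hs = np.zeros((B, T, h), dtype=DTYPE)
        cache = []
        h_t = np.zeros((B, h), dtype=DTYPE)
        c_t = np.zeros((B, h), dtype=DTYPE)
        for t in range(T):
            z = Z_in[:, t] + h_t @ U
            g = np.tanh(z[:, 2 * h : 3 * h])
            z *= 0.5
            np.tanh(z, out=z)
            z += 1.0
            z *= 0.5  # z is now sigmoid of the pre-activation
            i = z[:, :h]
            f = z[:, h : 2 * h]
            o = z[:, 3 * h :]
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            hs[:, t] = h_t
            cache.append((i, f, g, o, c_prev, tc))
        return hs, cache

    def forward(
        self,
        X: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Forward pass; dropout is applied only when ``dropout_rng`` is given."""
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 3 or X.shape[2] != self.n_in:
            raise ValueError(f"expected input (batch, time, {self.n_in}), got {X.shape}")
        h1_seq, cache1 = self._lstm_forward(X, "1", self.h1)
        if dropout_rng is not None and self.dropout_p > 0:
            keep = 1.0 - self.dropout_p
            mask = ((dropout_rng.random(h1_seq.shape) < keep) / keep).astype(DTYPE)
        else:
            mask = None
        h1_drop = h1_seq * mask if mask is not None else h1_seq
        h2_seq, cache2 = self._lstm_forward(h1_drop, "2", self.h2)
        h_last = h2_seq[:, -1]
        logits = h_last @ self.params["Wd"] + self.params["bd"]
        probs = softmax(logits)
        ctx = {
            "X": X, "h1_seq": h1_seq, "h1_drop": h1_drop, "mask": mask,
            "cache1": cache1, "cache2": cache2, "h2_seq": h2_seq, "probs": probs,
        }
        return probs, ctx

    # ---- backward ----------------------------------------------------------

    def _lstm_backward(self, X_in, hs, cache, dH_seq, layer: str, h: int):
        W, U = self.params["W" + layer], self.params["U" + layer]
        B, T, _ = X_in.shape
        dZ = np.zeros((B, T, 4 * h), dtype=DTYPE)
        dh_next = np.zeros((B, h), dtype=DTYPE)
        dc_next = np.zeros((B, h), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dH_seq[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dc_next = dc * f
            dz = dZ[:, t]
            dz[:, :h] = dc * g * i * (1 - i)
            dz[:, h : 2 * h] = dc * c_prev * f * (1 - f)
            dz[:, 2 * h : 3 * h] = dc * i * (1 - g * g)
            dz[:, 3 * h :] = do * o * (1 - o)
            dh_next = dz @ U.T
        dZ2d = dZ.reshape(B * T, 4 * h)
        X2d = X_in.reshape(B * T, -1)
        grads = {
            "W" + layer: X2d.T @ dZ2d,
            "U" + layer: hs_prev(hs).reshape(B * T, h).T @ dZ2d,
            "b" + layer: dZ2d.sum(axis=0),
        }
        dX = (dZ2d @ W.T).reshape(B, T, -1)
        return grads, dX

    def backward(self, ctx: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. all parameters."""
        probs = ctx["probs"]
        B = probs.shape[0]
        dlogits = ((probs - y_onehot) / B).astype(DTYPE)
        h_last = ctx["h2_seq"][:, -1]
        grads = {
            "Wd": h_last.T @ dlogits,
            "bd": dlogits.sum(axis=0),
        }
        dH2 = np.zeros_like(ctx["h2_seq"])
        dH2[:, -1] = dlogits @ self.params["Wd"].T
        g2, dH1_drop = self._lstm_backward(ctx["h1_drop"], ctx["h2_seq"], ctx["cache2"], dH2, "2", self.h2)
        if ctx["mask"] is not None:
            dH1 = dH1_drop * ctx["mask"]
        else:
            dH1 = dH1_drop
        g1, _ = self._lstm_backward(ctx["X"], ctx["h1_seq"], ctx["cache1"], dH1, "1", self.h1)
        grads.update(g2)
        grads.update(g1)
        return grads

    def loss(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        p = np.clip((probs * y_onehot).sum(axis=1), 1e-12, None)
        return float(-np.log(p).mean())


def hs_prev(hs: np.ndarray) -> np.ndarray:
    """Hidden states shifted one step right (h_{t-1}), zero initial state."""
    out = np.zeros_like(hs)
    out[:, 1:] = hs[:, :-1]
    return out


class SgdMomentum:
    """Classical SGD with momentum: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, momentum: float):
        self.lr = lr
        self.momentum = momentum
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k in params:
            self.vel[k] = self.momentum * self.vel[k] - self.lr * grads[k]
            params[k] += self.vel[k]
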