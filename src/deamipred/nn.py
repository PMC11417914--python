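"""Minimal seeded neural-network core (numpy, manual backprop).

Implements exactly the pieces the models need: a token-embedding +
bidirectional-LSTM local encoder (final forward/backward states
concatenated), a fully connected head with ReLU and inverted dropout, a
binary-cross-entropy-with-logits loss, a masked MSE loss, and Adam.

All parameters live in flat ``{name: ndarray}`` dicts so optimizers and
checkpoints can treat them uniformly. Gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# Local encoder: embedding + BiLSTM, final-state concatenation
# ---------------------------------------------------------------------------

class LocalEncoder:
    """Token embedding (V x E) followed by a bidirectional LSTM (H per direction).

    ``forward`` maps an (B, w) int token array to (B, 2H): the two
    directions' hidden states at the center (site) step, concatenated.
    The forward direction reads the left half up to the center, the
    backward direction the right half down to the center, so each output
    half summarizes one flank plus the site itself.
    """

    def __init__(self, vocab_size: int, window_size: int, token_dim: int, hidden: int):
        self.vocab_size = vocab_size
        self.window_size = window_size
        self.token_dim = token_dim
        self.hidden = hidden

    @property
    def out_dim(self) -> int:
        return 2 * self.hidden

    def param_names(self) -> list[str]:
        names = ["emb"]
        for d in ("f", "b"):
            names += [f"Wx_{d}", f"Wh_{d}", f"b_{d}"]
        return names

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        E, H = self.token_dim, self.hidden
        params = {"emb": rng.normal(0.0, 0.1, size=(self.vocab_size, E))}
        for d in ("f", "b"):
            params[f"Wx_{d}"] = glorot(rng, E, 4 * H)
            params[f"Wh_{d}"] = glorot(rng, H, 4 * H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            params[f"b_{d}"] = b
        return params

    def _lstm_forward(self, X: np.ndarray, Wx, Wh, b):
        B, T, _ = X.shape
        H = self.hidden
        XW = X.reshape(B * T, -1) @ Wx
        XW = XW.reshape(B, T, 4 * H) + b
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            z = XW[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            steps.append((i, f, g, o, c, hc, h))
            h, c = h_new, c_new
        return h, (X, steps)

    def _lstm_backward(self, dh_T: np.ndarray, cache, Wx, Wh):
        X, steps = cache
        B, T, E = X.shape
        H = self.hidden
        dZ = np.zeros((B, T, 4 * H))
        dWh = np.zeros_like(Wh)
        dh = dh_T
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, hc, h_prev = steps[t]
            do = dh * hc
            dc = dc + dh * o * (1.0 - hc * hc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dZ[:, t] = dz
            dWh += h_prev.T @ dz
            dh = dz @ Wh.T
            dc = dc * f
        dZ_flat = dZ.reshape(B * T, 4 * H)
        dWx = X.reshape(B * T, E).T @ dZ_flat
        db = dZ_flat.sum(axis=0)
        dX = (dZ_flat @ Wx.T).reshape(B, T, E)
        return dX, dWx, dWh, db

    def forward(self, tokens: np.ndarray, params: dict[str, np.ndarray] | None = None):
        """Encode (B, w) token ids to (B, 2H); returns (output, cache)."""
        if params is None:
            params = self.params  # type: ignore[attr-defined]
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim != 2:
            raise ShapeError(f"tokens must be 2-D (batch, w), got shape {tokens.shape}")
        if tokens.size and tokens.shape[1] != self.window_size:
            raise ShapeError(
                f"expected window width {self.window_size}, got {tokens.shape[1]}"
            )
        X = params["emb"][tokens]  # (B, T, E)
        center = (self.window_size - 1) // 2
        # states beyond the center never reach the output, so each
        # direction only runs to the center step
        h_f, cache_f = self._lstm_forward(
            X[:, : center + 1], params["Wx_f"], params["Wh_f"], params["b_f"]
        )
        h_b, cache_b = self._lstm_forward(
            X[:, center:][:, ::-1], params["Wx_b"], params["Wh_b"], params["b_b"]
        )
        out = np.concatenate([h_f, h_b], axis=1)
        return out, (tokens, params, cache_f, cache_b)

    def backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        tokens, params, cache_f, cache_b = cache
        H = self.hidden
        center = (self.window_size - 1) // 2
        dX_f, dWx_f, dWh_f, db_f = self._lstm_backward(
            dout[:, :H], cache_f, params["Wx_f"], params["Wh_f"]
        )
        dX_b_rev, dWx_b, dWh_b, db_b = self._lstm_backward(
            dout[:, H:], cache_b, params["Wx_b"], params["Wh_b"]
        )
        B = tokens.shape[0]
        dX = np.zeros((B, self.window_size, self.token_dim))
        dX[:, : center + 1] += dX_f
        dX[:, center:] += dX_b_rev[:, ::-1]
        demb = np.zeros_like(params["emb"])
        np.add.at(demb, tokens.reshape(-1), dX.reshape(-1, self.token_dim))
        return {
            "emb": demb,
            "Wx_f": dWx_f,
            "Wh_f": dWh_f,
            "b_f": db_f,
            "Wx_b": dWx_b,
            "Wh_b": dWh_b,
            "b_b": db_b,
        }


# ---------------------------------------------------------------------------
# Fully connected head with ReLU + inverted dropout
# ---------------------------------------------------------------------------

class MLPHead:
    """Dense stack: hidden layers with ReLU and dropout, then a linear output."""

    def __init__(self, in_dim: int, hidden_widths: tuple[int, ...], out_dim: int, dropout: float):
        self.widths = (in_dim, *hidden_widths, out_dim)
        self.dropout = dropout
        self.n_layers = len(self.widths) - 1

    def param_names(self) -> list[str]:
        return [f"{kind}{i}" for i in range(self.n_layers) for kind in ("W", "b")]

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params = {}
        for i in range(self.n_layers):
            params[f"W{i}"] = glorot(rng, self.widths[i], self.widths[i + 1])
            params[f"b{i}"] = np.zeros(self.widths[i + 1])
        return params

    def forward(self, x: np.ndarray, params, train: bool = False, rng: np.random.Generator | None = None):
        if x.ndim != 2 or x.shape[1] != self.widths[0]:
            raise ShapeError(f"head expected (batch, {self.widths[0]}), got {x.shape}")
        caches = []
        a = x
        for i in range(self.n_layers):
            z = a @ params[f"W{i}"] + params[f"b{i}"]
            if i < self.n_layers - 1:
                relu_mask = z > 0
                h = z * relu_mask
                if train and self.dropout > 0:
                    keep = 1.0 - self.dropout
                    drop_mask = (rng.random(h.shape) < keep) / keep
                    h = h * drop_mask
                else:
                    drop_mask = None
                caches.append((a, relu_mask, drop_mask))
                a = h
            else:
                caches.append((a, None, None))
                a = z
        return a, caches

    def backward(self, dout: np.ndarray, params, caches):
        grads = {}
        da = dout
        for i in range(self.n_layers - 1, -1, -1):
            a_in, relu_mask, drop_mask = caches[i]
            dz = da
            if relu_mask is not None:
                if drop_mask is not None:
                    dz = dz * drop_mask
                dz = dz * relu_mask
            grads[f"W{i}"] = a_in.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            da = dz @ params[f"W{i}"].T
        return grads, da


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None):
    """Mean weighted binary cross-entropy; returns (loss, dlogits)."""
    z = logits.ravel()
    y = y.ravel().astype(np.float64)
    if sample_weight is None:
        w = np.ones_like(z)
    else:
        w = sample_weight.ravel()
    wsum = w.sum()
    # log(1+e^z) computed stably
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.sum(w * (softplus - y * z)) / wsum)
    dz = (w * (_sigmoid(z) - y) / wsum).reshape(logits.shape)
    return loss, dz


def masked_mse(pred: np.ndarray, y: np.ndarray, mask: np.ndarray):
    """MSE over entries where mask is truthy; returns (loss, dpred)."""
    mask = mask.astype(np.float64)
    denom = mask.sum()
    if denom == 0:
        return 0.0, np.zeros_like(pred)
    diff = (pred - y) * mask
    loss = float(np.sum(diff * diff) / denom)
    dpred = 2.0 * diff / denom
    return loss, dpred


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled (AdamW-style) weight decay on matrix parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.weight_decay and params[k].ndim >= 2:  # decay weights, not biases
                params[k] -= self.lr * self.weight_decay * params[k]
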