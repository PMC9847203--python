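"""Numpy implementation of the layer stack and its gradients.

Everything here is deliberately plain: parameters live in a dict of numpy
arrays, the forward pass caches what the backward pass needs, and training
uses minibatch Adam on the binary cross-entropy.  The stack is

    embedding -> Bi-LSTM (full sequence, fwd||bwd) ->
    [conv1d(k) -> ReLU -> dropout  for each kernel size k] ->
    concat along the length axis -> flatten ->
    dense -> ReLU -> dropout -> dense -> ReLU -> dense(1) -> sigmoid

Convolutions are stride-1 "valid" (no padding), so a kernel of width k over
a length-L input yields L-k+1 positions.  The LSTM uses one bias vector per
gate, gate order (g, i, f, o): candidate, input, forget, output.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def init_params(cfg, seed: int) -> dict[str, np.ndarray]:
    """Initialise all trainable arrays from a single integer seed.

    Standard-normal embedding vectors, Glorot-uniform input/dense/conv
    kernels, orthogonal LSTM recurrent kernels, zero biases except the LSTM
    forget-gate bias which starts at 1.  The unit-scale embedding matters:
    a small-range init starves the LSTM of input variance and the whole
    stack can sit on the chance plateau for many epochs.
    """
    rng = np.random.default_rng(seed)
    E, H, F = cfg.embed_dim, cfg.lstm_units, cfg.filters
    p: dict[str, np.ndarray] = {}
    p["emb"] = rng.normal(0.0, 1.0, size=(cfg.vocab_size, E))
    for d in ("f", "b"):
        p[f"lstm_{d}_Wx"] = _glorot(rng, (E, 4 * H), E, 4 * H)
        p[f"lstm_{d}_Wh"] = np.concatenate(
            [_orthogonal(rng, H) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * H)
        b[2 * H : 3 * H] = 1.0  # forget gate
        p[f"lstm_{d}_b"] = b
    cin = 2 * H
    for k in cfg.kernel_sizes:
        p[f"conv{k}_W"] = _glorot(rng, (k, cin, F), k * cin, k * F)
        p[f"conv{k}_b"] = np.zeros(F)
    flat = sum(cfg.seq_len - k + 1 for k in cfg.kernel_sizes) * F
    widths = [flat, *cfg.dense_widths, cfg.output_units]
    for i, (win, wout) in enumerate(zip(widths[:-1], widths[1:]), start=1):
        p[f"dense{i}_W"] = _glorot(rng, (win, wout), win, wout)
        p[f"dense{i}_b"] = np.zeros(wout)
    return p


# ---------------------------------------------------------------------------
# LSTM


def _lstm_direction(E: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run one LSTM direction over (B, L, E) input; return (B, L, H) + cache."""
    B, L, _ = E.shape
    H = Wh.shape[0]
    Xp = E @ Wx + b
    h = np.zeros((B, H))
    s = np.zeros((B, H))
    Hs = np.empty((B, L, H))
    cache = []
    for t in range(L):
        a = Xp[:, t] + h @ Wh
        g = np.tanh(a[:, :H])
        i = sigmoid(a[:, H : 2 * H])
        f = sigmoid(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        s_new = g * i + s * f
        ts = np.tanh(s_new)
        cache.append((h, s, g, i, f, o, ts))
        h = ts * o
        s = s_new
        Hs[:, t] = h
    return Hs, cache


def _lstm_direction_backward(E, cache, dHs, Wx, Wh):
    B, L, _ = E.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dE = np.zeros_like(E)
    dh = np.zeros((B, H))
    ds = np.zeros((B, H))
    for t in range(L - 1, -1, -1):
        h_prev, s_prev, g, i, f, o, ts = cache[t]
        dh_t = dHs[:, t] + dh
        do = dh_t * ts
        ds = ds + dh_t * o * (1.0 - ts * ts)
        dg = ds * i
        di = ds * g
        df = ds * s_prev
        ds = ds * f
        da = np.concatenate(
            [
                dg * (1.0 - g * g),
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += E[:, t].T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dE[:, t] = da @ Wx.T
        dh = da @ Wh.T
    return dE, dWx, dWh, db


# ---------------------------------------------------------------------------
# Convolution (stride 1, valid)


def conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """X (B, L, C), W (k, C, F) -> (B, L-k+1, F)."""
    k = W.shape[0]
    win = sliding_window_view(X, k, axis=1)  # (B, O, C, k)
    return np.einsum("bock,kcf->bof", win, W, optimize=True) + b


def conv1d_backward(X: np.ndarray, W: np.ndarray, dZ: np.ndarray):
    k = W.shape[0]
    O = dZ.shape[1]
    win = sliding_window_view(X, k, axis=1)
    dW = np.einsum("bock,bof->kcf", win, dZ, optimize=True)
    db = dZ.sum(axis=(0, 1))
    dX = np.zeros_like(X)
    for j in range(k):
        dX[:, j : j + O, :] += dZ @ W[j].T
    return dX, dW, db


# ---------------------------------------------------------------------------
# Full network


class MultiScaleNet:
    """Forward/backward engine for the multi-scale architecture.

    Parameters are owned by the caller (a plain dict); this class only
    stores the architecture configuration.
    """

    def __init__(self, cfg):
        self.cfg = cfg

    def forward(
        self,
        params: dict[str, np.ndarray],
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (probabilities, logits, cache).  Dropout only when training."""
        cfg = self.cfg
        H = cfg.lstm_units
        Emb = params["emb"][X]  # (B, L, E)
        Hf, cache_f = _lstm_direction(
            Emb, params["lstm_f_Wx"], params["lstm_f_Wh"], params["lstm_f_b"]
        )
        Hb_rev, cache_b = _lstm_direction(
            Emb[:, ::-1], params["lstm_b_Wx"], params["lstm_b_Wh"], params["lstm_b_b"]
        )
        Hb = Hb_rev[:, ::-1]
        Hseq = np.concatenate([Hf, Hb], axis=2)  # (B, L, 2H)

        branch_out = []
        branch_cache = []
        for k in cfg.kernel_sizes:
            Z = conv1d_forward(Hseq, params[f"conv{k}_W"], params[f"conv{k}_b"])
            A = np.maximum(Z, 0.0)
            if train and cfg.branch_dropout > 0.0:
                mask = (rng.random(A.shape) >= cfg.branch_dropout) / (
                    1.0 - cfg.branch_dropout
                )
                D = A * mask
            else:
                mask = None
                D = A
            branch_out.append(D)
            branch_cache.append((Z, mask))
        C = np.concatenate(branch_out, axis=1)
        flat = C.reshape(C.shape[0], -1)

        z1 = flat @ params["dense1_W"] + params["dense1_b"]
        a1 = np.maximum(z1, 0.0)
        if train and cfg.head_dropout > 0.0:
            mask1 = (rng.random(a1.shape) >= cfg.head_dropout) / (1.0 - cfg.head_dropout)
            d1 = a1 * mask1
        else:
            mask1 = None
            d1 = a1
        z2 = d1 @ params["dense2_W"] + params["dense2_b"]
        a2 = np.maximum(z2, 0.0)
        logits = (a2 @ params["dense3_W"] + params["dense3_b"]).ravel()
        probs = sigmoid(logits)
        cache = {
            "X": X,
            "Emb": Emb,
            "cache_f": cache_f,
            "cache_b": cache_b,
            "Hseq": Hseq,
            "branch_cache": branch_cache,
            "flat": flat,
            "z1": z1,
            "mask1": mask1,
            "d1": d1,
            "z2": z2,
            "a2": a2,
        }
        return probs, logits, cache

    def backward(
        self, params: dict[str, np.ndarray], cache: dict, dlogits: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss w.r.t. every parameter array."""
        cfg = self.cfg
        H = cfg.lstm_units
        grads: dict[str, np.ndarray] = {}

        dlog = dlogits[:, None]  # (B, 1)
        grads["dense3_W"] = cache["a2"].T @ dlog
        grads["dense3_b"] = dlog.sum(axis=0)
        da2 = dlog @ params["dense3_W"].T
        dz2 = da2 * (cache["z2"] > 0)
        grads["dense2_W"] = cache["d1"].T @ dz2
        grads["dense2_b"] = dz2.sum(axis=0)
        dd1 = dz2 @ params["dense2_W"].T
        if cache["mask1"] is not None:
            dd1 = dd1 * cache["mask1"]
        dz1 = dd1 * (cache["z1"] > 0)
        grads["dense1_W"] = cache["flat"].T @ dz1
        grads["dense1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ params["dense1_W"].T

        B = dflat.shape[0]
        lengths = [cfg.seq_len - k + 1 for k in cfg.kernel_sizes]
        dC = dflat.reshape(B, sum(lengths), cfg.filters)
        dHseq = np.zeros_like(cache["Hseq"])
        offset = 0
        for k, L_k, (Z, mask) in zip(cfg.kernel_sizes, lengths, cache["branch_cache"]):
            dD = dC[:, offset : offset + L_k]
            offset += L_k
            dA = dD * mask if mask is not None else dD
            dZ = dA * (Z > 0)
            dX, dW, db = conv1d_backward(cache["Hseq"], params[f"conv{k}_W"], dZ)
            dHseq += dX
            grads[f"conv{k}_W"] = dW
            grads[f"conv{k}_b"] = db

        dHf = dHseq[:, :, :H]
        dHb = dHseq[:, :, H:]
        Emb = cache["Emb"]
        dE_f, dWx_f, dWh_f, db_f = _lstm_direction_backward(
            Emb, cache["cache_f"], dHf, params["lstm_f_Wx"], params["lstm_f_Wh"]
        )
        dE_b_rev, dWx_b, dWh_b, db_b = _lstm_direction_backward(
            Emb[:, ::-1], cache["cache_b"], dHb[:, ::-1],
            params["lstm_b_Wx"], params["lstm_b_Wh"],
        )
        grads["lstm_f_Wx"], grads["lstm_f_Wh"], grads["lstm_f_b"] = dWx_f, dWh_f, db_f
        grads["lstm_b_Wx"], grads["lstm_b_Wh"], grads["lstm_b_b"] = dWx_b, dWh_b, db_b
        dEmb = dE_f + dE_b_rev[:, ::-1]

        demb = np.zeros_like(params["emb"])
        np.add.at(demb, cache["X"].ravel(), dEmb.reshape(-1, cfg.embed_dim))
        grads["emb"] = demb
        return grads


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy from logits; returns (loss, dlogits)."""
    n = logits.shape[0]
    # log(1 + exp(-|z|)) formulation, numerically stable
    loss = np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    dlogits = (sigmoid(logits) - y) / n
    return loss, dlogits


class Adam:
    """Minibatch Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * (g * g)
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
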