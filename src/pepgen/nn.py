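"""Minimal numpy LSTM with backpropagation through time.

Implements exactly what the character-level peptide model needs: stacked
unidirectional LSTM layers with per-layer output dropout, a dense softmax
head, masked categorical cross-entropy, and an Adam optimiser.  All
randomness flows through an explicit ``numpy.random.Generator`` so training
is bit-reproducible from a seed.

Gate layout in the fused weight matrices is ``[input, forget, cell, output]``
with the forget-gate bias initialised to a fixed positive value, which keeps
early gradients alive on short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def masked_cross_entropy(
    targets: np.ndarray,
    predictions: np.ndarray,
    mask: np.ndarray | None = None,
    epsilon: float = 0.0,
) -> float:
    """Mean categorical cross-entropy, in nats, over unmasked positions.

    ``targets`` is one-hot and ``predictions`` row-stochastic, both of shape
    ``(..., K)``; ``mask`` broadcasts over the leading axes.  A zero (or
    negative) predicted probability at a target position raises unless a
    positive ``epsilon`` clip is supplied.
    """
    targets = np.asarray(targets, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if targets.shape != predictions.shape:
        raise ValueError("targets and predictions must have identical shapes")
    row_sums = predictions.sum(axis=-1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("prediction rows must sum to 1 within 1e-6")
    p_at_target = (targets * predictions).sum(axis=-1)
    active = targets.sum(axis=-1) > 0
    if mask is not None:
        active = active & np.asarray(mask, dtype=bool)
    if not active.any():
        return 0.0
    p = p_at_target[active]
    if epsilon > 0:
        p = np.clip(p, epsilon, 1.0)
    elif (p <= 0).any():
        raise FloatingPointError(
            "zero predicted probability at a target position; "
            "set a positive epsilon to clip"
        )
    return float(-np.log(p).mean())


@dataclass
class LSTMParams:
    """Fused parameters for one LSTM layer: ``z = x Wx + h Wh + b``."""

    Wx: np.ndarray  # (input_dim, 4H)
    Wh: np.ndarray  # (H, 4H)
    b: np.ndarray   # (4H,)

    @property
    def hidden(self) -> int:
        return self.Wh.shape[0]


@dataclass
class DenseParams:
    W: np.ndarray  # (H, K)
    b: np.ndarray  # (K,)


def glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def init_lstm_layer(
    rng: np.random.Generator, input_dim: int, hidden: int, forget_bias: float
) -> LSTMParams:
    Wx = glorot(rng, (input_dim, 4 * hidden))
    Wh = glorot(rng, (hidden, 4 * hidden))
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = forget_bias
    return LSTMParams(Wx=Wx, Wh=Wh, b=b)


def init_dense(rng: np.random.Generator, hidden: int, classes: int) -> DenseParams:
    return DenseParams(W=glorot(rng, (hidden, classes)), b=np.zeros(classes))


@dataclass
class _LayerCache:
    x: np.ndarray       # (T, N, D) layer inputs
    i: np.ndarray       # gate activations, each (T, N, H)
    f: np.ndarray
    g: np.ndarray
    o: np.ndarray
    c: np.ndarray       # (T+1, N, H) cell states, c[0] initial
    h: np.ndarray       # (T+1, N, H) hidden states
    drop_mask: np.ndarray | None  # (T, N, H) inverted-dropout mask or None


def lstm_forward(
    params: LSTMParams,
    x: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, _LayerCache]:
    """Run one layer over ``x`` of shape (T, N, D); returns (T, N, H) outputs.

    Dropout (inverted, resampled each step) is applied to the layer output
    only when ``rng`` is given, i.e. during training.
    """
    T, N, _ = x.shape
    H = params.hidden
    i_s = np.empty((T, N, H)); f_s = np.empty((T, N, H))
    g_s = np.empty((T, N, H)); o_s = np.empty((T, N, H))
    c_s = np.zeros((T + 1, N, H)); h_s = np.zeros((T + 1, N, H))
    out = np.empty((T, N, H))
    drop_mask = None
    training = dropout > 0.0 and rng is not None
    if training:
        drop_mask = (rng.random((T, N, H)) >= dropout) / (1.0 - dropout)
    for t in range(T):
        z = x[t] @ params.Wx + h_s[t] @ params.Wh + params.b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c = f * c_s[t] + i * g
        h = o * np.tanh(c)
        i_s[t], f_s[t], g_s[t], o_s[t] = i, f, g, o
        c_s[t + 1], h_s[t + 1] = c, h
        out[t] = h * drop_mask[t] if training else h
    cache = _LayerCache(x=x, i=i_s, f=f_s, g=g_s, o=o_s, c=c_s, h=h_s,
                        drop_mask=drop_mask)
    return out, cache


def lstm_backward(
    params: LSTMParams, cache: _LayerCache, dout: np.ndarray
) -> tuple[LSTMParams, np.ndarray]:
    """BPTT for one layer; returns (gradients, dX of shape (T, N, D))."""
    T, N, H = cache.i.shape
    dWx = np.zeros_like(params.Wx)
    dWh = np.zeros_like(params.Wh)
    db = np.zeros_like(params.b)
    dx = np.empty_like(cache.x)
    dh_next = np.zeros((N, H))
    dc_next = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        dh = dout[t] + dh_next
        if cache.drop_mask is not None:
            dh = dout[t] * cache.drop_mask[t] + dh_next
        i, f, g, o = cache.i[t], cache.f[t], cache.g[t], cache.o[t]
        c, c_prev = cache.c[t + 1], cache.c[t]
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += cache.x[t].T @ dz
        dWh += cache.h[t].T @ dz
        db += dz.sum(axis=0)
        dx[t] = dz @ params.Wx.T
        dh_next = dz @ params.Wh.T
    return LSTMParams(Wx=dWx, Wh=dWh, b=db), dx


@dataclass
class AdamState:
    """Per-parameter first/second moment accumulators."""

    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    t: int = 0


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-7,
) -> None:
    """In-place Adam update over a flat name -> array parameter dict."""
    state.t += 1
    t = state.t
    for name, p in params.items():
        g = grads[name]
        m = state.m.setdefault(name, np.zeros_like(p))
        v = state.v.setdefault(name, np.zeros_like(p))
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** t)
        vhat = v / (1 - beta2 ** t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)
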