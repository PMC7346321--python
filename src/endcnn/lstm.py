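"""LSTM and bidirectional LSTM encoders with hand-written backpropagation.

Standard LSTM cell with input/forget/output gates and a tanh candidate,
no peepholes:

    [i; f; o; g] = W [x_t; h_{t-1}] + b,   i, f, o = sigmoid, g = tanh
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)

The bidirectional encoder runs two independently parameterized cells over
the sequence left-to-right and right-to-left and concatenates
``h_t = [h_fwd_t ; h_bwd_t]``. The forget-gate bias is initialized to 1.0,
a common stability default for gated recurrences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """Weights of one direction: ``W`` is ``4H x (d + H)``, gate order
    [input, forget, output, candidate]; ``b`` is ``4H``."""

    W: np.ndarray
    b: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0] // 4

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator,
             scale: float = 0.1) -> "LSTMParams":
        W = rng.uniform(-scale, scale, size=(4 * hidden, input_dim + hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget bias
        return cls(W, b)


def lstm_forward(X: np.ndarray, params: LSTMParams) -> tuple[np.ndarray, dict]:
    """Run the cell over ``X`` (n x d); returns (n x H hidden states, cache)."""
    n, d = X.shape
    H = params.hidden_size
    hs = np.zeros((n, H))
    cache = {"X": X, "gates": np.zeros((n, 4 * H)), "c": np.zeros((n, H)),
             "tanh_c": np.zeros((n, H)), "xh": np.zeros((n, d + H)),
             "params": params}
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(n):
        xh = cache["xh"][t]
        xh[:d] = X[t]
        xh[d:] = h
        z = params.W @ xh + params.b
        z[: 3 * H] = _sigmoid(z[: 3 * H])
        i, f, o = z[:H], z[H : 2 * H], z[2 * H : 3 * H]
        g = np.tanh(z[3 * H :])
        z[3 * H :] = g
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[t] = h
        cache["gates"][t] = z
        cache["c"][t] = c
        cache["tanh_c"][t] = tc
    return hs, cache


def lstm_backward(dhs: np.ndarray, cache: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backprop through :func:`lstm_forward`.

    ``dhs`` is the gradient w.r.t. the hidden-state matrix. Returns
    ``(dX, dW, db)``.
    """
    X = cache["X"]
    params: LSTMParams = cache["params"]
    n, d = X.shape
    H = params.hidden_size
    c_prev = np.zeros((n, H))
    if n > 1:
        c_prev[1:] = cache["c"][:-1]

    dZ = np.zeros((n, 4 * H))
    dX = np.zeros_like(X)
    Wt = params.W.T
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(n - 1, -1, -1):
        gates = cache["gates"][t]
        i, f = gates[:H], gates[H : 2 * H]
        o, g = gates[2 * H : 3 * H], gates[3 * H :]
        tc = cache["tanh_c"][t]
        dh = dhs[t] + dh_next
        dc = dc_next + dh * o * (1.0 - tc**2)
        dz = dZ[t]
        dz[:H] = dc * g * i * (1.0 - i)              # input gate
        dz[H : 2 * H] = dc * c_prev[t] * f * (1.0 - f)  # forget gate
        dz[2 * H : 3 * H] = dh * tc * o * (1.0 - o)  # output gate
        dz[3 * H :] = dc * i * (1.0 - g**2)          # candidate
        dxh = Wt @ dz
        dX[t] = dxh[:d]
        dh_next = dxh[d:]
        dc_next = dc * f
    dW = dZ.T @ cache["xh"]
    db = dZ.sum(axis=0)
    return dX, dW, db


@dataclass
class BiLSTMParams:
    forward: LSTMParams
    backward: LSTMParams

    @property
    def hidden_size(self) -> int:
        return self.forward.hidden_size

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator) -> "BiLSTMParams":
        return cls(LSTMParams.init(input_dim, hidden, rng),
                   LSTMParams.init(input_dim, hidden, rng))


def bilstm_encode(X: np.ndarray, params: BiLSTMParams) -> np.ndarray:
    """Encode ``X`` (n x d) into ``n x 2H`` states, forward half first."""
    hs, _ = bilstm_forward(X, params)
    return hs


def bilstm_forward(X: np.ndarray, params: BiLSTMParams) -> tuple[np.ndarray, dict]:
    n = X.shape[0]
    if n == 0:
        return np.zeros((0, 2 * params.hidden_size)), {"empty": True}
    hf, cache_f = lstm_forward(X, params.forward)
    hb_rev, cache_b = lstm_forward(X[::-1], params.backward)
    hs = np.concatenate([hf, hb_rev[::-1]], axis=1)
    return hs, {"f": cache_f, "b": cache_b, "empty": False}


def bilstm_backward(
    dhs: np.ndarray, cache: dict, params: BiLSTMParams
) -> tuple[np.ndarray, BiLSTMParams]:
    """Returns (dX, gradient-structured BiLSTMParams)."""
    H = params.hidden_size
    dXf, dWf, dbf = lstm_backward(dhs[:, :H], cache["f"])
    dXb_rev, dWb, dbb = lstm_backward(dhs[::-1, H:], cache["b"])
    dX = dXf + dXb_rev[::-1]
    return dX, BiLSTMParams(LSTMParams(dWf, dbf), LSTMParams(dWb, dbb))
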