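"""Functional LSTM cell with explicitly named gate blocks.

One step of the standard LSTM recurrence::

    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)      input gate
    g_t = tanh   (W_xg x_t + W_hg h_{t-1} + b_g)      candidate
    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)      forget gate
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)      output gate
    C_t = f_t ∘ C_{t-1} + i_t ∘ g_t
    h_t = o_t ∘ tanh(C_t)

This purely functional form backs the oracle tests for the trainable
layer in :mod:`ecgstress._layers`; the two are written independently.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._layers import sigmoid

_GATES = ("i", "g", "f", "o")


@dataclass(frozen=True)
class LSTMState:
    """Hidden state h and cell state C, each of length ``hidden``."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, hidden: int) -> "LSTMState":
        return cls(h=np.zeros(hidden), c=np.zeros(hidden))


@dataclass(frozen=True)
class LSTMWeights:
    """Per-gate weight blocks.

    ``w_x*`` are ``hidden × input_dim``, ``w_h*`` are ``hidden × hidden``
    and ``b_*`` length ``hidden``.  Stacking the four input blocks
    row-wise gives the ``4·hidden × input_dim`` matrix of the canonical
    architecture table (800 × 11532 at hidden 200, input 11532).
    """

    w_xi: np.ndarray
    w_xg: np.ndarray
    w_xf: np.ndarray
    w_xo: np.ndarray
    w_hi: np.ndarray
    w_hg: np.ndarray
    w_hf: np.ndarray
    w_ho: np.ndarray
    b_i: np.ndarray
    b_g: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray

    @property
    def hidden(self) -> int:
        return self.w_xi.shape[0]

    @property
    def input_dim(self) -> int:
        return self.w_xi.shape[1]

    def validate(self) -> None:
        h, d = self.hidden, self.input_dim
        for gate in _GATES:
            for prefix, shape in (("w_x", (h, d)), ("w_h", (h, h)), ("b_", (h,))):
                name = prefix + gate
                block = np.asarray(getattr(self, name))
                if block.shape != shape:
                    raise ValueError(
                        f"block {name} has shape {block.shape}, expected {shape}"
                    )

    def stacked_input(self) -> np.ndarray:
        """4·hidden × input_dim block, gate order (i, g, f, o)."""
        return np.vstack([self.w_xi, self.w_xg, self.w_xf, self.w_xo])

    def stacked_recurrent(self) -> np.ndarray:
        return np.vstack([self.w_hi, self.w_hg, self.w_hf, self.w_ho])

    def stacked_bias(self) -> np.ndarray:
        """4·hidden × 1 bias column."""
        return np.concatenate([self.b_i, self.b_g, self.b_f, self.b_o])[:, None]

    @classmethod
    def zeros(cls, hidden: int, input_dim: int) -> "LSTMWeights":
        kw = {}
        for gate in _GATES:
            kw["w_x" + gate] = np.zeros((hidden, input_dim))
            kw["w_h" + gate] = np.zeros((hidden, hidden))
            kw["b_" + gate] = np.zeros(hidden)
        return cls(**kw)

    @classmethod
    def random(cls, hidden: int, input_dim: int, rng: np.random.Generator, scale: float = 0.5) -> "LSTMWeights":
        kw = {}
        for gate in _GATES:
            kw["w_x" + gate] = rng.normal(0, scale, (hidden, input_dim))
            kw["w_h" + gate] = rng.normal(0, scale, (hidden, hidden))
            kw["b_" + gate] = rng.normal(0, scale, hidden)
        return cls(**kw)


def lstm_cell_step(x_t: np.ndarray, state: LSTMState, w: LSTMWeights) -> LSTMState:
    """One LSTM step; purely functional (inputs are never mutated)."""
    w.validate()
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (w.input_dim,):
        raise ValueError(f"x_t has shape {x_t.shape}, expected ({w.input_dim},)")
    if state.h.shape != (w.hidden,) or state.c.shape != (w.hidden,):
        raise ValueError(
            f"state shapes {state.h.shape}/{state.c.shape} do not match hidden {w.hidden}"
        )
    i = sigmoid(w.w_xi @ x_t + w.w_hi @ state.h + w.b_i)
    g = np.tanh(w.w_xg @ x_t + w.w_hg @ state.h + w.b_g)
    f = sigmoid(w.w_xf @ x_t + w.w_hf @ state.h + w.b_f)
    o = sigmoid(w.w_xo @ x_t + w.w_ho @ state.h + w.b_o)
    c = f * state.c + i * g
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)
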