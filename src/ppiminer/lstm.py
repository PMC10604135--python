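"""Reference LSTM/BiLSTM recurrence operations.

These are the mathematical definition of one LSTM cell step and of a
bidirectional pass, written for clarity on single sequences. The trainable
network in :mod:`ppiminer.nn` vectorizes the same arithmetic over batches;
the test suite checks the two agree on shared parameters.

Gate equations for one step (``@`` is a matrix-vector product, ``*``
elementwise, sigma the logistic function):

    i_t = sigma(W_ix @ x_t + W_ih @ h_{t-1} + b_i)      input gate
    f_t = sigma(W_fx @ x_t + W_fh @ h_{t-1} + b_f)      forget gate
    o_t = sigma(W_ox @ x_t + W_oh @ h_{t-1} + b_o)      output gate
    c_t = f_t * c_{t-1} + i_t * tanh(W_cx @ x_t + W_ch @ h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)

The bidirectional pass runs one cell left-to-right and a second cell
right-to-left and joins their hidden states linearly at each position:

    y_t = W_fy @ h_fwd_t + W_by @ h_bwd_t + b_y
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LSTMParams", "BiLSTMParams", "lstm_step", "lstm_sequence", "bilstm_sequence", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMParams:
    """Per-gate weight matrices and biases of one LSTM cell.

    ``W_*x`` have shape ``(units, input_dim)``, ``W_*h`` shape
    ``(units, units)``, biases shape ``(units,)``.
    """

    W_ix: np.ndarray
    W_ih: np.ndarray
    W_fx: np.ndarray
    W_fh: np.ndarray
    W_ox: np.ndarray
    W_oh: np.ndarray
    W_cx: np.ndarray
    W_ch: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        u, d = self.W_ix.shape
        for name in ("W_fx", "W_ox", "W_cx"):
            if getattr(self, name).shape != (u, d):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != ({u}, {d})")
        for name in ("W_ih", "W_fh", "W_oh", "W_ch"):
            if getattr(self, name).shape != (u, u):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != ({u}, {u})")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            if getattr(self, name).shape != (u,):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != ({u},)")

    @property
    def units(self) -> int:
        return self.W_ix.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_ix.shape[1]

    @classmethod
    def random(cls, input_dim: int, units: int, rng: np.random.Generator, scale: float = 0.5) -> "LSTMParams":
        def w(*shape):
            return rng.uniform(-scale, scale, size=shape)

        return cls(
            W_ix=w(units, input_dim), W_ih=w(units, units),
            W_fx=w(units, input_dim), W_fh=w(units, units),
            W_ox=w(units, input_dim), W_oh=w(units, units),
            W_cx=w(units, input_dim), W_ch=w(units, units),
            b_i=w(units), b_f=w(units), b_o=w(units), b_c=w(units),
        )


def lstm_step(
    p: LSTMParams, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns ``(h_t, c_t)``."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x_t.shape != (p.input_dim,):
        raise ValueError(f"x_t shape {x_t.shape} != ({p.input_dim},)")
    if h_prev.shape != (p.units,) or c_prev.shape != (p.units,):
        raise ValueError(f"state shapes {h_prev.shape}/{c_prev.shape} != ({p.units},)")
    i = sigmoid(p.W_ix @ x_t + p.W_ih @ h_prev + p.b_i)
    f = sigmoid(p.W_fx @ x_t + p.W_fh @ h_prev + p.b_f)
    o = sigmoid(p.W_ox @ x_t + p.W_oh @ h_prev + p.b_o)
    c_t = f * c_prev + i * np.tanh(p.W_cx @ x_t + p.W_ch @ h_prev + p.b_c)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def lstm_sequence(p: LSTMParams, xs: np.ndarray) -> np.ndarray:
    """Run the cell over a ``(T, input_dim)`` sequence from zero state;
    returns the ``(T, units)`` hidden-state sequence."""
    xs = np.asarray(xs, dtype=np.float64)
    h = np.zeros(p.units)
    c = np.zeros(p.units)
    out = np.empty((len(xs), p.units))
    for t, x_t in enumerate(xs):
        h, c = lstm_step(p, x_t, h, c)
        out[t] = h
    return out


@dataclass
class BiLSTMParams:
    """Forward and backward cells plus the per-step output projection."""

    forward: LSTMParams
    backward: LSTMParams
    W_fy: np.ndarray
    W_by: np.ndarray
    b_y: np.ndarray

    def __post_init__(self) -> None:
        if self.forward.units != self.backward.units:
            raise ValueError("forward and backward cells must have equal units")
        out_dim = self.W_fy.shape[0]
        if self.W_fy.shape != (out_dim, self.forward.units):
            raise ValueError("W_fy shape inconsistent")
        if self.W_by.shape != (out_dim, self.backward.units):
            raise ValueError("W_by shape inconsistent")
        if self.b_y.shape != (out_dim,):
            raise ValueError("b_y shape inconsistent")

    @classmethod
    def random(cls, input_dim: int, units: int, out_dim: int, rng: np.random.Generator) -> "BiLSTMParams":
        return cls(
            forward=LSTMParams.random(input_dim, units, rng),
            backward=LSTMParams.random(input_dim, units, rng),
            W_fy=rng.uniform(-0.5, 0.5, size=(out_dim, units)),
            W_by=rng.uniform(-0.5, 0.5, size=(out_dim, units)),
            b_y=rng.uniform(-0.5, 0.5, size=out_dim),
        )

    def swapped(self) -> "BiLSTMParams":
        """The parameter set with the two directions exchanged."""
        return BiLSTMParams(
            forward=self.backward, backward=self.forward,
            W_fy=self.W_by, W_by=self.W_fy, b_y=self.b_y,
        )


def bilstm_sequence(p: BiLSTMParams, xs: np.ndarray) -> np.ndarray:
    """Bidirectional pass over a ``(T, input_dim)`` sequence.

    The forward cell reads left to right, the backward cell reads the
    reversed sequence, and per-position outputs are joined linearly.
    Raises on an empty sequence.
    """
    xs = np.asarray(xs, dtype=np.float64)
    if len(xs) == 0:
        raise ValueError("bilstm_sequence requires a non-empty sequence")
    h_fwd = lstm_sequence(p.forward, xs)
    h_bwd = lstm_sequence(p.backward, xs[::-1])[::-1]
    return h_fwd @ p.W_fy.T + h_bwd @ p.W_by.T + p.b_y
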