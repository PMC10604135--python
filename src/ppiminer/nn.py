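"""Trainable stacked-BiLSTM network: batched forward, BPTT, Adam.

This is the numerical engine behind :class:`ppiminer.classifier.
BiLSTMSentenceClassifier`. It vectorizes exactly the cell arithmetic
defined by the reference operations in :mod:`ppiminer.lstm` (the test
suite asserts the equivalence on shared parameters) and adds what
training needs: padding masks, variational input/recurrent dropout,
backpropagation through time, and the Adam update.

Conventions
-----------
* Weights per direction per layer: ``Wx (d_in, 4u)``, ``Wh (u, 4u)``,
  ``b (4u,)`` with gate blocks ordered ``[input, forget, candidate,
  output]``; forget-gate bias initialized to 1.
* Padding uses index 0, whose embedding row is zero; masked positions
  carry ``h``/``c`` through unchanged, so the forward-direction state at
  the last position equals the state at the last real token.
* The backward direction runs the fully reversed (sequence and mask)
  batch through the same masked recurrence.
* The embedding matrix is frozen; only LSTM and dense weights train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ppiminer.lstm import LSTMParams

__all__ = ["BiLSTMNetwork", "softmax", "masked_lstm_forward"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def masked_lstm_forward(Wx, Wh, b, X, mask, rec_drop=None):
    """Run one LSTM direction over a padded batch.

    Parameters: ``X (B,T,d)``, ``mask (B,T)`` in {0,1}; ``rec_drop`` is an
    optional ``(B,u)`` multiplier applied to ``h_{t-1}`` inside the
    recurrence (variational recurrent dropout). Returns ``(H, cache)``
    where ``H (B,T,u)`` holds post-mask hidden states.
    """
    B, T, _ = X.shape
    u = Wh.shape[0]
    I = np.empty((B, T, u)); F = np.empty((B, T, u))
    G = np.empty((B, T, u)); O = np.empty((B, T, u))
    Craw = np.empty((B, T, u)); C = np.empty((B, T, u)); H = np.empty((B, T, u))
    h = np.zeros((B, u)); c = np.zeros((B, u))
    for t in range(T):
        h_in = h * rec_drop if rec_drop is not None else h
        A = X[:, t] @ Wx + h_in @ Wh + b
        i = _sigmoid(A[:, :u])
        f = _sigmoid(A[:, u : 2 * u])
        g = np.tanh(A[:, 2 * u : 3 * u])
        o = _sigmoid(A[:, 3 * u :])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        m = mask[:, t : t + 1]
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
        Craw[:, t], C[:, t], H[:, t] = c_new, c, h
    cache = (X, mask, rec_drop, I, F, G, O, Craw, C, H)
    return H, cache


def _masked_lstm_backward(Wx, Wh, b, cache, dH):
    """BPTT for one direction. ``dH (B,T,u)`` is the loss gradient with
    respect to the post-mask hidden states. Returns ``(dWx, dWh, db, dX)``."""
    X, mask, rec_drop, I, F, G, O, Craw, C, H = cache
    B, T, u = dH.shape
    dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh); db = np.zeros_like(b)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, u)); dc_next = np.zeros((B, u))
    for t in range(T - 1, -1, -1):
        m = mask[:, t : t + 1]
        dh_total = dH[:, t] + dh_next
        dc_total = dc_next
        dh_prime = dh_total * m          # into the unmasked update
        dh_carry = dh_total * (1.0 - m)  # straight through to h_{t-1}
        dc_prime = dc_total * m
        dc_carry = dc_total * (1.0 - m)

        o = O[:, t]; tc = np.tanh(Craw[:, t])
        do = dh_prime * tc
        dcraw = dc_prime + dh_prime * o * (1.0 - tc ** 2)
        i, f, g = I[:, t], F[:, t], G[:, t]
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, u))
        di = dcraw * g
        df = dcraw * c_prev
        dg = dcraw * i
        dc_prev = dcraw * f

        dA = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g ** 2), do * o * (1.0 - o)],
            axis=1,
        )
        h_prev = H[:, t - 1] if t > 0 else np.zeros((B, u))
        h_prev_in = h_prev * rec_drop if rec_drop is not None else h_prev
        dWx += X[:, t].T @ dA
        dWh += h_prev_in.T @ dA
        db += dA.sum(axis=0)
        dX[:, t] = dA @ Wx.T
        dh_from_gates = dA @ Wh.T
        if rec_drop is not None:
            dh_from_gates = dh_from_gates * rec_drop
        dh_next = dh_carry + dh_from_gates
        dc_next = dc_carry + dc_prev
    return dWx, dWh, db, dX


def _reverse(X: np.ndarray) -> np.ndarray:
    return X[:, ::-1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class _Layer:
    fwd_Wx: np.ndarray; fwd_Wh: np.ndarray; fwd_b: np.ndarray
    bwd_Wx: np.ndarray; bwd_Wh: np.ndarray; bwd_b: np.ndarray

    @property
    def units(self) -> int:
        return self.fwd_Wh.shape[0]

    def params(self) -> list[np.ndarray]:
        return [self.fwd_Wx, self.fwd_Wh, self.fwd_b, self.bwd_Wx, self.bwd_Wh, self.bwd_b]

    def as_reference(self, direction: str) -> LSTMParams:
        """Export one direction as reference :class:`LSTMParams` (gate
        blocks [i, f, g, o] in the fused matrices)."""
        Wx, Wh, b = {
            "forward": (self.fwd_Wx, self.fwd_Wh, self.fwd_b),
            "backward": (self.bwd_Wx, self.bwd_Wh, self.bwd_b),
        }[direction]
        u = self.units
        blk = lambda M, k: M[:, k * u : (k + 1) * u].T
        return LSTMParams(
            W_ix=blk(Wx, 0), W_ih=blk(Wh, 0),
            W_fx=blk(Wx, 1), W_fh=blk(Wh, 1),
            W_cx=blk(Wx, 2), W_ch=blk(Wh, 2),
            W_ox=blk(Wx, 3), W_oh=blk(Wh, 3),
            b_i=b[0 * u : 1 * u], b_f=b[1 * u : 2 * u],
            b_c=b[2 * u : 3 * u], b_o=b[3 * u : 4 * u],
        )


@dataclass
class BiLSTMNetwork:
    """Embedding -> stacked BiLSTM -> dense softmax over two classes."""

    embedding: np.ndarray          # (V, d), frozen; row 0 zero padding
    layer_units: tuple[int, ...]
    dropout: float = 0.5
    recurrent_dropout: float = 0.2
    seed: int = 0
    layers: list[_Layer] = field(default_factory=list)
    dense_W: np.ndarray | None = None
    dense_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.layers:
            return
        rng = np.random.default_rng(self.seed)
        d_in = self.embedding.shape[1]
        for u in self.layer_units:
            def make(d_in=d_in, u=u):
                Wx = _glorot(rng, d_in, 4 * u, (d_in, 4 * u))
                Wh = _glorot(rng, u, 4 * u, (u, 4 * u))
                b = np.zeros(4 * u)
                b[u : 2 * u] = 1.0  # forget-gate bias
                return Wx, Wh, b

            fWx, fWh, fb = make()
            bWx, bWh, bb = make()
            self.layers.append(_Layer(fWx, fWh, fb, bWx, bWh, bb))
            d_in = 2 * u
        u_last = self.layer_units[-1]
        self.dense_W = _glorot(rng, 2 * u_last, 2, (2 * u_last, 2))
        self.dense_b = np.zeros(2)

    # -- parameter bookkeeping ------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend([self.dense_W, self.dense_b])
        return out

    def n_trainable_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward ---------------------------------------------

    def _dropout_mask(self, rng, shape, rate):
        if rate <= 0.0:
            return None
        keep = 1.0 - rate
        return (rng.random(shape) < keep).astype(np.float64) / keep

    def forward(self, ids: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Compute class probabilities for an int id batch ``(B, T)``.

        Returns ``(probs, cache)``; ``cache`` is consumed by
        :meth:`backward` when ``train`` is true.
        """
        ids = np.asarray(ids)
        B, T = ids.shape
        mask = (ids > 0).astype(np.float64)
        X = self.embedding[ids]
        caches = []
        for layer in self.layers:
            in_drop = rec_drop_f = rec_drop_b = None
            if train:
                in_drop = self._dropout_mask(rng, (B, 1, X.shape[2]), self.dropout)
                rec_drop_f = self._dropout_mask(rng, (B, layer.units), self.recurrent_dropout)
                rec_drop_b = self._dropout_mask(rng, (B, layer.units), self.recurrent_dropout)
            Xin = X * in_drop if in_drop is not None else X
            Hf, cache_f = masked_lstm_forward(layer.fwd_Wx, layer.fwd_Wh, layer.fwd_b, Xin, mask, rec_drop_f)
            Hb_rev, cache_b = masked_lstm_forward(
                layer.bwd_Wx, layer.bwd_Wh, layer.bwd_b, _reverse(Xin), _reverse(mask), rec_drop_b
            )
            Hb = _reverse(Hb_rev)
            X = np.concatenate([Hf, Hb], axis=2)
            caches.append((in_drop, cache_f, cache_b, Hf.shape[2]))
        # final representation: forward state after the last position,
        # backward state after position 0 (both carry-masked)
        feats = np.concatenate([caches[-1][1][-1][:, -1], caches[-1][2][-1][:, -1]], axis=1)
        logits = feats @ self.dense_W + self.dense_b
        probs = softmax(logits)
        cache = (ids, mask, caches, feats, probs)
        return probs, cache

    def backward(self, cache, y_true: np.ndarray) -> list[np.ndarray]:
        """Mean cross-entropy gradient for all trainable parameters, in the
        order of :meth:`parameters`."""
        ids, mask, caches, feats, probs = cache
        B, T = ids.shape
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y_true] = 1.0
        dlogits = (probs - onehot) / B
        d_dense_W = feats.T @ dlogits
        d_dense_b = dlogits.sum(axis=0)
        dfeats = dlogits @ self.dense_W.T

        grads: list[np.ndarray | None] = [None] * (6 * len(self.layers))
        dX_next: np.ndarray | None = None
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            in_drop, cache_f, cache_b, u = caches[li]
            Hshape = cache_f[-1].shape
            dHf = np.zeros(Hshape)
            dHb = np.zeros(Hshape)
            if li == len(self.layers) - 1:
                dHf[:, -1] += dfeats[:, :u]
            else:
                dHf += dX_next[:, :, :u]
            if li == len(self.layers) - 1:
                dHb_restored = np.zeros(Hshape)
                dHb_restored[:, 0] += dfeats[:, u:]
            else:
                dHb_restored = dX_next[:, :, u:].copy()
            dHb = _reverse(dHb_restored)

            dfWx, dfWh, dfb, dXf = _masked_lstm_backward(layer.fwd_Wx, layer.fwd_Wh, layer.fwd_b, cache_f, dHf)
            dbWx, dbWh, dbb, dXb_rev = _masked_lstm_backward(layer.bwd_Wx, layer.bwd_Wh, layer.bwd_b, cache_b, dHb)
            dXin = dXf + _reverse(dXb_rev)
            if in_drop is not None:
                dXin = dXin * in_drop
            dX_next = dXin
            grads[6 * li : 6 * li + 6] = [dfWx, dfWh, dfb, dbWx, dbWh, dbb]
        grads.extend([d_dense_W, d_dense_b])
        return grads  # type: ignore[return-value]

    # -- training --------------------------------------------------------

    @staticmethod
    def cross_entropy(probs: np.ndarray, y_true: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(y_true)), y_true] + eps)))

    def fit(
        self,
        ids: np.ndarray,
        labels: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        seed: int = 0,
        shuffle: bool = True,
    ) -> list[dict]:
        """Adam / categorical cross-entropy training loop.

        Returns a per-epoch history of mean loss and training accuracy.
        """
        if len(ids) == 0:
            raise ValueError("empty training set")
        ids = np.asarray(ids)
        labels = np.asarray(labels, dtype=int)
        rng = np.random.default_rng(seed)
        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        step = 0
        history = []
        for _epoch in range(epochs):
            order = rng.permutation(len(ids)) if shuffle else np.arange(len(ids))
            losses = []
            correct = 0
            for k in range(0, len(ids), batch_size):
                batch = order[k : k + batch_size]
                xb, yb = ids[batch], labels[batch]
                # trim shared trailing padding for speed
                upto = int(max(1, (xb > 0).any(axis=0).nonzero()[0].max() + 1)) if (xb > 0).any() else 1
                xb = xb[:, :upto]
                probs, cache = self.forward(xb, train=True, rng=rng)
                losses.append(self.cross_entropy(probs, yb) * len(batch))
                correct += int((probs.argmax(axis=1) == yb).sum())
                grads = self.backward(cache, yb)
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1; mi += (1 - beta1) * g
                    vi *= beta2; vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1 ** step)
                    vhat = vi / (1 - beta2 ** step)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            history.append(
                {"loss": sum(losses) / len(ids), "accuracy": correct / len(ids)}
            )
        return history

    def predict_proba(self, ids: np.ndarray, batch_size: int = 256) -> np.ndarray:
        ids = np.asarray(ids)
        out = []
        for k in range(0, len(ids), batch_size):
            xb = ids[k : k + batch_size]
            upto = int(max(1, (xb > 0).any(axis=0).nonzero()[0].max() + 1)) if (xb > 0).any() else 1
            probs, _ = self.forward(xb[:, :upto], train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)
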