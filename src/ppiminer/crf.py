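"""Linear-chain conditional random field, trained by L-BFGS.

A discriminative sequence model: the score of a tag sequence y for a
sentence x is

    score(y | x) = sum_t  w_state . f(x, t, y_t)  +  sum_t  w_trans[y_{t-1}, y_t]

and P(y | x) = exp(score) / Z(x). Training minimizes the corpus negative
log-likelihood plus an elastic-net penalty (c1 * L1 + c2 * L2, the L1 term
smoothed as sqrt(w^2 + 1e-10) so the objective stays differentiable for
L-BFGS). With ``all_possible_transitions=False`` only tag bigrams observed
in training own a transition weight; unobserved transitions are fixed at 0,
matching CRFsuite's convention.

The forward-backward recursions and marginals are vectorized over the
whole corpus (padded to the longest sentence, with carry-over masking), so
one objective evaluation is a handful of dense numpy operations plus one
sparse matmul for the feature-expectation accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

__all__ = ["LinearChainCRF"]

_L1_EPS = 1e-10


def _smoothed_l1(w: np.ndarray) -> tuple[float, np.ndarray]:
    r = np.sqrt(w * w + _L1_EPS)
    return float(r.sum()), w / r


@dataclass
class LinearChainCRF:
    """Core CRF over integer feature ids; see :mod:`ppiminer.ner` for the
    feature template and the string-level estimator."""

    c1: float = 0.1
    c2: float = 0.1
    max_iterations: int = 100
    all_possible_transitions: bool = False

    n_features_: int = field(default=0, init=False)
    n_labels_: int = field(default=0, init=False)
    state_weights_: np.ndarray | None = field(default=None, init=False)
    trans_weights_: np.ndarray | None = field(default=None, init=False)
    trans_mask_: np.ndarray | None = field(default=None, init=False)
    converged_: bool = field(default=False, init=False)
    n_iter_: int = field(default=0, init=False)

    # -- data packing ----------------------------------------------------

    def _pack_corpus(self, X: list[list[list[int]]]):
        """Flatten per-position feature-id lists into a sparse indicator
        matrix and a padded position-index tensor."""
        lengths = np.array([len(s) for s in X], dtype=int)
        total = int(lengths.sum())
        t_max = int(lengths.max())
        rows, cols = [], []
        pos = 0
        pos_index = np.zeros((len(X), t_max), dtype=int)
        valid = np.zeros((len(X), t_max), dtype=bool)
        for n, sent in enumerate(X):
            for t, feats in enumerate(sent):
                rows.extend([pos] * len(feats))
                cols.extend(feats)
                pos_index[n, t] = pos
                valid[n, t] = True
                pos += 1
        F = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(total, self.n_features_)
        )
        return F, pos_index, valid, lengths

    # -- objective -------------------------------------------------------

    def _neg_log_likelihood(self, theta, F, pos_index, valid, lengths, y_flat, emp_state, emp_trans):
        L = self.n_labels_
        n_state = self.n_features_ * L
        W = theta[:n_state].reshape(self.n_features_, L)
        T = np.zeros((L, L))
        T[self.trans_mask_] = theta[n_state:]

        S_flat = F @ W                                    # (total, L)
        N, t_max = pos_index.shape
        S = S_flat[pos_index] * valid[:, :, None]         # (N, t_max, L)

        # forward recursion with carry-over masking
        alpha = np.empty((N, t_max, L))
        alpha[:, 0] = S[:, 0]
        for t in range(1, t_max):
            nxt = logsumexp(alpha[:, t - 1][:, :, None] + T[None], axis=1) + S[:, t]
            m = valid[:, t][:, None]
            alpha[:, t] = np.where(m, nxt, alpha[:, t - 1])
        log_z = logsumexp(alpha[:, -1], axis=1)           # (N,)

        # backward recursion (in reversed padded time, carry-masked)
        beta = np.empty((N, t_max, L))
        beta[:, -1] = 0.0
        last = lengths - 1
        for t in range(t_max - 2, -1, -1):
            nxt = logsumexp(T[None] + (S[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
            m = (valid[:, t + 1] & (t + 1 <= last))[:, None]
            beta[:, t] = np.where(m, nxt, 0.0)

        # node marginals
        logp_node = alpha + beta - log_z[:, None, None]
        p_node = np.exp(logp_node) * valid[:, :, None]
        p_flat = p_node[valid]                            # (total, L) in position order

        # edge marginals accumulated into an (L, L) expectation
        exp_trans = np.zeros((L, L))
        for t in range(1, t_max):
            m = valid[:, t]
            if not m.any():
                continue
            logm = (
                alpha[m, t - 1][:, :, None]
                + T[None]
                + (S[m, t] + beta[m, t])[:, None, :]
                - log_z[m][:, None, None]
            )
            exp_trans += np.exp(logm).sum(axis=0)

        # empirical score of the gold paths
        gold = S_flat[np.arange(len(y_flat)), y_flat].sum()
        starts = np.cumsum(np.concatenate([[0], lengths[:-1]]))
        for n, ln in enumerate(lengths):
            seq = y_flat[starts[n] : starts[n] + ln]
            gold += T[seq[:-1], seq[1:]].sum()

        nll = float(log_z.sum() - gold)
        d_state = np.asarray(F.T @ p_flat) - emp_state
        d_trans = (exp_trans - emp_trans)[self.trans_mask_]

        l2 = self.c2 * float(theta @ theta)
        l1, dl1 = _smoothed_l1(theta)
        grad = np.concatenate([d_state.ravel(), d_trans]) + 2 * self.c2 * theta + self.c1 * dl1
        return nll + l2 + self.c1 * l1, grad

    # -- public API ------------------------------------------------------

    def fit(self, X: list[list[list[int]]], y: list[list[int]], n_features: int, n_labels: int):
        """Train on sentences of per-position feature-id lists with integer
        label sequences."""
        if not X:
            raise ValueError("empty training corpus")
        self.n_features_ = n_features
        self.n_labels_ = n_labels

        if self.all_possible_transitions:
            self.trans_mask_ = np.ones((n_labels, n_labels), dtype=bool)
        else:
            mask = np.zeros((n_labels, n_labels), dtype=bool)
            for seq in y:
                for a, b in zip(seq[:-1], seq[1:]):
                    mask[a, b] = True
            self.trans_mask_ = mask

        F, pos_index, valid, lengths = self._pack_corpus(X)
        y_flat = np.concatenate([np.asarray(seq, dtype=int) for seq in y])
        onehot = np.zeros((len(y_flat), n_labels))
        onehot[np.arange(len(y_flat)), y_flat] = 1.0
        emp_state = np.asarray(F.T @ onehot)
        emp_trans = np.zeros((n_labels, n_labels))
        starts = np.cumsum(np.concatenate([[0], lengths[:-1]]))
        for n, ln in enumerate(lengths):
            seq = y_flat[starts[n] : starts[n] + ln]
            np.add.at(emp_trans, (seq[:-1], seq[1:]), 1.0)

        theta0 = np.zeros(n_features * n_labels + int(self.trans_mask_.sum()))
        result = scipy.optimize.minimize(
            self._neg_log_likelihood,
            theta0,
            args=(F, pos_index, valid, lengths, y_flat, emp_state, emp_trans),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": self.max_iterations},
        )
        n_state = n_features * n_labels
        self.state_weights_ = result.x[:n_state].reshape(n_features, n_labels)
        self.trans_weights_ = np.zeros((n_labels, n_labels))
        self.trans_weights_[self.trans_mask_] = result.x[n_state:]
        self.converged_ = bool(result.success)
        self.n_iter_ = int(result.nit)
        return self

    def decode(self, sent: list[list[int]]) -> list[int]:
        """Viterbi best tag sequence for one sentence of feature-id lists."""
        if self.state_weights_ is None:
            raise RuntimeError("CRF is not fitted")
        if not sent:
            return []
        L = self.n_labels_
        S = np.stack([self.state_weights_[feats].sum(axis=0) for feats in sent])
        T = self.trans_weights_
        delta = S[0].copy()
        back = np.zeros((len(sent), L), dtype=int)
        for t in range(1, len(sent)):
            cand = delta[:, None] + T
            back[t] = cand.argmax(axis=0)
            delta = cand.max(axis=0) + S[t]
        path = [int(delta.argmax())]
        for t in range(len(sent) - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]
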