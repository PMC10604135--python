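"""BiLSTM sentence classifier: PPI-positive vs negative sentences.

Architecture (matching the stacked variant that performed best on the
AIMed/BioInfer benchmark): a frozen pretrained-embedding layer feeding
either one BiLSTM layer of 100 units or three stacked BiLSTM layers of 32
units each (dropout 0.5, recurrent dropout 0.2 per layer), topped by a
dense softmax over the two classes. Training uses Adam with categorical
cross-entropy; a predicted positive-class probability >= 0.5 labels the
sentence positive.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, fitted attributes with a trailing
underscore) so it composes with sklearn model selection, in the same way
sklearn-crfsuite wraps sequence models.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ppiminer.embeddings import DEFAULT_DIM, EmbeddingMatrix, build_embedding_matrix, build_vocab
from ppiminer.metrics import evaluate_binary
from ppiminer.nn import BiLSTMNetwork

ARTIFACT_VERSION = 1

__all__ = [
    "ClassifierConfig",
    "encode",
    "build_model",
    "BiLSTMSentenceClassifier",
    "save_classifier",
    "load_classifier",
]


@dataclass
class ClassifierConfig:
    """Hyperparameters of the sentence classification model.

    Defaults are the benchmark settings: sentences padded/truncated to 120
    tokens, 100 units for the single-layer variant or 32 units per layer
    for the 3-layer stack, dropout 0.5 / recurrent dropout 0.2, Adam at
    learning rate 1e-4, 40 epochs, batch size 128, softmax output.
    """

    max_len: int = 120
    single_layer_units: int = 100
    stacked_hidden_units: int = 32
    n_bilstm_layers: int = 3
    dropout_rate: float = 0.5
    recurrent_dropout_rate: float = 0.2
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 40
    batch_size: int = 128
    activation: str = "softmax"

    def __post_init__(self) -> None:
        if self.n_bilstm_layers not in (1, 3):
            raise ValueError("n_bilstm_layers must be 1 or 3")
        if not (0.0 <= self.dropout_rate < 1.0 and 0.0 <= self.recurrent_dropout_rate < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")

    @property
    def layer_units(self) -> tuple[int, ...]:
        if self.n_bilstm_layers == 1:
            return (self.single_layer_units,)
        return (self.stacked_hidden_units,) * self.n_bilstm_layers


def encode(
    tokens: Sequence[str], vocab: dict[str, int] | EmbeddingMatrix, max_len: int = 120
) -> np.ndarray:
    """Map tokens to vocabulary indices, post-padded with 0 to ``max_len``.

    Sequences longer than ``max_len`` are truncated at the tail; unknown
    words map to the padding index 0.
    """
    if isinstance(vocab, EmbeddingMatrix):
        vocab = vocab.vocab
    ids = np.zeros(max_len, dtype=np.int64)
    for k, tok in enumerate(tokens[:max_len]):
        ids[k] = vocab.get(tok, 0)
    return ids


def build_model(config: ClassifierConfig, embedding: EmbeddingMatrix, seed: int = 0) -> BiLSTMNetwork:
    """Assemble the untrained network for ``config`` over a frozen
    embedding matrix."""
    return BiLSTMNetwork(
        embedding=embedding.matrix,
        layer_units=config.layer_units,
        dropout=config.dropout_rate,
        recurrent_dropout=config.recurrent_dropout_rate,
        seed=seed,
    )


class BiLSTMSentenceClassifier(BaseEstimator, ClassifierMixin):
    """Sentence-level PPI classifier over token-string sequences.

    Parameters mirror :class:`ClassifierConfig`; ``vector_file`` points to
    a plain-text word-vector file (one ``word v1 .. v_d`` line per word)
    used to initialize the frozen embedding layer, with seeded
    uniform(-0.25, 0.25) rows for out-of-vocabulary words.

    Fitted attributes: ``embedding_`` (vocabulary + weight matrix),
    ``network_`` (trained parameters), ``history_`` (per-epoch loss and
    accuracy), ``classes_``.
    """

    def __init__(
        self,
        max_len: int = 120,
        n_bilstm_layers: int = 3,
        single_layer_units: int = 100,
        stacked_hidden_units: int = 32,
        dropout_rate: float = 0.5,
        recurrent_dropout_rate: float = 0.2,
        learning_rate: float = 1e-4,
        epochs: int = 40,
        batch_size: int = 128,
        embedding_dim: int = DEFAULT_DIM,
        vector_file: str | None = None,
        random_state: int = 0,
    ):
        self.max_len = max_len
        self.n_bilstm_layers = n_bilstm_layers
        self.single_layer_units = single_layer_units
        self.stacked_hidden_units = stacked_hidden_units
        self.dropout_rate = dropout_rate
        self.recurrent_dropout_rate = recurrent_dropout_rate
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.embedding_dim = embedding_dim
        self.vector_file = vector_file
        self.random_state = random_state

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            max_len=self.max_len,
            single_layer_units=self.single_layer_units,
            stacked_hidden_units=self.stacked_hidden_units,
            n_bilstm_layers=self.n_bilstm_layers,
            dropout_rate=self.dropout_rate,
            recurrent_dropout_rate=self.recurrent_dropout_rate,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
        )

    def fit(
        self,
        X: Sequence[Sequence[str]],
        y: Sequence[int],
        embedding: EmbeddingMatrix | None = None,
    ):
        """Train on token sequences ``X`` with binary labels ``y``.

        An :class:`EmbeddingMatrix` may be supplied directly; otherwise the
        vocabulary is built from ``X`` and weights come from
        ``vector_file`` (or seeded OOV rows when it is ``None``).
        """
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        y = np.asarray(y, dtype=int)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        config = self._config()
        if embedding is None:
            vocab = build_vocab(X)
            embedding = build_embedding_matrix(
                vocab, self.vector_file, dim=self.embedding_dim, seed=self.random_state
            )
        self.embedding_ = embedding
        self.network_ = build_model(config, embedding, seed=self.random_state)
        ids = np.stack([encode(toks, embedding.vocab, config.max_len) for toks in X])
        self.history_ = self.network_.fit(
            ids,
            y,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=self.random_state,
        )
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")

    def predict_proba(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        self._check_fitted()
        ids = np.stack([encode(toks, self.embedding_.vocab, self.max_len) for toks in X])
        return self.network_.predict_proba(ids)

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        """Label 1 iff the positive-class probability is >= 0.5."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_one(self, tokens: Sequence[str]) -> tuple[float, int]:
        """Convenience single-sentence call: ``(p_positive, label)``."""
        p = float(self.predict_proba([tokens])[0, 1])
        return p, int(p >= 0.5)

    def evaluate(self, X: Sequence[Sequence[str]], y: Sequence[int]) -> dict:
        """Per-class precision/recall/F1 and macro-average F1 on ``(X, y)``."""
        return evaluate_binary(list(y), list(self.predict(X)))


# ---------------------------------------------------------------------------
# Model artifact: directory with config, vocabulary, and weights


def save_classifier(clf: BiLSTMSentenceClassifier, directory: str | Path) -> None:
    clf._check_fitted()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": ARTIFACT_VERSION,
        "params": clf.get_params(),
        "config": asdict(clf._config()),
        "embedding_dim": clf.embedding_.dim,
        "layer_units": list(clf.network_.layer_units),
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    (directory / "vocab.json").write_text(json.dumps(clf.embedding_.vocab))
    (directory / "history.json").write_text(json.dumps(clf.history_))
    arrays = {"embedding": clf.embedding_.matrix}
    for li, layer in enumerate(clf.network_.layers):
        for name, arr in zip(
            ("fwd_Wx", "fwd_Wh", "fwd_b", "bwd_Wx", "bwd_Wh", "bwd_b"), layer.params()
        ):
            arrays[f"layer{li}_{name}"] = arr
    arrays["dense_W"] = clf.network_.dense_W
    arrays["dense_b"] = clf.network_.dense_b
    np.savez(directory / "weights.npz", **arrays)


def load_classifier(directory: str | Path) -> BiLSTMSentenceClassifier:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    if meta.get("format_version") != ARTIFACT_VERSION:
        raise ValueError(f"unsupported artifact version {meta.get('format_version')!r}")
    vocab = json.loads((directory / "vocab.json").read_text())
    weights = np.load(directory / "weights.npz")
    clf = BiLSTMSentenceClassifier(**meta["params"])
    embedding = EmbeddingMatrix(
        vocab=vocab, matrix=weights["embedding"], dim=meta["embedding_dim"]
    )
    clf.embedding_ = embedding
    clf.network_ = build_model(clf._config(), embedding, seed=clf.random_state)
    for li, layer in enumerate(clf.network_.layers):
        layer.fwd_Wx = weights[f"layer{li}_fwd_Wx"]
        layer.fwd_Wh = weights[f"layer{li}_fwd_Wh"]
        layer.fwd_b = weights[f"layer{li}_fwd_b"]
        layer.bwd_Wx = weights[f"layer{li}_bwd_Wx"]
        layer.bwd_Wh = weights[f"layer{li}_bwd_Wh"]
        layer.bwd_b = weights[f"layer{li}_bwd_b"]
    clf.network_.dense_W = weights["dense_W"]
    clf.network_.dense_b = weights["dense_b"]
    clf.history_ = json.loads((directory / "history.json").read_text())
    clf.classes_ = np.array([0, 1])
    return clf
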