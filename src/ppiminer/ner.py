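"""CRF protein-name tagger: features, training, tagging, evaluation.

Tokens are tagged ``P`` (part of a protein name) or ``O`` (anything
else) — deliberately no pair labels (P1/P2) and no BIO prefixes, since
sentence selection is the classifier's job and mentions are recovered as
maximal P runs.

The per-token feature template is the de-facto standard CRF-suite recipe:
lowercased word, 2- and 3-character suffixes, case/shape flags, the POS
tag and its 2-character prefix, the same block for the +-1 neighbors, and
BOS/EOS boundary flags.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ppiminer.crf import LinearChainCRF
from ppiminer.metrics import weighted_f1
from ppiminer.types import ProteinMention, TaggedSentence, Token

FEATURE_TEMPLATE_VERSION = 1
ARTIFACT_VERSION = 1

_LABELS = ("O", "P")
_LABEL_INDEX = {l: k for k, l in enumerate(_LABELS)}

__all__ = [
    "CRFConfig",
    "token_features",
    "sentence_features",
    "CRFTagger",
    "train_crf",
    "tagged_to_mentions",
    "save_tagger",
    "load_tagger",
    "weighted_f1",
]


@dataclass
class CRFConfig:
    """Training parameters of the linear-chain CRF.

    Defaults: L-BFGS with elastic-net penalties c1 = c2 = 0.1, at most 100
    iterations, transition weights only for tag bigrams observed in
    training.
    """

    algorithm: str = "lbfgs"
    c1: float = 0.1
    c2: float = 0.1
    max_iterations: int = 100
    all_possible_transitions: bool = False


def _word_block(prefix: str, word: str, pos: str) -> dict:
    return {
        f"{prefix}word.lower": word.lower(),
        f"{prefix}word.suffix3": word[-3:],
        f"{prefix}word.suffix2": word[-2:],
        f"{prefix}word.isupper": word.isupper(),
        f"{prefix}word.istitle": word.istitle(),
        f"{prefix}word.isdigit": word.isdigit(),
        f"{prefix}postag": pos,
        f"{prefix}postag2": pos[:2],
    }


def token_features(tokens: Sequence[Token], i: int) -> dict:
    """Feature map for position ``i``: the word block for the token itself
    and for its immediate neighbors, plus sentence-boundary flags."""
    if not (0 <= i < len(tokens)):
        raise IndexError(f"position {i} out of range for {len(tokens)} tokens")
    feats = {"bias": True}
    feats.update(_word_block("", tokens[i].text, tokens[i].pos))
    if i == 0:
        feats["BOS"] = True
    else:
        feats.update(_word_block("-1:", tokens[i - 1].text, tokens[i - 1].pos))
    if i == len(tokens) - 1:
        feats["EOS"] = True
    else:
        feats.update(_word_block("+1:", tokens[i + 1].text, tokens[i + 1].pos))
    return feats


def sentence_features(tokens: Sequence[Token]) -> list[dict]:
    return [token_features(tokens, i) for i in range(len(tokens))]


def _feature_strings(fmap: dict) -> list[str]:
    # booleans fire only when true; everything else is key=value
    out = []
    for k, v in fmap.items():
        if isinstance(v, bool):
            if v:
                out.append(k)
        else:
            out.append(f"{k}={v}")
    return out


class CRFTagger(BaseEstimator):
    """scikit-learn-style estimator for the P/O protein tagger.

    ``fit`` takes a list of :class:`TaggedSentence` (or ``(tokens, tags)``
    pairs); ``predict`` returns one tag sequence per input token list.
    Fitted attributes: ``model_`` (weights), ``feature_index_``.
    """

    def __init__(
        self,
        c1: float = 0.1,
        c2: float = 0.1,
        max_iterations: int = 100,
        all_possible_transitions: bool = False,
    ):
        self.c1 = c1
        self.c2 = c2
        self.max_iterations = max_iterations
        self.all_possible_transitions = all_possible_transitions

    def config(self) -> CRFConfig:
        return CRFConfig(
            c1=self.c1,
            c2=self.c2,
            max_iterations=self.max_iterations,
            all_possible_transitions=self.all_possible_transitions,
        )

    @staticmethod
    def _as_tagged(s) -> TaggedSentence:
        if isinstance(s, TaggedSentence):
            return s
        tokens, tags = s
        return TaggedSentence(tokens=list(tokens), tags=list(tags))

    def fit(self, X: Sequence, y=None):
        sentences = [self._as_tagged(s) for s in X]
        if not sentences:
            raise ValueError("empty training corpus")
        self.feature_index_: dict[str, int] = {}
        encoded: list[list[list[int]]] = []
        labels: list[list[int]] = []
        for s in sentences:
            sent_feats = []
            for fmap in sentence_features(s.tokens):
                ids = []
                for fs in _feature_strings(fmap):
                    if fs not in self.feature_index_:
                        self.feature_index_[fs] = len(self.feature_index_)
                    ids.append(self.feature_index_[fs])
                sent_feats.append(ids)
            encoded.append(sent_feats)
            labels.append([_LABEL_INDEX[t] for t in s.tags])
        self.model_ = LinearChainCRF(
            c1=self.c1,
            c2=self.c2,
            max_iterations=self.max_iterations,
            all_possible_transitions=self.all_possible_transitions,
        )
        self.model_.fit(encoded, labels, n_features=len(self.feature_index_), n_labels=len(_LABELS))
        return self

    def _encode(self, tokens: Sequence[Token]) -> list[list[int]]:
        out = []
        for fmap in sentence_features(tokens):
            out.append(
                [self.feature_index_[fs] for fs in _feature_strings(fmap) if fs in self.feature_index_]
            )
        return out

    def predict_single(self, tokens: Sequence[Token]) -> list[str]:
        """Viterbi-best tag sequence for one token list (``[]`` for ``[]``)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("tagger is not fitted")
        if not tokens:
            return []
        return [_LABELS[k] for k in self.model_.decode(self._encode(tokens))]

    def predict(self, X: Sequence[Sequence[Token]]) -> list[list[str]]:
        return [self.predict_single(tokens) for tokens in X]

    def score(self, X: Sequence, y=None) -> float:
        """Support-weighted F1 against the gold tags of ``X``."""
        sentences = [self._as_tagged(s) for s in X]
        pred = self.predict([s.tokens for s in sentences])
        return weighted_f1([s.tags for s in sentences], pred)


def train_crf(sentences: Sequence[TaggedSentence], config: CRFConfig | None = None) -> CRFTagger:
    """Train a :class:`CRFTagger` on tagged sentences."""
    config = config or CRFConfig()
    tagger = CRFTagger(
        c1=config.c1,
        c2=config.c2,
        max_iterations=config.max_iterations,
        all_possible_transitions=config.all_possible_transitions,
    )
    return tagger.fit(sentences)


def tagged_to_mentions(tokens: Sequence[Token], tags: Sequence[str]) -> list[ProteinMention]:
    """Collapse maximal runs of ``P`` into protein mentions."""
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags length mismatch")
    mentions = []
    start = None
    for i, tag in enumerate(list(tags) + ["O"]):
        if tag == "P" and start is None:
            start = i
        elif tag != "P" and start is not None:
            surface = " ".join(t.text for t in tokens[start:i])
            mentions.append(ProteinMention(start, i, surface))
            start = None
    return mentions


# ---------------------------------------------------------------------------
# Model artifact: weights file + JSON sidecar


def save_tagger(tagger: CRFTagger, directory: str | Path) -> None:
    if not hasattr(tagger, "model_"):
        raise RuntimeError("tagger is not fitted")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "format_version": ARTIFACT_VERSION,
        "feature_template_version": FEATURE_TEMPLATE_VERSION,
        "config": asdict(tagger.config()),
        "labels": list(_LABELS),
    }
    (directory / "crf_config.json").write_text(json.dumps(sidecar, indent=2))
    (directory / "features.json").write_text(json.dumps(tagger.feature_index_))
    np.savez(
        directory / "crf_weights.npz",
        state=tagger.model_.state_weights_,
        trans=tagger.model_.trans_weights_,
        trans_mask=tagger.model_.trans_mask_,
    )


def load_tagger(directory: str | Path) -> CRFTagger:
    directory = Path(directory)
    sidecar = json.loads((directory / "crf_config.json").read_text())
    if sidecar.get("format_version") != ARTIFACT_VERSION:
        raise ValueError(f"unsupported artifact version {sidecar.get('format_version')!r}")
    cfg = sidecar["config"]
    tagger = CRFTagger(
        c1=cfg["c1"],
        c2=cfg["c2"],
        max_iterations=cfg["max_iterations"],
        all_possible_transitions=cfg["all_possible_transitions"],
    )
    tagger.feature_index_ = json.loads((directory / "features.json").read_text())
    weights = np.load(directory / "crf_weights.npz")
    model = LinearChainCRF(
        c1=cfg["c1"],
        c2=cfg["c2"],
        max_iterations=cfg["max_iterations"],
        all_possible_transitions=cfg["all_possible_transitions"],
    )
    model.n_features_ = len(tagger.feature_index_)
    model.n_labels_ = len(_LABELS)
    model.state_weights_ = weights["state"]
    model.trans_weights_ = weights["trans"]
    model.trans_mask_ = weights["trans_mask"]
    tagger.model_ = model
    return tagger
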