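"""Synthetic corpora, embeddings, and gold parses for download-free testing.

Every pipeline stage can be exercised against generated data that has the
statistical structure the stages assume: positive sentences put a relation
verb between two protein names (with the verb at the parse ROOT), negative
sentences either mention a single protein or co-mention two proteins with
no relation verb. Positives and negatives are therefore linearly separable
in bag-of-words space by construction, and parse trees are hand-templated
per sentence template so no external dependency parser is needed.

The generator is a pure function of its :class:`FixtureSpec`: the same
spec yields byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ppiminer.corpus import (
    heuristic_pos_tagger,
    tag_tokens,
    write_abstracts_jsonl,
    write_conll_tagged,
    write_labeled_jsonl,
)
from ppiminer.embeddings import OOV_RANGE
from ppiminer.relations import DependencyParse, DepToken, extract_candidates, write_parse_tables
from ppiminer.network import PPIGraph, build_network
from ppiminer.types import LabeledSentence, ProteinMention, TaggedSentence, Token

__all__ = [
    "FixtureSpec",
    "GoldRecord",
    "generate_corpus",
    "generate_embedding_file",
    "fig4_fixture",
    "relation_vocabulary",
    "expected_network",
    "write_fixture_files",
]

# Real protein names exercise multiword (hyphen/slash) tokenization.
_REAL_PROTEINS = ("INTS6", "WIF-1", "USP9X", "RAPTOR", "beta-catenin")

_VERBS = (
    "binds", "activates", "inhibits", "phosphorylates", "increased",
    "decreased", "regulates", "suppresses", "stabilizes", "degrades",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic corpus."""

    n_sentences: int = 2000
    positive_fraction: float = 0.5
    n_protein_names: int = 40
    n_relation_verbs: int = 8
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_sentences, self.n_protein_names, self.n_relation_verbs) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")


@dataclass
class GoldRecord:
    """One generated sentence with its gold tags, parse, and relation word
    (non-empty exactly for positives)."""

    sentence: LabeledSentence
    tagged: TaggedSentence
    parse: DependencyParse | None
    relation_word: str = ""


def _protein_names(spec: FixtureSpec) -> list[str]:
    synthetic = [f"PRX{k + 1}" for k in range(max(0, spec.n_protein_names - len(_REAL_PROTEINS)))]
    return list(_REAL_PROTEINS[: spec.n_protein_names]) + synthetic


def relation_vocabulary(spec: FixtureSpec) -> list[str]:
    """The relation verbs positives draw from (``interacts`` is always
    present via the phrasal template)."""
    return list(_VERBS[: spec.n_relation_verbs]) + ["interacts"]


def _tokens(words: Sequence[str]) -> list[Token]:
    # POS comes from the same pluggable default tagger the pipeline applies
    # at inference time, so the CRF sees one consistent tag distribution
    return [Token(w, p) for w, p in zip(words, heuristic_pos_tagger(words))]


def _positive_verb_expression(a: str, b: str, verb: str):
    tokens = _tokens([a, verb, b, "expression"])
    parse = DependencyParse(
        [
            DepToken(a, 1, "nsubj"),
            DepToken(verb, 1, "ROOT"),
            DepToken(b, 3, "compound"),
            DepToken("expression", 1, "dobj"),
        ]
    )
    mentions = [ProteinMention(0, 1, a), ProteinMention(2, 3, b)]
    return tokens, mentions, parse, verb


def _positive_interacts(a: str, b: str, _verb: str):
    tokens = _tokens([a, "physically", "interacts", "with", b])
    parse = DependencyParse(
        [
            DepToken(a, 2, "nsubj"),
            DepToken("physically", 2, "amod"),
            DepToken("interacts", 2, "ROOT"),
            DepToken("with", 2, "prep"),
            DepToken(b, 3, "pobj"),
        ]
    )
    mentions = [ProteinMention(0, 1, a), ProteinMention(4, 5, b)]
    return tokens, mentions, parse, "interacts"


def _negative_comention(a: str, b: str):
    tokens = _tokens([a, "and", b, "were", "measured"])
    parse = DependencyParse(
        [
            DepToken(a, 4, "nsubj"),
            DepToken("and", 0, "dep"),
            DepToken(b, 0, "conj"),
            DepToken("were", 4, "dep"),
            DepToken("measured", 4, "ROOT"),
        ]
    )
    mentions = [ProteinMention(0, 1, a), ProteinMention(2, 3, b)]
    return tokens, mentions, parse


def _negative_single(a: str):
    tokens = _tokens([a, "expression", "was", "measured", "in", "cells"])
    parse = DependencyParse(
        [
            DepToken(a, 1, "compound"),
            DepToken("expression", 3, "nsubj"),
            DepToken("was", 3, "dep"),
            DepToken("measured", 3, "ROOT"),
            DepToken("in", 3, "prep"),
            DepToken("cells", 4, "pobj"),
        ]
    )
    mentions = [ProteinMention(0, 1, a)]
    return tokens, mentions, parse


def generate_corpus(spec: FixtureSpec) -> list[GoldRecord]:
    """Generate ``spec.n_sentences`` gold records, with exactly
    ``round(n * positive_fraction)`` positives, deterministically."""
    rng = np.random.default_rng(spec.seed)
    proteins = _protein_names(spec)
    verbs = list(_VERBS[: spec.n_relation_verbs])
    n_pos = round(spec.n_sentences * spec.positive_fraction)
    labels = np.zeros(spec.n_sentences, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    records: list[GoldRecord] = []
    for idx, label in enumerate(labels):
        pmid = f"1{idx:06d}"
        a, b = (proteins[k] for k in rng.choice(len(proteins), size=2, replace=False))
        if label == 1:
            verb = verbs[int(rng.integers(len(verbs)))]
            template = _positive_interacts if rng.random() < 0.5 else _positive_verb_expression
            tokens, mentions, parse, relation_word = template(a, b, verb)
        else:
            relation_word = ""
            if rng.random() < 0.5:
                tokens, mentions, parse = _negative_comention(a, b)
            else:
                tokens, mentions, parse = _negative_single(a)
        sentence = LabeledSentence(tokens=tokens, label=int(label), mentions=mentions, pmid=pmid)
        sentence.validate()
        records.append(
            GoldRecord(
                sentence=sentence,
                tagged=tag_tokens(sentence),
                parse=parse,
                relation_word=relation_word,
            )
        )
    return records


def generate_embedding_file(
    vocab: Sequence[str], dim: int, seed: int, path: str | Path
) -> Path:
    """Write a plain-text word-vector file with i.i.d. uniform(-0.25, 0.25)
    values; stands in for 200-dimensional pretrained vectors."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if len(set(vocab)) != len(vocab):
        raise ValueError("duplicate vocabulary entries")
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for word in vocab:
            values = rng.uniform(-OOV_RANGE, OOV_RANGE, size=dim)
            fh.write(word + " " + " ".join(f"{v:.6f}" for v in values) + "\n")
    return path


def fig4_fixture() -> GoldRecord:
    """The worked three-protein example sentence with its hand-built parse.

    "Mechanistically INTS6 increased WIF-1 expression and then inhibited
    the Wnt/beta-catenin signaling pathway" — ``increased`` is the ROOT
    with INTS6 as nsubj; ``inhibited`` is a conj of the ROOT whose dobj
    chain reaches Wnt/beta-catenin. Three mentions, hence three
    extractable pairs.
    """
    words = [
        ("Mechanistically", "RB", 2, "dep"),
        ("INTS6", "NNP", 2, "nsubj"),
        ("increased", "VBD", 2, "ROOT"),
        ("WIF-1", "NNP", 4, "compound"),
        ("expression", "NN", 2, "dobj"),
        ("and", "CC", 7, "dep"),
        ("then", "RB", 7, "dep"),
        ("inhibited", "VBD", 2, "conj"),
        ("the", "DT", 11, "det"),
        ("Wnt/beta-catenin", "NNP", 11, "compound"),
        ("signaling", "NN", 11, "compound"),
        ("pathway", "NN", 7, "dobj"),
    ]
    tokens = [Token(w, p) for w, p, _, _ in words]
    parse = DependencyParse([DepToken(w, h, l) for w, _, h, l in words])
    mentions = [
        ProteinMention(1, 2, "INTS6"),
        ProteinMention(3, 4, "WIF-1"),
        ProteinMention(9, 10, "Wnt/beta-catenin"),
    ]
    sentence = LabeledSentence(tokens=tokens, label=1, mentions=mentions, pmid="fig4")
    sentence.validate()
    return GoldRecord(
        sentence=sentence, tagged=tag_tokens(sentence), parse=parse, relation_word="increased"
    )


def expected_network(records: Sequence[GoldRecord], include_empty: bool = False) -> PPIGraph:
    """The network the pipeline should produce from these records, derived
    from the gold mentions and parses."""
    candidates = []
    for r in records:
        if r.parse is None or len(r.sentence.mentions) < 2:
            continue
        candidates.extend(
            extract_candidates(
                [t.text for t in r.sentence.tokens],
                r.sentence.mentions,
                r.parse,
                pmid=r.sentence.pmid,
            )
        )
    return build_network(candidates, include_empty=include_empty)


def write_fixture_files(
    records: Sequence[GoldRecord], out_dir: str | Path, embedding_dim: int = 200, seed: int = 0
) -> dict[str, Path]:
    """Emit the full fixture file set: labeled JSON-lines, CoNLL tags,
    parse tables, abstract JSON-lines, a synthetic embedding file, and the
    expected network JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sentences": out_dir / "sentences.jsonl",
        "tagged": out_dir / "tagged.conll",
        "parses": out_dir / "parses.tsv",
        "abstracts": out_dir / "abstracts.jsonl",
        "embeddings": out_dir / "embeddings.txt",
        "expected_network": out_dir / "expected_network.json",
    }
    write_labeled_jsonl([r.sentence for r in records], paths["sentences"])
    write_conll_tagged([r.tagged for r in records], paths["tagged"])
    write_parse_tables([r.parse for r in records if r.parse is not None], paths["parses"])
    write_abstracts_jsonl(
        [(r.sentence.pmid, " ".join(t.text for t in r.sentence.tokens)) for r in records],
        paths["abstracts"],
    )
    vocab: list[str] = []
    seen = set()
    for r in records:
        for t in r.sentence.tokens:
            if t.text not in seen:
                seen.add(t.text)
                vocab.append(t.text)
    generate_embedding_file(vocab, embedding_dim, seed, paths["embeddings"])
    expected_network(records).export_json(paths["expected_network"])
    return paths
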