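"""Corpus reading, tokenization, masking, labeling, and splitting.

Defines the interchange formats used by every other stage:

* labeled-sentence JSON-lines — one object per line with keys ``pmid``,
  ``tokens``, ``pos`` (optional), ``label`` (0/1) and ``mentions``
  (array of ``{start, end, surface}``);
* tagged-corpus CoNLL-style text — ``TOKEN<TAB>POS<TAB>TAG`` rows,
  sentences separated by blank lines, tags restricted to ``{P, O}``;
* abstract JSON-lines — ``{pmid, text}`` records for inference.

Tokenization is "multiword": hyphen- and slash-joined alphanumeric runs
(``Beta-catenin``, ``Wnt/beta-catenin``) stay single tokens so protein
names survive intact; other punctuation is split off.
"""

from __future__ import annotations

import json
import random
import re
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Callable, Iterable, Sequence

from ppiminer.types import (
    MASK_FIRST,
    MASK_SECOND,
    DatasetSplit,
    LabeledSentence,
    MaskedInstance,
    ProteinMention,
    TaggedSentence,
    Token,
)

__all__ = [
    "tokenize",
    "segment_sentences",
    "mask_pair",
    "masked_instances",
    "tag_tokens",
    "split_60_40",
    "read_labeled_jsonl",
    "write_labeled_jsonl",
    "read_conll_tagged",
    "write_conll_tagged",
    "read_abstracts_jsonl",
    "write_abstracts_jsonl",
    "convert_shared_task_xml",
    "heuristic_pos_tagger",
]


class InvalidPairError(ValueError):
    """Raised when a mention pair passed to :func:`mask_pair` is unusable."""


# A token is a maximal alphanumeric run, optionally extended through '-' or
# '/' into further alphanumeric runs, or a single non-space punctuation mark.
_TOKEN_RE = re.compile(r"\w+(?:[-/]\w+)*|[^\w\s]")


def tokenize(text: str) -> list[Token]:
    """Tokenize ``text``, keeping hyphen/slash-joined protein names whole.

    >>> [t.text for t in tokenize("Beta-catenin binds APC")]
    ['Beta-catenin', 'binds', 'APC']
    """
    return [Token(m.group(0)) for m in _TOKEN_RE.finditer(text)]


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Like :func:`tokenize` but returns ``(text, char_start, char_end)``."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# Abbreviations after which a period never ends a sentence.
_ABBREVIATIONS = frozenset(
    {"fig.", "figs.", "al.", "e.g.", "i.e.", "vs.", "cf.", "dr.", "no.", "ca.", "etc.", "approx."}
)
def segment_sentences(abstract: str) -> list[str]:
    """Split an abstract into sentences on terminal ``. ! ?``.

    A period does not terminate a sentence when the word carrying it is a
    known abbreviation (``Fig.``, ``et al.``, ``e.g.`` ...). Concatenating
    the result recovers the input up to whitespace.
    """
    out: list[str] = []
    start = 0
    for m in re.finditer(r"[.!?]+(?=\s)", abstract):
        prefix = abstract[: m.end()].split()
        last_word = prefix[-1].lower().lstrip("([{'\"") if prefix else ""
        if last_word in _ABBREVIATIONS:
            continue
        segment = abstract[start : m.end()].strip()
        if segment:
            out.append(segment)
        start = m.end()
    tail = abstract[start:].strip()
    if tail:
        out.append(tail)
    return out


def mask_pair(sentence: LabeledSentence, i: int, j: int) -> MaskedInstance:
    """Replace mention ``i`` with ``PROT1`` and mention ``j`` with ``PROT2``.

    Mention ``i`` must precede mention ``j`` in token order. Mentions other
    than the pair are left verbatim.
    """
    n_mentions = len(sentence.mentions)
    if i == j:
        raise InvalidPairError("pair indices must differ")
    if not (0 <= i < n_mentions and 0 <= j < n_mentions):
        raise InvalidPairError(f"mention index out of range for {n_mentions} mentions")
    first, second = sentence.mentions[i], sentence.mentions[j]
    if first.start >= second.start:
        raise InvalidPairError("mention i must precede mention j in token order")

    tokens: list[str] = []
    t = 0
    n = len(sentence.tokens)
    while t < n:
        if t == first.start:
            tokens.append(MASK_FIRST)
            t = first.end
        elif t == second.start:
            tokens.append(MASK_SECOND)
            t = second.end
        else:
            tokens.append(sentence.tokens[t].text)
            t += 1
    inst = MaskedInstance(tokens=tokens, label=sentence.label, source=sentence, pair=(i, j))
    inst.validate()
    return inst


def masked_instances(
    sentence: LabeledSentence,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> list[MaskedInstance]:
    """Generate classifier instances for a sentence, one per mention pair.

    When the corpus provides pair annotations, pass them as ``pairs``;
    otherwise every unordered mention pair is enumerated and given the
    sentence label. Sentences with fewer than two mentions yield nothing.
    """
    mentions = sentence.mentions
    if len(mentions) < 2:
        return []
    if pairs is None:
        order = sorted(range(len(mentions)), key=lambda k: mentions[k].start)
        pairs = [(order[a], order[b]) for a in range(len(order)) for b in range(a + 1, len(order))]
    out = []
    for i, j in pairs:
        if mentions[i].start > mentions[j].start:
            i, j = j, i
        out.append(mask_pair(sentence, i, j))
    return out


def classification_instances(
    sentences: Sequence[LabeledSentence], mode: str = "masked"
) -> tuple[list[list[str]], list[int]]:
    """Token sequences + labels for classifier training/evaluation.

    ``mode="masked"`` enumerates one PROT1/PROT2-masked instance per
    mention pair (sentences with fewer than two mentions contribute
    nothing); ``mode="raw"`` uses each sentence verbatim, matching how the
    pipeline classifies before any mention tagging has happened.
    """
    X: list[list[str]] = []
    y: list[int] = []
    if mode == "masked":
        for s in sentences:
            for inst in masked_instances(s):
                X.append(inst.tokens)
                y.append(inst.label)
    elif mode == "raw":
        for s in sentences:
            X.append(s.texts)
            y.append(s.label)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'masked' or 'raw'")
    return X, y


def tag_tokens(sentence: LabeledSentence) -> TaggedSentence:
    """Project mention spans onto per-token ``P``/``O`` tags."""
    tags = ["O"] * len(sentence.tokens)
    for m in sentence.mentions:
        for t in range(m.start, m.end):
            tags[t] = "P"
    return TaggedSentence(tokens=list(sentence.tokens), tags=tags)


def split_60_40(sentences: Sequence, seed: int) -> DatasetSplit:
    """Shuffle with ``seed`` and split 60% train / 40% test.

    The train size is ``round(0.6 * n)``; the partition is exact and
    deterministic for a fixed seed.
    """
    n = len(sentences)
    if n < 2:
        raise ValueError("need at least 2 sentences to split")
    indices = list(range(n))
    random.Random(seed).shuffle(indices)
    n_train = round(0.6 * n)
    train = [sentences[k] for k in indices[:n_train]]
    test = [sentences[k] for k in indices[n_train:]]
    return DatasetSplit(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# JSON-lines interchange


def _sentence_to_record(s: LabeledSentence) -> dict:
    rec: dict = {
        "pmid": s.pmid,
        "tokens": [t.text for t in s.tokens],
        "label": s.label,
        "mentions": [{"start": m.start, "end": m.end, "surface": m.surface} for m in s.mentions],
    }
    if any(t.pos for t in s.tokens):
        rec["pos"] = [t.pos for t in s.tokens]
    return rec


def _record_to_sentence(rec: dict) -> LabeledSentence:
    for key in ("tokens", "label", "mentions"):
        if key not in rec:
            raise KeyError(key)
    pos = rec.get("pos") or [""] * len(rec["tokens"])
    if len(pos) != len(rec["tokens"]):
        raise ValueError("pos and tokens length mismatch")
    tokens = [Token(t, p) for t, p in zip(rec["tokens"], pos)]
    mentions = [ProteinMention(m["start"], m["end"], m["surface"]) for m in rec["mentions"]]
    s = LabeledSentence(tokens=tokens, label=rec["label"], mentions=mentions, pmid=rec.get("pmid", ""))
    s.validate()
    return s


def write_labeled_jsonl(sentences: Iterable[LabeledSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps(_sentence_to_record(s)) + "\n")


def read_labeled_jsonl(path: str | Path) -> list[LabeledSentence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(_record_to_sentence(json.loads(line)))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return out


def write_abstracts_jsonl(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(pmid, text)`` pairs as ``{pmid, text}`` JSON-lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for pmid, text in records:
            fh.write(json.dumps({"pmid": pmid, "text": text}) + "\n")


def read_abstracts_jsonl(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                out.append((str(rec["pmid"]), rec["text"]))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# CoNLL-style tagged corpus


def write_conll_tagged(sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            for tok, tag in zip(s.tokens, s.tags):
                fh.write(f"{tok.text}\t{tok.pos}\t{tag}\n")
            fh.write("\n")


def read_conll_tagged(path: str | Path) -> list[TaggedSentence]:
    sentences: list[TaggedSentence] = []
    tokens: list[Token] = []
    tags: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal tokens, tags
        if tokens:
            try:
                sentences.append(TaggedSentence(tokens=tokens, tags=tags))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            tokens, tags = [], []

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}")
            text, pos, tag = fields
            if tag not in ("P", "O"):
                raise ValueError(f"{path}:{lineno}: invalid tag {tag!r}; allowed: P, O")
            tokens.append(Token(text, pos))
            tags.append(tag)
        flush(lineno)
    return sentences


# ---------------------------------------------------------------------------
# Best-effort converter for shared-task style PPI corpus XML


def convert_shared_task_xml(
    path: str | Path,
) -> list[tuple[LabeledSentence, list[tuple[int, int]]]]:
    """Convert unified shared-task PPI XML (AIMed/BioInfer dialects) to the
    JSON-lines interchange model.

    Expects ``<corpus><document><sentence>`` elements where each sentence
    carries a ``text`` attribute, ``<entity>`` children with ``charOffset``
    attributes like ``"12-24"`` and ``<interaction>`` (or ``<pair>``)
    children referencing entity ids. Character offsets are mapped onto the
    package tokenization; entities whose offsets cannot be aligned are
    dropped. Returns ``(sentence, annotated_pairs)`` tuples, where pairs
    index into the sentence's mention list.
    """
    tree = ET.parse(str(path))
    results: list[tuple[LabeledSentence, list[tuple[int, int]]]] = []
    for sent_el in tree.iter("sentence"):
        text = sent_el.get("text", "")
        if not text:
            continue
        toks = tokenize_with_offsets(text)
        tokens = [Token(t) for t, _, _ in toks]

        mention_index: dict[str, int] = {}
        mentions: list[ProteinMention] = []
        for ent in sent_el.findall("entity"):
            offset = ent.get("charOffset") or ent.get("origOffset") or ""
            first_span = offset.split(",")[0]
            m = re.fullmatch(r"(\d+)-(\d+)", first_span)
            if not m:
                continue
            c0, c1 = int(m.group(1)), int(m.group(2)) + 1  # XML offsets are inclusive
            covered = [k for k, (_, s, e) in enumerate(toks) if s < c1 and e > c0]
            if not covered:
                continue
            start, end = covered[0], covered[-1] + 1
            surface = " ".join(t for t, _, _ in toks[start:end])
            span = ProteinMention(start, end, surface)
            if span not in mentions:
                mentions.append(span)
            mention_index[ent.get("id", "")] = mentions.index(span)

        pairs: list[tuple[int, int]] = []
        positive = False
        for inter in list(sent_el.findall("interaction")) + list(sent_el.findall("pair")):
            if inter.tag == "pair" and inter.get("interaction", "True") == "False":
                continue
            e1, e2 = inter.get("e1", ""), inter.get("e2", "")
            if e1 in mention_index and e2 in mention_index and mention_index[e1] != mention_index[e2]:
                positive = True
                pairs.append((mention_index[e1], mention_index[e2]))

        label = 1 if (positive and len(mentions) >= 2) else 0
        doc = sent_el.get("id", "")
        sentence = LabeledSentence(tokens=tokens, label=label, mentions=mentions, pmid=doc.split(".")[0])
        sentence.validate()
        results.append((sentence, pairs))
    return results


# ---------------------------------------------------------------------------
# Pluggable POS tagging

PosTagger = Callable[[Sequence[str]], list[str]]

_VERB_SUFFIXES = ("ates", "ate", "ated", "ates", "izes", "ize", "ized")


def heuristic_pos_tagger(words: Sequence[str]) -> list[str]:
    """Tiny rule-based POS tagger used when the input carries no tags.

    Coarse Penn-style guesses driven by suffix and shape; adequate for the
    CRF feature template (which uses the tag and its 2-character prefix),
    not a general-purpose tagger.
    """
    out = []
    for w in words:
        lw = w.lower()
        if not any(ch.isalnum() for ch in w):
            tag = "."
        elif lw.isdigit():
            tag = "CD"
        elif lw in {"the", "a", "an"}:
            tag = "DT"
        elif lw in {"and", "or", "but"}:
            tag = "CC"
        elif lw in {"of", "in", "with", "to", "by", "for", "on", "through"}:
            tag = "IN"
        elif lw in {"is", "are", "was", "were", "be", "been"}:
            tag = "VB"
        elif lw.endswith("ed"):
            tag = "VBD"
        elif lw.endswith("s") and lw.endswith(("ates", "izes", "inds", "ibits")):
            tag = "VBZ"
        elif lw.endswith("ing"):
            tag = "VBG"
        elif lw.endswith("ly"):
            tag = "RB"
        elif w[:1].isupper() or any(ch.isdigit() for ch in w):
            tag = "NNP"
        else:
            tag = "NN"
        out.append(tag)
    return out


def ensure_pos(tokens: Sequence[Token], tagger: PosTagger = heuristic_pos_tagger) -> list[Token]:
    """Return tokens with POS tags, invoking ``tagger`` for missing ones."""
    if all(t.pos for t in tokens):
        return list(tokens)
    guessed = tagger([t.text for t in tokens])
    return [t if t.pos else Token(t.text, g) for t, g in zip(tokens, guessed)]
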