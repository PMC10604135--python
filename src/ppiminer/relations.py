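"""Shortest-dependency-path relation extraction.

A sentence's dependency parse is a tree: every token points to a head
token, except the single ROOT token which points to itself. Interaction
sentences put the relation verb at or near the ROOT, so the path between
two protein names in the undirected head<->dependent graph — the shortest
dependency path (SDP) — passes through the words that express their
relation. Relation words are picked off the path interior by matching
dependency-label patterns (by default ``amod* conj* ROOT* acomp*``), and
the pair is oriented by the dependency labels of the two protein tokens
(first-protein range ``nsubj/amod/compound``, second-protein range
``dobj/pobj/npadvmod/appos``).

Dependency parsing itself is consumed, not implemented: parses arrive in a
tab-separated table format (``index TAB token TAB head TAB label``, blank
line between sentences) or through a pluggable parser adapter. Labels use
the English ClearNLP-style inventory (nsubj, dobj, pobj, amod, conj,
acomp, appos, npadvmod, compound, prep, det, dep, ROOT).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx

from ppiminer.types import ProteinMention

ROOT_LABEL = "ROOT"

#: Dependency labels a first (agent-side) protein token usually carries.
FIRST_PROTEIN_LABELS = frozenset({"nsubj", "amod", "compound"})
#: Dependency labels a second (patient-side) protein token usually carries.
SECOND_PROTEIN_LABELS = frozenset({"dobj", "pobj", "npadvmod", "appos"})

LABEL_INVENTORY = frozenset(
    {"nsubj", "dobj", "pobj", "amod", "conj", "acomp", "appos", "npadvmod",
     "compound", "prep", "det", "dep", ROOT_LABEL}
)

__all__ = [
    "DepToken",
    "DependencyParse",
    "SDPResult",
    "PatternRule",
    "RelationCandidate",
    "DEFAULT_PATTERN",
    "pairs",
    "to_undirected_graph",
    "shortest_dependency_path",
    "extract_relation",
    "orient",
    "extract_candidates",
    "read_parse_tables",
    "write_parse_tables",
    "FixtureParserAdapter",
    "get_parser_adapter",
    "register_parser_adapter",
]


@dataclass(frozen=True)
class DepToken:
    text: str
    head: int
    label: str


@dataclass
class DependencyParse:
    """Tokens with head links and dependency labels; exactly one ROOT whose
    head is itself, and the head links form a tree."""

    tokens: list[DepToken]

    def __post_init__(self) -> None:
        roots = [k for k, t in enumerate(self.tokens) if t.label == ROOT_LABEL]
        if len(roots) != 1:
            raise ValueError(f"parse must have exactly one ROOT, found {len(roots)}")
        if self.tokens[roots[0]].head != roots[0]:
            raise ValueError("ROOT token must be its own head")
        n = len(self.tokens)
        for k, t in enumerate(self.tokens):
            if not (0 <= t.head < n):
                raise ValueError(f"token {k} head {t.head} out of range")
            if t.head == k and t.label != ROOT_LABEL:
                raise ValueError(f"token {k} is its own head but not ROOT")
        # tree check: following heads from every token must reach ROOT
        root = roots[0]
        for k in range(n):
            seen = set()
            cur = k
            while cur != root:
                if cur in seen:
                    raise ValueError("head links contain a cycle")
                seen.add(cur)
                cur = self.tokens[cur].head

    @property
    def root_index(self) -> int:
        return next(k for k, t in enumerate(self.tokens) if t.label == ROOT_LABEL)

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]

    def label_of(self, index: int) -> str:
        return self.tokens[index].label


@dataclass
class SDPResult:
    """An SDP between two token indices: the ordered token indices and
    their dependency labels."""

    path: list[int]
    labels: list[str]


@dataclass(frozen=True)
class PatternRule:
    """An ordered sequence of zero-or-more dependency-label elements,
    e.g. ``amod* conj* ROOT* acomp*``."""

    elements: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for label, op in self.elements:
            if op != "*":
                raise ValueError(f"unsupported quantifier {op!r}; only zero-or-more '*'")
            if label not in LABEL_INVENTORY:
                raise ValueError(f"unknown dependency label {label!r}")

    @classmethod
    def of(cls, *labels: str) -> "PatternRule":
        return cls(tuple((l, "*") for l in labels))


DEFAULT_PATTERN = PatternRule.of("amod", "conj", ROOT_LABEL, "acomp")


@dataclass
class RelationCandidate:
    """One protein pair from one sentence, with the relation words found on
    its SDP (possibly none) and the inferred direction."""

    protein_a: ProteinMention
    protein_b: ProteinMention
    relation_words: list[str]
    direction: str = "undirected"  # "a->b" | "b->a" | "undirected"
    pmid: str = ""
    sentence: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.protein_a.start, self.protein_a.end) == (self.protein_b.start, self.protein_b.end):
            raise ValueError("candidate proteins must be distinct mentions")


def pairs(mentions: Sequence[ProteinMention]) -> list[tuple[ProteinMention, ProteinMention]]:
    """All C(n, 2) unordered mention pairs in first-occurrence order."""
    out = []
    for a in range(len(mentions)):
        for b in range(a + 1, len(mentions)):
            out.append((mentions[a], mentions[b]))
    return out


def to_undirected_graph(parse: DependencyParse) -> nx.Graph:
    """One undirected edge per head<->dependent link; node attributes carry
    token text and dependency label. A valid n-token parse yields a
    connected graph with n-1 edges."""
    g = nx.Graph()
    for k, t in enumerate(parse.tokens):
        g.add_node(k, text=t.text, label=t.label)
    for k, t in enumerate(parse.tokens):
        if t.head != k:
            g.add_edge(k, t.head)
    if len(parse.tokens) > 1 and not nx.is_connected(g):
        raise ValueError("dependency graph is not connected")
    return g


def shortest_dependency_path(graph: nx.Graph, a: int, b: int) -> SDPResult:
    """Breadth-first shortest path from ``a`` to ``b``.

    Among equal-length paths (impossible in a tree, possible in a general
    graph) the path visiting the lowest token indices first is returned.
    ``a == b`` yields the single-node path.
    """
    if a not in graph or b not in graph:
        raise KeyError(f"token index {a if a not in graph else b} not in graph")
    # BFS distances from b, then greedily walk from a choosing the
    # lowest-index neighbor that moves strictly closer to b.
    dist = {b: 0}
    queue = deque([b])
    while queue:
        cur = queue.popleft()
        for nb in graph.neighbors(cur):
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    if a not in dist:
        raise ValueError(f"no path between {a} and {b}")
    path = [a]
    cur = a
    while cur != b:
        cur = min(nb for nb in graph.neighbors(cur) if dist.get(nb, float("inf")) == dist[cur] - 1)
        path.append(cur)
    labels = [graph.nodes[k]["label"] for k in path]
    return SDPResult(path=path, labels=labels)


def _match_rule(rule: PatternRule, interior: list[tuple[int, str]]) -> list[int]:
    """Repeated unanchored maximal matching of an all-optional ordered
    pattern; returns the matched token indices in order."""
    matched: list[int] = []
    pos = 0
    n = len(interior)
    while pos < n:
        k = pos
        consumed: list[int] = []
        for label, _op in rule.elements:
            while k < n and interior[k][1] == label:
                consumed.append(interior[k][0])
                k += 1
        if consumed:
            matched.extend(consumed)
            pos = k
        else:
            pos += 1
    return matched


def extract_relation(
    path: SDPResult,
    parse: DependencyParse,
    rules: Sequence[PatternRule] = (DEFAULT_PATTERN,),
) -> list[str]:
    """Relation words on the path interior (endpoints excluded).

    Interior tokens are scanned left-to-right against each rule's ordered
    optional-label sequence; matched token texts are emitted in path
    order. Endpoints are excluded so protein tokens carrying amod/compound
    labels are never returned as relation words.
    """
    interior = [(k, parse.label_of(k)) for k in path.path[1:-1]]
    seen: set[int] = set()
    out: list[str] = []
    for rule in rules:
        for idx in _match_rule(rule, interior):
            if idx not in seen:
                seen.add(idx)
                out.append(parse.tokens[idx].text)
    return out


def _mention_head(mention: ProteinMention) -> int:
    # the last token of a (possibly multi-token) mention is its syntactic
    # head in English compounds
    return mention.end - 1


def orient(
    mention_a: ProteinMention, mention_b: ProteinMention, parse: DependencyParse
) -> str:
    """Direction of the pair from the protein tokens' dependency labels:
    agent-range label on one side and patient-range on the other decides
    ``a->b`` or ``b->a``; anything else is undirected."""
    la = parse.label_of(_mention_head(mention_a))
    lb = parse.label_of(_mention_head(mention_b))
    if la in FIRST_PROTEIN_LABELS and lb in SECOND_PROTEIN_LABELS:
        return "a->b"
    if lb in FIRST_PROTEIN_LABELS and la in SECOND_PROTEIN_LABELS:
        return "b->a"
    return "undirected"


def extract_candidates(
    sentence_tokens: Sequence[str],
    mentions: Sequence[ProteinMention],
    parse: DependencyParse,
    pmid: str = "",
    rules: Sequence[PatternRule] = (DEFAULT_PATTERN,),
) -> list[RelationCandidate]:
    """Run pairs -> SDP -> pattern matching -> orientation for a sentence.

    Yields one candidate per mention pair; candidates whose SDP carries no
    pattern label keep an empty ``relation_words`` list (the network
    builder excludes them by default).
    """
    texts = list(sentence_tokens)
    if parse.texts != texts:
        raise ValueError("parse tokens do not match sentence tokens")
    unique: list[ProteinMention] = []
    spans = set()
    for m in mentions:
        if (m.start, m.end) not in spans:
            spans.add((m.start, m.end))
            unique.append(m)
    if len(unique) < 2:
        return []
    graph = to_undirected_graph(parse)
    out = []
    for ma, mb in pairs(unique):
        sdp = shortest_dependency_path(graph, _mention_head(ma), _mention_head(mb))
        words = extract_relation(sdp, parse, rules)
        out.append(
            RelationCandidate(
                protein_a=ma,
                protein_b=mb,
                relation_words=words,
                direction=orient(ma, mb, parse),
                pmid=pmid,
                sentence=tuple(texts),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Parse-table I/O (CoNLL-U-reduced dialect) and parser adapters


def write_parse_tables(parses: Iterable[DependencyParse], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for parse in parses:
            for k, t in enumerate(parse.tokens):
                fh.write(f"{k}\t{t.text}\t{t.head}\t{t.label}\n")
            fh.write("\n")


def read_parse_tables(path: str | Path) -> list[DependencyParse]:
    parses: list[DependencyParse] = []
    rows: list[DepToken] = []

    def flush(lineno: int) -> None:
        nonlocal rows
        if rows:
            try:
                parses.append(DependencyParse(tokens=rows))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows = []

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            idx, text, head, label = fields
            if int(idx) != len(rows):
                raise ValueError(f"{path}:{lineno}: token index {idx} out of order")
            rows.append(DepToken(text=text, head=int(head), label=label))
        flush(lineno)
    return parses


ParserAdapter = Callable[[Sequence[str]], DependencyParse | None]


class FixtureParserAdapter:
    """Replays stored parses keyed by the space-joined token sequence.

    Stands in for a live dependency parser in tests and offline runs;
    returns ``None`` for sentences it has no parse for.
    """

    def __init__(self, parses: Iterable[DependencyParse] | str | Path):
        if isinstance(parses, (str, Path)):
            parses = read_parse_tables(parses)
        self._by_key = {" ".join(p.texts): p for p in parses}

    def __call__(self, tokens: Sequence[str]) -> DependencyParse | None:
        return self._by_key.get(" ".join(tokens))

    def __len__(self) -> int:
        return len(self._by_key)


_ADAPTERS: dict[str, Callable[..., ParserAdapter]] = {
    "fixture": FixtureParserAdapter,
}


def register_parser_adapter(name: str, factory: Callable[..., ParserAdapter]) -> None:
    _ADAPTERS[name] = factory


def get_parser_adapter(name: str, *args, **kwargs) -> ParserAdapter:
    """Resolve a parser adapter by name (``fixture`` is bundled)."""
    if name not in _ADAPTERS:
        raise KeyError(f"unknown parser adapter {name!r}; known: {sorted(_ADAPTERS)}")
    return _ADAPTERS[name](*args, **kwargs)
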