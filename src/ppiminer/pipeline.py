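"""End-to-end orchestration: abstracts in, annotated PPI network out.

The stage order is fixed and mirrors how the models were designed to be
used: segment abstracts into sentences, classify each sentence and keep
only PPI-positives, tag protein names in the kept sentences, enumerate
mention pairs, parse, walk the shortest dependency path, match relation
patterns, and merge everything into the network. The NER stage therefore
only ever sees classifier-positive sentences.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from ppiminer import corpus
from ppiminer.classifier import load_classifier
from ppiminer.ner import load_tagger, tagged_to_mentions
from ppiminer.network import PPIGraph, build_network
from ppiminer.relations import (
    RelationCandidate,
    extract_candidates,
    get_parser_adapter,
)

logger = logging.getLogger("ppiminer.pipeline")

__all__ = ["PipelineConfig", "RunReport", "run", "candidate_to_dict", "candidate_from_dict"]


@dataclass
class PipelineConfig:
    classifier_dir: str
    crf_dir: str
    parser: str = "fixture"
    parser_arg: str | None = None  # e.g. the parse-table path for "fixture"
    threshold: float = 0.5
    include_empty_relations: bool = False
    output_dir: str = "ppi_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class RunReport:
    """Stage counters and warnings for one pipeline run."""

    counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        if c.get("positive_sentences", 0) > c.get("sentences", 0):
            raise ValueError("positives exceed sentences")
        if c.get("emitted_edges", 0) > c.get("candidate_pairs", 0):
            raise ValueError("edges exceed candidate pairs")

    def to_dict(self) -> dict:
        return {"counts": self.counts, "warnings": self.warnings, "stage_seconds": self.stage_seconds}


def candidate_to_dict(c: RelationCandidate) -> dict:
    return {
        "a": {"start": c.protein_a.start, "end": c.protein_a.end, "surface": c.protein_a.surface},
        "b": {"start": c.protein_b.start, "end": c.protein_b.end, "surface": c.protein_b.surface},
        "relation_words": c.relation_words,
        "direction": c.direction,
        "pmid": c.pmid,
        "sentence": list(c.sentence),
    }


def candidate_from_dict(d: dict) -> RelationCandidate:
    from ppiminer.types import ProteinMention

    return RelationCandidate(
        protein_a=ProteinMention(d["a"]["start"], d["a"]["end"], d["a"]["surface"]),
        protein_b=ProteinMention(d["b"]["start"], d["b"]["end"], d["b"]["surface"]),
        relation_words=list(d["relation_words"]),
        direction=d["direction"],
        pmid=d["pmid"],
        sentence=tuple(d.get("sentence", ())),
    )


def run(abstracts_path: str | Path, config: PipelineConfig) -> tuple[PPIGraph, RunReport]:
    """Run the full extraction pipeline over ``{pmid, text}`` JSON-lines.

    Writes ``network.graphml``, ``network_edges.tsv``, ``network.json``,
    ``candidates.jsonl`` and ``report.json`` into ``config.output_dir``
    and returns the in-memory graph and report.
    """
    for artifact in (config.classifier_dir, config.crf_dir):
        if not Path(artifact).exists():
            raise FileNotFoundError(f"model artifact not found: {artifact}")
    if not Path(abstracts_path).exists():
        raise FileNotFoundError(f"abstracts file not found: {abstracts_path}")

    report = RunReport()
    t0 = time.perf_counter()
    clf = load_classifier(config.classifier_dir)
    tagger = load_tagger(config.crf_dir)
    adapter_args = (config.parser_arg,) if config.parser_arg else ()
    parser = get_parser_adapter(config.parser, *adapter_args)
    report.stage_seconds["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    abstracts = corpus.read_abstracts_jsonl(abstracts_path)
    sentences: list[tuple[str, list[str]]] = []  # (pmid, tokens)
    for pmid, text in abstracts:
        for sent_text in corpus.segment_sentences(text):
            sentences.append((pmid, [t.text for t in corpus.tokenize(sent_text)]))
    report.counts["abstracts"] = len(abstracts)
    report.counts["sentences"] = len(sentences)
    report.stage_seconds["segment"] = time.perf_counter() - t0
    logger.info("segmented %d abstracts into %d sentences", len(abstracts), len(sentences))

    t0 = time.perf_counter()
    if sentences:
        proba = clf.predict_proba([toks for _, toks in sentences])[:, 1]
        kept = [(pmid, toks) for (pmid, toks), p in zip(sentences, proba) if p >= config.threshold]
    else:
        kept = []
    report.counts["positive_sentences"] = len(kept)
    report.stage_seconds["classify"] = time.perf_counter() - t0
    logger.info("classifier kept %d / %d sentences", len(kept), len(sentences))

    t0 = time.perf_counter()
    candidates: list[RelationCandidate] = []
    n_mentions = 0
    for pmid, toks in kept:
        tokens = corpus.ensure_pos([corpus.Token(t) for t in toks])
        tags = tagger.predict_single(tokens)
        mentions = tagged_to_mentions(tokens, tags)
        n_mentions += len(mentions)
        if len(mentions) < 2:
            continue
        parse = parser(toks)
        if parse is None:
            report.warnings.append(f"no parse for sentence ({pmid}): {' '.join(toks[:8])} ...")
            continue
        candidates.extend(extract_candidates(toks, mentions, parse, pmid=pmid))
    report.counts["tagged_mentions"] = n_mentions
    report.counts["candidate_pairs"] = len(candidates)
    report.stage_seconds["tag_and_extract"] = time.perf_counter() - t0
    logger.info("tagged %d mentions, %d candidate pairs", n_mentions, len(candidates))

    t0 = time.perf_counter()
    graph = build_network(candidates, include_empty=config.include_empty_relations)
    report.counts["emitted_edges"] = graph.n_edges()
    report.stage_seconds["network"] = time.perf_counter() - t0
    report.validate()

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph.export_graphml(out / "network.graphml")
    graph.export_edge_tsv(out / "network_edges.tsv")
    graph.export_json(out / "network.json")
    with open(out / "candidates.jsonl", "w", encoding="utf-8") as fh:
        for c in candidates:
            fh.write(json.dumps(candidate_to_dict(c)) + "\n")
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    logger.info("network: %d nodes, %d edges", graph.n_nodes(), graph.n_edges())
    return graph, report
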