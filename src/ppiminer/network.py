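"""PPI network assembly and export.

Relation candidates from many sentences merge into one graph: nodes are
proteins identified by case-folded name (no synonym resolution), edges
accumulate the union of relation words and PMIDs plus a support count of
contributing sentences, so every interaction can be traced back to the
articles asserting it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from ppiminer.relations import RelationCandidate

__all__ = ["PPINode", "PPIEdge", "PPIGraph", "build_network"]


@dataclass
class PPINode:
    canonical_id: str
    display: str  # first-seen surface form


@dataclass
class PPIEdge:
    node_a: str
    node_b: str
    relations: set[str] = field(default_factory=set)
    pmids: set[str] = field(default_factory=set)
    support: int = 0
    evidence_directions: set[str] = field(default_factory=set)

    @property
    def directed(self) -> bool:
        """True only when every piece of evidence points the same way."""
        return len(self.evidence_directions) == 1 and "undirected" not in self.evidence_directions

    @property
    def direction(self) -> str:
        return next(iter(self.evidence_directions)) if self.directed else "undirected"


class PPIGraph:
    """Protein nodes plus merged, annotated interaction edges.

    Merging is commutative and idempotent over candidate multisets: any
    insertion order of the same candidates yields the identical graph.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, PPINode] = {}
        self.edges: dict[tuple[str, str], PPIEdge] = {}

    def _node(self, surface: str) -> str:
        cid = surface.casefold()
        if cid not in self.nodes:
            self.nodes[cid] = PPINode(canonical_id=cid, display=surface)
        return cid

    def add_candidate(self, c: RelationCandidate, include_empty: bool = False) -> "PPIGraph":
        """Merge one relation candidate into the graph.

        Candidates with no relation words are skipped unless
        ``include_empty`` is set; pairs that collapse to a single node
        after case folding are rejected with a warning.
        """
        if not c.relation_words and not include_empty:
            return self
        ca = c.protein_a.surface.casefold()
        cb = c.protein_b.surface.casefold()
        if ca == cb:
            warnings.warn(f"self-loop rejected for {c.protein_a.surface!r}", stacklevel=2)
            return self
        ca = self._node(c.protein_a.surface)
        cb = self._node(c.protein_b.surface)
        key = (min(ca, cb), max(ca, cb))
        edge = self.edges.get(key)
        if edge is None:
            edge = self.edges[key] = PPIEdge(node_a=key[0], node_b=key[1])
        edge.relations.update(c.relation_words)
        if c.pmid:
            edge.pmids.add(c.pmid)
        edge.support += 1
        # normalize the evidence direction onto the sorted key orientation
        direction = c.direction
        if direction != "undirected" and ca != key[0]:
            direction = "b->a" if direction == "a->b" else "a->b"
        edge.evidence_directions.add(direction)
        return self

    # -- views -----------------------------------------------------------

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def edge_between(self, name_a: str, name_b: str) -> PPIEdge | None:
        ca, cb = name_a.casefold(), name_b.casefold()
        return self.edges.get((min(ca, cb), max(ca, cb)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPIGraph):
            return NotImplemented
        return (
            {k: (v.canonical_id, v.display) for k, v in self.nodes.items()}
            == {k: (v.canonical_id, v.display) for k, v in other.nodes.items()}
            and {
                k: (v.relations, v.pmids, v.support, v.evidence_directions)
                for k, v in self.edges.items()
            }
            == {
                k: (v.relations, v.pmids, v.support, v.evidence_directions)
                for k, v in other.edges.items()
            }
        )

    # -- export ----------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for cid, node in sorted(self.nodes.items()):
            g.add_node(cid, display=node.display)
        for (a, b), e in sorted(self.edges.items()):
            g.add_edge(
                a,
                b,
                relations=";".join(sorted(e.relations)),
                pmids=";".join(sorted(e.pmids)),
                support=e.support,
                directed=e.directed,
                direction=e.direction,
            )
        return g

    def export_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def export_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\tdirected\trelations\tpmids\tsupport\n")
            for (a, b), e in sorted(self.edges.items()):
                fh.write(
                    f"{self.nodes[a].display}\t{self.nodes[b].display}\t"
                    f"{str(e.directed).lower()}\t"
                    f"{';'.join(sorted(e.relations))}\t{';'.join(sorted(e.pmids))}\t{e.support}\n"
                )

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.canonical_id, "display": n.display}
                for _, n in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "a": e.node_a,
                    "b": e.node_b,
                    "relations": sorted(e.relations),
                    "pmids": sorted(e.pmids),
                    "support": e.support,
                    "directions": sorted(e.evidence_directions),
                    "directed": e.directed,
                }
                for _, e in sorted(self.edges.items())
            ],
        }

    def export_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "PPIGraph":
        g = cls()
        for n in data["nodes"]:
            g.nodes[n["id"]] = PPINode(canonical_id=n["id"], display=n["display"])
        for e in data["edges"]:
            g.edges[(e["a"], e["b"])] = PPIEdge(
                node_a=e["a"],
                node_b=e["b"],
                relations=set(e["relations"]),
                pmids=set(e["pmids"]),
                support=e["support"],
                evidence_directions=set(e["directions"]),
            )
        return g

    @classmethod
    def import_json(cls, path: str | Path) -> "PPIGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_network(
    candidates: Iterable[RelationCandidate], include_empty: bool = False
) -> PPIGraph:
    """Merge candidates into a fresh :class:`PPIGraph`."""
    g = PPIGraph()
    for c in candidates:
        g.add_candidate(c, include_empty=include_empty)
    return g
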