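"""Dependency graphs, shortest paths, pattern matching, and orientation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ppiminer.relations import (
    DEFAULT_PATTERN,
    DependencyParse,
    DepToken,
    FixtureParserAdapter,
    PatternRule,
    RelationCandidate,
    extract_candidates,
    extract_relation,
    get_parser_adapter,
    orient,
    pairs,
    read_parse_tables,
    shortest_dependency_path,
    to_undirected_graph,
    write_parse_tables,
)
from ppiminer.types import ProteinMention


def random_tree_graph(n, rng):
    """A random labeled tree on n nodes (uniform random parent links)."""
    g = nx.Graph()
    for k in range(n):
        g.add_node(k, text=f"t{k}", label="dep")
    for k in range(1, n):
        g.add_edge(k, int(rng.integers(0, k)))
    return g


def brute_force_min_path_length(g, a, b):
    return min(len(p) for p in nx.all_simple_paths(g, a, b)) if a != b else 1


class TestPairs:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (5, 10)])
    def test_counts(self, n, expected):
        mentions = [ProteinMention(k, k + 1, f"P{k}") for k in range(n)]
        result = pairs(mentions)
        assert len(result) == expected
        assert result[0] == (mentions[0], mentions[1])  # first-occurrence order


class TestDependencyParse:
    def test_multi_root_rejected(self):
        with pytest.raises(ValueError):
            DependencyParse([DepToken("a", 0, "ROOT"), DepToken("b", 1, "ROOT")])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            DependencyParse(
                [DepToken("a", 1, "dep"), DepToken("b", 0, "dep"), DepToken("c", 2, "ROOT")]
            )

    def test_two_token_parse_has_one_edge(self):
        parse = DependencyParse([DepToken("binds", 0, "ROOT"), DepToken("it", 0, "nsubj")])
        assert to_undirected_graph(parse).number_of_edges() == 1

    def test_tree_edge_count(self, fig4):
        g = to_undirected_graph(fig4.parse)
        assert g.number_of_edges() == len(fig4.parse.tokens) - 1
        assert nx.is_connected(g)
        root = fig4.parse.root_index
        assert any(g.nodes[nb]["label"] == "nsubj" for nb in g.neighbors(root))


class TestShortestDependencyPath:
    def test_adjacent_tokens(self):
        parse = DependencyParse([DepToken("binds", 0, "ROOT"), DepToken("it", 0, "nsubj")])
        assert shortest_dependency_path(to_undirected_graph(parse), 0, 1).path == [0, 1]

    def test_same_endpoint_single_node(self, fig4):
        g = to_undirected_graph(fig4.parse)
        sdp = shortest_dependency_path(g, 2, 2)
        assert sdp.path == [2] and sdp.labels == ["ROOT"]

    def test_path_symmetry(self, fig4):
        g = to_undirected_graph(fig4.parse)
        for a, b in itertools.combinations(range(len(fig4.parse.tokens)), 2):
            fwd = shortest_dependency_path(g, a, b).path
            rev = shortest_dependency_path(g, b, a).path
            assert fwd == rev[::-1]

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            g = random_tree_graph(n, rng)
            a, b = (int(x) for x in rng.choice(n, size=2, replace=False))
            sdp = shortest_dependency_path(g, a, b)
            assert len(sdp.path) == brute_force_min_path_length(g, a, b)
            assert sdp.path[0] == a and sdp.path[-1] == b
            for u, v in zip(sdp.path, sdp.path[1:]):
                assert g.has_edge(u, v)

    def test_unknown_node_rejected(self, fig4):
        with pytest.raises(KeyError):
            shortest_dependency_path(to_undirected_graph(fig4.parse), 0, 99)


class TestExtractRelation:
    def test_fig4_ints6_wif1_yields_increased(self, fig4):
        g = to_undirected_graph(fig4.parse)
        sdp = shortest_dependency_path(g, 1, 3)
        assert extract_relation(sdp, fig4.parse) == ["increased"]

    def test_fig4_ints6_wnt_contains_inhibited(self, fig4):
        g = to_undirected_graph(fig4.parse)
        sdp = shortest_dependency_path(g, 1, 9)
        assert "inhibited" in extract_relation(sdp, fig4.parse)

    def test_prep_det_interior_matches_nothing(self):
        # path 0-1-3 has interior label prep only; 0-2 covers det
        parse = DependencyParse(
            [
                DepToken("A", 1, "nsubj"),
                DepToken("of", 3, "prep"),
                DepToken("the", 1, "det"),
                DepToken("B", 3, "ROOT"),
            ]
        )
        g = to_undirected_graph(parse)
        sdp = shortest_dependency_path(g, 0, 3)
        assert extract_relation(sdp, parse) == []

    def test_matched_tokens_lie_on_path_interior(self, fig4):
        g = to_undirected_graph(fig4.parse)
        for a, b in itertools.combinations([1, 3, 9], 2):
            sdp = shortest_dependency_path(g, a, b)
            interior_texts = {fig4.parse.texts[k] for k in sdp.path[1:-1]}
            assert set(extract_relation(sdp, fig4.parse)) <= interior_texts

    def test_pattern_rule_validation(self):
        with pytest.raises(ValueError):
            PatternRule((("amod", "+"),))
        with pytest.raises(ValueError):
            PatternRule.of("not-a-label")


class TestOrient:
    def _parse(self, la, lb):
        return DependencyParse(
            [DepToken("A", 1, la), DepToken("binds", 1, "ROOT"), DepToken("B", 1, lb)]
        )

    def test_subject_object(self):
        parse = self._parse("nsubj", "dobj")
        a, b = ProteinMention(0, 1, "A"), ProteinMention(2, 3, "B")
        assert orient(a, b, parse) == "a->b"
        assert orient(b, a, parse) == "b->a"

    def test_outside_both_ranges_undirected(self):
        parse = self._parse("det", "prep")
        a, b = ProteinMention(0, 1, "A"), ProteinMention(2, 3, "B")
        assert orient(a, b, parse) == "undirected"


class TestExtractCandidates:
    def test_fig4_three_candidates(self, fig4):
        cands = extract_candidates(
            fig4.sentence.texts, fig4.sentence.mentions, fig4.parse, pmid="fig4"
        )
        assert len(cands) == 3
        first = cands[0]
        assert {first.protein_a.surface, first.protein_b.surface} == {"INTS6", "WIF-1"}
        assert first.relation_words == ["increased"]
        assert all(c.pmid == "fig4" for c in cands)

    def test_single_mention_yields_nothing(self, fig4):
        assert extract_candidates(fig4.sentence.texts, fig4.sentence.mentions[:1], fig4.parse) == []

    def test_empty_relation_candidates_are_retained(self):
        parse = DependencyParse(
            [
                DepToken("A", 4, "nsubj"),
                DepToken("and", 0, "dep"),
                DepToken("B", 0, "conj"),
                DepToken("were", 4, "dep"),
                DepToken("measured", 4, "ROOT"),
            ]
        )
        mentions = [ProteinMention(0, 1, "A"), ProteinMention(2, 3, "B")]
        cands = extract_candidates(["A", "and", "B", "were", "measured"], mentions, parse)
        assert len(cands) == 1 and cands[0].relation_words == []

    def test_token_mismatch_rejected(self, fig4):
        with pytest.raises(ValueError):
            extract_candidates(["wrong", "tokens"], fig4.sentence.mentions, fig4.parse)

    def test_duplicate_spans_deduplicated(self, fig4):
        doubled = list(fig4.sentence.mentions) + [fig4.sentence.mentions[0]]
        cands = extract_candidates(fig4.sentence.texts, doubled, fig4.parse)
        assert len(cands) == 3

    def test_self_pair_rejected_in_candidate(self):
        m = ProteinMention(0, 1, "A")
        with pytest.raises(ValueError):
            RelationCandidate(protein_a=m, protein_b=m, relation_words=[])


class TestParseTablesAndAdapters:
    def test_round_trip(self, tmp_path, fig4, small_corpus):
        parses = [fig4.parse] + [r.parse for r in small_corpus[:5]]
        path = tmp_path / "p.tsv"
        write_parse_tables(parses, path)
        back = read_parse_tables(path)
        assert [p.texts for p in back] == [p.texts for p in parses]
        assert [[t.head for t in p.tokens] for p in back] == [[t.head for t in p.tokens] for p in parses]

    def test_fixture_adapter_lookup(self, fig4):
        adapter = FixtureParserAdapter([fig4.parse])
        assert adapter(fig4.sentence.texts) is fig4.parse
        assert adapter(["unknown", "tokens"]) is None

    def test_adapter_registry(self, fig4):
        adapter = get_parser_adapter("fixture", [fig4.parse])
        assert len(adapter) == 1
        with pytest.raises(KeyError):
            get_parser_adapter("no-such-parser")
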