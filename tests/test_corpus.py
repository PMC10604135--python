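"""Tokenization, masking, tagging, splitting, and interchange formats."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiminer import corpus
from ppiminer.corpus import (
    InvalidPairError,
    classification_instances,
    mask_pair,
    masked_instances,
    read_abstracts_jsonl,
    read_conll_tagged,
    read_labeled_jsonl,
    segment_sentences,
    split_60_40,
    tag_tokens,
    tokenize,
    write_abstracts_jsonl,
    write_conll_tagged,
    write_labeled_jsonl,
)
from ppiminer.types import LabeledSentence, ProteinMention, TaggedSentence, Token


def sent(words, label=0, mentions=(), pmid=""):
    toks = [Token(w) for w in words]
    s = LabeledSentence(tokens=toks, label=label, mentions=list(mentions), pmid=pmid)
    s.validate()
    return s


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Beta-catenin binds APC", ["Beta-catenin", "binds", "APC"]),
            ("", []),
            ("the Wnt/beta-catenin signaling pathway .", ["the", "Wnt/beta-catenin", "signaling", "pathway", "."]),
            ("IL-2 (interleukin-2) binds IL-2R.", ["IL-2", "(", "interleukin-2", ")", "binds", "IL-2R", "."]),
        ],
    )
    def test_examples(self, text, expected):
        assert [t.text for t in tokenize(text)] == expected

    @given(st.text(alphabet="abXY12-/ .,", max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_tokens_never_contain_whitespace(self, text):
        for tok in tokenize(text):
            assert tok.text and not any(c.isspace() for c in tok.text)

    @given(
        st.lists(
            st.from_regex(r"[A-Za-z0-9]{1,4}([-/][A-Za-z0-9]{1,4}){0,2}", fullmatch=True),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_hyphen_slash_runs_stay_single_tokens(self, words):
        assert [t.text for t in tokenize(" ".join(words))] == words


class TestSegmentSentences:
    def test_two_terminal_periods(self):
        assert segment_sentences("A binds B. C binds D.") == ["A binds B.", "C binds D."]

    def test_abbreviation_guard(self):
        assert segment_sentences("Binding of p53 (Fig. 2) occurs.") == ["Binding of p53 (Fig. 2) occurs."]

    def test_empty(self):
        assert segment_sentences("") == []

    def test_concatenation_recovers_text_modulo_whitespace(self):
        text = "USP9X binds RAPTOR. It was shown by Smith et al. in 2019! Really?"
        parts = segment_sentences(text)
        assert " ".join(" ".join(p.split()) for p in parts) == " ".join(text.split())


class TestMaskPair:
    def test_fig4_style_pair(self):
        s = sent(
            ["INTS6", "increased", "WIF-1", "expression"],
            label=1,
            mentions=[ProteinMention(0, 1, "INTS6"), ProteinMention(2, 3, "WIF-1")],
        )
        inst = mask_pair(s, 0, 1)
        assert inst.tokens == ["PROT1", "increased", "PROT2", "expression"]
        assert inst.label == 1

    def test_same_index_rejected(self):
        s = sent(["A", "binds", "B"], mentions=[ProteinMention(0, 1, "A"), ProteinMention(2, 3, "B")])
        with pytest.raises(InvalidPairError):
            mask_pair(s, 1, 1)
        with pytest.raises(InvalidPairError):
            mask_pair(s, 0, 5)

    def test_third_party_mention_left_verbatim(self):
        s = sent(
            ["A", "binds", "B", "and", "C"],
            mentions=[ProteinMention(0, 1, "A"), ProteinMention(2, 3, "B"), ProteinMention(4, 5, "C")],
        )
        inst = mask_pair(s, 0, 2)
        assert inst.tokens == ["PROT1", "binds", "B", "and", "PROT2"]

    def test_token_count_conservation(self):
        s = sent(
            ["The", "TGF", "beta", "receptor", "binds", "SMAD2"],
            mentions=[ProteinMention(1, 4, "TGF beta receptor"), ProteinMention(5, 6, "SMAD2")],
        )
        inst = mask_pair(s, 0, 1)
        span_widths = (4 - 1) + (6 - 5)
        assert len(inst.tokens) == len(s.tokens) - (span_widths - 2)

    def test_enumeration_and_pair_annotations(self):
        s = sent(
            ["A", "binds", "B", "and", "C"],
            label=1,
            mentions=[ProteinMention(0, 1, "A"), ProteinMention(2, 3, "B"), ProteinMention(4, 5, "C")],
        )
        assert len(masked_instances(s)) == 3  # C(3,2)
        annotated = masked_instances(s, pairs=[(0, 2)])
        assert len(annotated) == 1 and annotated[0].pair == (0, 2)
        assert masked_instances(sent(["A"], mentions=[ProteinMention(0, 1, "A")])) == []


class TestTagTokens:
    @pytest.mark.parametrize(
        "n,mentions,expected",
        [
            (4, [(0, 1)], ["P", "O", "O", "O"]),
            (3, [], ["O", "O", "O"]),
            (5, [(2, 4)], ["O", "O", "P", "P", "O"]),
        ],
    )
    def test_span_projection(self, n, mentions, expected):
        words = [f"w{i}" for i in range(n)]
        ms = [ProteinMention(a, b, " ".join(words[a:b])) for a, b in mentions]
        assert tag_tokens(sent(words, mentions=ms)).tags == expected

    def test_p_count_equals_span_widths(self, small_corpus):
        for r in small_corpus[:50]:
            widths = sum(m.end - m.start for m in r.sentence.mentions)
            assert r.tagged.tags.count("P") == widths


class TestSplit6040:
    def test_sizes(self):
        split = split_60_40(list(range(10)), seed=0)
        assert len(split.train) == 6 and len(split.test) == 4

    def test_benchmark_corpus_size(self):
        assert len(split_60_40(list(range(3067)), seed=1).train) == 1840

    def test_deterministic_and_exact_partition(self):
        data = [f"s{i}" for i in range(37)]
        a, b = split_60_40(data, seed=5), split_60_40(data, seed=5)
        assert a.train == b.train and a.test == b.test
        assert sorted(a.train + a.test) == sorted(data)
        assert set(a.train).isdisjoint(a.test)

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_60_40(["only"], seed=0)


class TestInterchangeFormats:
    def test_labeled_jsonl_round_trip(self, tmp_path, small_corpus):
        path = tmp_path / "s.jsonl"
        originals = [r.sentence for r in small_corpus[:5]]
        write_labeled_jsonl(originals, path)
        assert read_labeled_jsonl(path) == originals

    def test_missing_label_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        good = {"pmid": "1", "tokens": ["A"], "label": 0, "mentions": []}
        path.write_text(json.dumps(good) + "\n" + json.dumps({"tokens": ["B"], "mentions": []}) + "\n")
        with pytest.raises(ValueError, match=r":2:"):
            read_labeled_jsonl(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_labeled_jsonl(path) == []

    def test_conll_round_trip_two_blocks(self, tmp_path):
        path = tmp_path / "t.conll"
        sents = [
            TaggedSentence([Token("INTS6", "NNP"), Token("binds", "VBZ")], ["P", "O"]),
            TaggedSentence([Token("x", "NN")], ["O"]),
        ]
        write_conll_tagged(sents, path)
        back = read_conll_tagged(path)
        assert len(back) == 2
        assert back == sents

    def test_conll_rejects_bio_tags(self, tmp_path):
        path = tmp_path / "t.conll"
        path.write_text("INTS6\tNNP\tB-PROT\n")
        with pytest.raises(ValueError, match="B-PROT"):
            read_conll_tagged(path)

    def test_abstracts_round_trip(self, tmp_path):
        path = tmp_path / "a.jsonl"
        recs = [("123", "A binds B."), ("456", "Nothing here.")]
        write_abstracts_jsonl(recs, path)
        assert read_abstracts_jsonl(path) == recs


class TestSharedTaskXML:
    XML = """<?xml version="1.0"?>
<corpus source="demo">
 <document id="d1">
  <sentence id="d1.s0" text="INTS6 increased WIF-1 expression">
   <entity id="d1.s0.e0" charOffset="0-4" text="INTS6"/>
   <entity id="d1.s0.e1" charOffset="16-20" text="WIF-1"/>
   <interaction id="d1.s0.i0" e1="d1.s0.e0" e2="d1.s0.e1"/>
  </sentence>
  <sentence id="d1.s1" text="ATP levels were low">
  </sentence>
 </document>
</corpus>"""

    def test_best_effort_conversion(self, tmp_path):
        path = tmp_path / "c.xml"
        path.write_text(self.XML)
        converted = corpus.convert_shared_task_xml(path)
        assert len(converted) == 2
        s0, pairs0 = converted[0]
        assert s0.label == 1
        assert [m.surface for m in s0.mentions] == ["INTS6", "WIF-1"]
        assert pairs0 == [(0, 1)]
        s1, pairs1 = converted[1]
        assert s1.label == 0 and s1.mentions == [] and pairs1 == []


class TestClassificationInstances:
    def test_masked_vs_raw(self, small_corpus):
        sentences = [r.sentence for r in small_corpus[:20]]
        Xm, ym = classification_instances(sentences, mode="masked")
        Xr, yr = classification_instances(sentences, mode="raw")
        assert len(Xr) == 20
        assert all(("PROT1" in x and "PROT2" in x) for x in Xm)
        assert len(Xm) == sum(1 for s in sentences if len(s.mentions) >= 2)
        with pytest.raises(ValueError):
            classification_instances(sentences, mode="nope")
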