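# ppiminer

Extraction of protein–protein interaction (PPI) networks from biomedical
abstracts by text mining. The volume of published literature makes manual
curation of interaction evidence slow and perpetually out of date; given a
set of pre-fetched abstracts (PMID + text), this package finds the
sentences that actually assert an interaction, locates the protein names
in them, recovers the word that expresses the relation, and merges
everything into an annotated interaction graph whose edges carry the
relation words and the PMIDs of the supporting articles.

The system runs three models in a fixed order:

1. **Sentence classification** — a frozen pretrained word-embedding layer
   (plain-text word-vector files, 200-dimensional by default, e.g.
   BioWordVec or GloVe) feeding a bidirectional LSTM — either one layer of
   100 units or three stacked layers of 32 units — and a dense softmax
   over {PPI, not-PPI}. Each LSTM cell follows the standard gate
   equations

   ```
   i_t = σ(W_ix x_t + W_ih h_{t−1} + b_i)
   f_t = σ(W_fx x_t + W_fh h_{t−1} + b_f)
   o_t = σ(W_ox x_t + W_oh h_{t−1} + b_o)
   c_t = f_t ⊙ c_{t−1} + i_t ⊙ tanh(W_cx x_t + W_ch h_{t−1} + b_c)
   h_t = o_t ⊙ tanh(c_t)
   ```

   run forward and backward over the token sequence; a positive-class
   probability ≥ 0.5 labels the sentence as PPI-bearing. Training data are
   benchmark PPI corpora (AIMed/BioInfer style) in which each candidate
   protein pair is masked as `PROT1`/`PROT2`.

2. **Protein-name tagging** — a linear-chain conditional random field
   over the two-label scheme {P, O} (protein token / other), trained by
   L-BFGS with an elastic-net penalty (c1 = c2 = 0.1) on surface, suffix,
   shape and POS features of each token and its ±1 neighbors. Maximal
   runs of P become protein mentions. Evaluation uses support-weighted F1,
   as P tokens are heavily outnumbered by O tokens.

3. **Relation extraction** — the sentence's dependency parse (consumed
   from a pluggable parser, never computed here) is viewed as an
   undirected tree; for every protein pair the shortest dependency path
   (SDP) between the mention heads is walked, and interior tokens whose
   dependency labels match the pattern `amod* conj* ROOT* acomp*` are
   emitted as relation words. The pair is oriented by the protein tokens'
   own labels (`nsubj/amod/compound` → agent; `dobj/pobj/npadvmod/appos`
   → patient).

Precision, recall and F1 are computed as
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`.

The two learned models are scikit-learn-style estimators
(`BiLSTMSentenceClassifier`, `CRFTagger`: `fit`/`predict`/`get_params`),
so they compose with sklearn model selection. A synthetic-corpus
generator (`ppiminer.fixtures`) produces labeled sentences, gold P/O
tags, hand-templated dependency parses and synthetic embedding files, so
the whole pipeline is testable without downloading corpora, pretrained
vectors, or a parser.

## Worked example

The three-protein sentence from the relation-extraction walkthrough:

```python
from ppiminer.fixtures import fig4_fixture
from ppiminer.relations import extract_candidates
from ppiminer.network import build_network

record = fig4_fixture()   # sentence + gold mentions + hand-built parse
candidates = extract_candidates(
    record.sentence.texts, record.sentence.mentions, record.parse, pmid="fig4"
)
for c in candidates:
    print(f"{c.protein_a.surface} -- {c.protein_b.surface}: {c.relation_words}")
graph = build_network(candidates)
print(f"network: {graph.n_nodes()} nodes, {graph.n_edges()} edges")
```

prints

```
INTS6 -- WIF-1: ['increased']
INTS6 -- Wnt/beta-catenin: ['increased', 'inhibited']
WIF-1 -- Wnt/beta-catenin: ['increased', 'inhibited']
network: 3 nodes, 3 edges
```

The sentence has three tagged proteins, so exactly C(3,2) = 3 relations
are extractable. On the INTS6 → WIF-1 path the only pattern-matching
interior token is the ROOT verb *increased*; the paths into
*Wnt/beta-catenin* additionally cross the conjoined verb *inhibited*,
which is how the pattern recovers both assertions made by the sentence.

## Command line

```
ppiminer simulate --n 2000 --seed 42 --out fx/          # synthetic corpus
ppiminer train-classifier --train fx/sentences.jsonl --mode raw --out clf/
ppiminer train-ner --train fx/tagged.conll --out crf/
ppiminer extract --abstracts fx/abstracts.jsonl --classifier clf/ \
    --ner crf/ --parses fx/parses.tsv --out network/
```

`extract` writes `network.graphml`, `network_edges.tsv`, `network.json`,
`candidates.jsonl` and a `report.json` with per-stage counters.

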