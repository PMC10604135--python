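"""Encoding, embedding matrix, model construction, training, prediction."""

import numpy as np
import pytest

from ppiminer.classifier import (
    BiLSTMSentenceClassifier,
    ClassifierConfig,
    build_model,
    encode,
    load_classifier,
    save_classifier,
)
from ppiminer.corpus import classification_instances, split_60_40
from ppiminer.embeddings import build_embedding_matrix
from ppiminer.fixtures import generate_embedding_file
from ppiminer.nn import softmax


@pytest.fixture()
def vector_file(tmp_path):
    return str(generate_embedding_file(["alpha", "beta", "binds"], 8, 0, tmp_path / "v.txt"))


class TestEncode:
    def test_three_tokens_padded_to_120(self):
        vocab = {"a": 1, "b": 2, "c": 3}
        ids = encode(["a", "b", "c"], vocab)
        assert ids.shape == (120,)
        assert list(ids[:3]) == [1, 2, 3]
        assert np.count_nonzero(ids) == 3

    def test_empty_sentence_all_zero(self):
        assert not np.any(encode([], {"a": 1}))

    def test_long_sentence_truncated_at_tail(self):
        vocab = {f"w{i}": i + 1 for i in range(130)}
        ids = encode([f"w{i}" for i in range(130)], vocab)
        assert len(ids) == 120
        assert ids[-1] == vocab["w119"]


class TestEmbeddingMatrix:
    def test_file_vector_copied_and_padding_zero(self, vector_file):
        em = build_embedding_matrix(["alpha", "novel"], vector_file, dim=8, seed=1)
        file_vec = np.array(open(vector_file).readline().split()[1:], dtype=float)
        assert np.allclose(em.matrix[em.vocab["alpha"]], file_vec)
        assert not np.any(em.matrix[0])

    def test_oov_rows_seeded_and_bounded(self, vector_file):
        a = build_embedding_matrix(["alpha", "novel"], vector_file, dim=8, seed=1)
        b = build_embedding_matrix(["alpha", "novel"], vector_file, dim=8, seed=1)
        row = a.matrix[a.vocab["novel"]]
        assert np.allclose(row, b.matrix[b.vocab["novel"]])
        assert np.all(np.abs(row) < 0.25)

    def test_mask_tokens_always_included(self, vector_file):
        em = build_embedding_matrix(["alpha"], vector_file, dim=8, seed=0)
        assert "PROT1" in em.vocab and "PROT2" in em.vocab

    def test_dimension_mismatch_rejected(self, vector_file):
        with pytest.raises(ValueError):
            build_embedding_matrix(["alpha"], vector_file, dim=16, seed=0)


class TestBuildModel:
    def test_three_layer_stack_totals_96_units_per_direction(self):
        config = ClassifierConfig(n_bilstm_layers=3)
        assert sum(config.layer_units) == 96

    def test_invalid_layer_count_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(n_bilstm_layers=2)

    def test_trainable_parameter_count_closed_form(self, vector_file):
        em = build_embedding_matrix(["alpha"], vector_file, dim=8, seed=0)
        config = ClassifierConfig(n_bilstm_layers=3, stacked_hidden_units=4)
        net = build_model(config, em)
        expected = 0
        d_in = 8
        for u in (4, 4, 4):
            expected += 2 * 4 * (d_in + u + 1) * u
            d_in = 2 * u
        expected += 2 * 4 * 2 + 2  # dense over the concatenated final state
        assert net.n_trainable_parameters() == expected

    def test_softmax_normalization(self):
        z = np.random.default_rng(0).normal(size=(6, 2)) * 10
        assert np.allclose(softmax(z).sum(axis=1), 1.0, atol=1e-6)


class TestTraining:
    def test_single_instance_overfits_within_40_epochs(self, vector_file):
        clf = BiLSTMSentenceClassifier(
            n_bilstm_layers=1, single_layer_units=8, epochs=40,
            learning_rate=1e-2, embedding_dim=8, vector_file=vector_file, random_state=0,
        )
        clf.fit([["alpha", "binds", "beta"]], [1])
        p, label = clf.predict_one(["alpha", "binds", "beta"])
        assert p > 0.5 and label == 1

    def test_loss_decreases_on_separable_corpus(self, small_corpus, tmp_path):
        sentences = [r.sentence for r in small_corpus]
        X, y = classification_instances(sentences, mode="masked")
        clf = BiLSTMSentenceClassifier(
            n_bilstm_layers=1, single_layer_units=16, epochs=5,
            learning_rate=1e-3, embedding_dim=16, random_state=0,
        )
        clf.fit(X, y)
        assert clf.history_[-1]["loss"] <= clf.history_[0]["loss"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            BiLSTMSentenceClassifier().fit([], [])

    def test_fixed_seed_reproducible(self, vector_file):
        def train():
            clf = BiLSTMSentenceClassifier(
                n_bilstm_layers=1, single_layer_units=4, epochs=2,
                learning_rate=1e-3, embedding_dim=8, vector_file=vector_file, random_state=5,
            )
            clf.fit([["alpha", "binds", "beta"], ["alpha", "beta"]], [1, 0])
            return clf.history_[0]["loss"]

        assert train() == train()


class TestPredict:
    def test_threshold_is_inclusive_at_half(self):
        clf = BiLSTMSentenceClassifier()
        clf.predict_proba = lambda X: np.array([[0.5, 0.5], [0.51, 0.49]])
        assert list(clf.predict([["a"], ["b"]])) == [1, 0]

    def test_probabilities_sum_to_one(self, vector_file):
        clf = BiLSTMSentenceClassifier(
            n_bilstm_layers=1, single_layer_units=4, epochs=1,
            embedding_dim=8, vector_file=vector_file,
        )
        clf.fit([["alpha", "beta"]], [0])
        probs = clf.predict_proba([["alpha"], ["beta", "binds"]])
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            BiLSTMSentenceClassifier().predict([["a"]])


class TestArtifact:
    def test_save_load_round_trip(self, tmp_path, vector_file):
        clf = BiLSTMSentenceClassifier(
            n_bilstm_layers=3, stacked_hidden_units=4, epochs=2,
            embedding_dim=8, vector_file=vector_file, random_state=1,
        )
        clf.fit([["alpha", "binds", "beta"], ["alpha", "beta"]], [1, 0])
        save_classifier(clf, tmp_path / "model")
        loaded = load_classifier(tmp_path / "model")
        X = [["alpha", "binds", "beta"], ["beta"], ["binds"]]
        assert np.allclose(clf.predict_proba(X), loaded.predict_proba(X))
        assert loaded.get_params() == clf.get_params()
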