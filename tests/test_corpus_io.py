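"""Corpus serialization, lexica, feature binarization, probe encodings and
training filters."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgn400 import (EncodingConfig, FillerFeatureTable, Frame,
                    FrameAnnotatedSentence, binarize_embeddings, build_lexicon,
                    encode_probes, filter_training_sentences,
                    read_frame_corpus, read_word2vec_text, sample_corpus,
                    synthetic_embeddings, write_frame_corpus,
                    write_word2vec_text)
from sgn400.corpus_io import (DEFAULT_ROLE_INVENTORY, MICRO_ROLE_INVENTORY,
                              CorpusParseError, Lexicon)


def _nested_event_sentence():
    # 13 tokens carrying three nested event frames
    tokens = ("she", "took", "great", "heaving", "breaths", "as", "though",
              "she", "had", "come", "up", "a", "hill")
    frames = (
        Frame(1, "took", (("A0", "she"), ("A1", "breaths"), ("AM-MNR", "as"))),
        Frame(2, "heaving", (("A1", "breaths"),)),
        Frame(3, "come", (("A0", "she"), ("AM-DIR", "up"))),
    )
    return FrameAnnotatedSentence(tokens, frames)


class TestFrameCorpusIO:
    def test_multi_frame_sentence_roundtrip(self, tmp_path):
        sent = _nested_event_sentence()
        path = tmp_path / "c.jsonl"
        write_frame_corpus(path, [sent])
        (back,) = read_frame_corpus(path)
        assert back.n_words == 13
        assert back.n_frames == 3
        assert back == sent

    def test_roundtrip_identity_on_sampled_corpus(self, tmp_path, world):
        corpus = sample_corpus(world, 50, seed=3)
        path = tmp_path / "c.jsonl"
        write_frame_corpus(path, corpus)
        assert read_frame_corpus(path, world.roles) == corpus

    def test_unknown_role_label_reports_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        good = {"tokens": ["a", "b"], "frames": [
            {"index": 1, "predicate": "b", "args": [{"role": "A0", "filler": "a"}]}]}
        bad = {"tokens": ["a", "b"], "frames": [
            {"index": 1, "predicate": "b", "args": [{"role": "XYZ", "filler": "a"}]}]}
        path.write_text(json.dumps(good) + "\n" + json.dumps(bad) + "\n")
        with pytest.raises(CorpusParseError, match="line 2"):
            read_frame_corpus(path)

    def test_noncontiguous_frame_indices_rejected(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        rec = {"tokens": ["a"], "frames": [
            {"index": 2, "predicate": "a", "args": []}]}
        path.write_text(json.dumps(rec) + "\n")
        with pytest.raises(CorpusParseError, match="line 1"):
            read_frame_corpus(path)


def _word_corpus(counts):
    """Corpus realizing given token counts (one word per sentence)."""
    sents = []
    for w, c in counts.items():
        sents += [FrameAnnotatedSentence((w,), ())] * c
    return sents


class TestLexicon:
    def test_most_frequent_kept(self):
        lex = build_lexicon(_word_corpus({"a": 5, "b": 3, "c": 1}), max_size=2)
        assert "a" in lex and "b" in lex
        assert lex.get("c") == lex.oov_index

    def test_no_truncation_when_large(self):
        lex = build_lexicon(_word_corpus({"a": 1, "b": 1}), max_size=50)
        assert "a" in lex and "b" in lex
        assert len(lex) == 4  # two words + OOV + start

    def test_lexicographic_tie_break(self):
        lex = build_lexicon(_word_corpus({"b": 2, "a": 2}), max_size=1)
        assert "a" in lex and "b" not in lex

    def test_bad_max_size(self):
        with pytest.raises(ValueError):
            build_lexicon(_word_corpus({"a": 1}), max_size=0)

    def test_indices_contiguous_and_specials(self):
        lex = build_lexicon(_word_corpus({"a": 2, "b": 1}), max_size=2)
        assert sorted(lex.index.values()) == list(range(len(lex)))
        with pytest.raises(ValueError):
            Lexicon({"a": 0, "b": 2})  # gap, no specials


class TestBinarize:
    def test_sign_rule(self):
        table = binarize_embeddings({"w": np.array([0.3, -0.2, 0.0])})
        assert table.get("w").tolist() == [1.0, 0.0, 0.0]

    def test_all_positive_gives_ones(self):
        table = binarize_embeddings({"w": np.array([0.1, 2.0, 0.5])})
        assert table.get("w").tolist() == [1.0, 1.0, 1.0]

    def test_matches_elementwise_oracle(self, rng):
        emb = {f"w{i}": rng.standard_normal(300) for i in range(40)}
        table = binarize_embeddings(emb, threshold=0.1)
        for w, v in emb.items():
            expected = np.array([1.0 if x > 0.1 else 0.0 for x in v])
            np.testing.assert_array_equal(table.get(w), expected)

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            binarize_embeddings({"a": np.zeros(3), "b": np.zeros(4)})


class TestWord2VecText:
    def test_roundtrip(self, tmp_path, rng):
        emb = {f"w{i}": rng.standard_normal(8) for i in range(5)}
        path = tmp_path / "emb.txt"
        write_word2vec_text(path, emb)
        back = read_word2vec_text(path)
        assert set(back) == set(emb)
        for w in emb:
            np.testing.assert_allclose(back[w], emb[w], rtol=1e-4)


@pytest.fixture(scope="module")
def enc():
    return EncodingConfig(MICRO_ROLE_INVENTORY, n_features=8, n_frames=2)


@pytest.fixture(scope="module")
def features(enc):
    words = ["boy", "opened", "door", "slowly"]
    return binarize_embeddings(synthetic_embeddings(words, enc.n_features, seed=1))


class TestEncodeProbes:
    def _sentence(self):
        return FrameAnnotatedSentence(
            ("the", "boy", "opened", "the", "door", "slowly"),
            (Frame(1, "opened", (("A0", "boy"), ("V", "opened"),
                                 ("A1", "door"), ("AM-MNR", "slowly"))),))

    def test_two_probes_per_argument(self, enc, features):
        pairs = encode_probes(self._sentence(), features, enc)
        assert len(pairs) == 8  # 4 arguments x (role probe + filler probe)

    def test_role_probe_layout(self, enc, features):
        pairs = encode_probes(self._sentence(), features, enc)
        probe, target = pairs[0]       # frame-major, role probe first (A0 boy)
        F, R = enc.n_features, enc.n_roles
        assert probe.probe_kind == "role"
        assert (probe.vector[F:F + R] == 0).all()
        assert probe.vector[:F].any()
        # the target carries the agent role one-hot
        assert target[F + MICRO_ROLE_INVENTORY.index("A0")] == 1.0
        assert target[F:F + R].sum() == 1.0

    def test_filler_probe_layout(self, enc, features):
        probe, _ = encode_probes(self._sentence(), features, enc)[1]
        F, R = enc.n_features, enc.n_roles
        assert probe.probe_kind == "filler"
        assert (probe.vector[:F] == 0).all()
        assert probe.vector[F:F + R].sum() == 1.0

    def test_target_one_hot_invariants(self, enc, features, world):
        for sent in sample_corpus(world, 20, seed=5):
            feats = binarize_embeddings(
                synthetic_embeddings(world.vocabulary(), enc.n_features, seed=2))
            for _, target in encode_probes(sent, feats, enc):
                F, R = enc.n_features, enc.n_roles
                assert target[F:F + R].sum() == 1.0
                assert target[F + R:].sum() == 1.0

    def test_frame_index_beyond_k_rejected(self, enc, features):
        sent = FrameAnnotatedSentence(
            ("a", "b", "c"),
            tuple(Frame(i, "b", (("A0", "boy"),)) for i in (1, 2, 3)))
        with pytest.raises(ValueError, match="frame index"):
            encode_probes(sent, features, enc)


class TestTrainingFilter:
    def _sent(self, n_words, n_frames=1):
        return FrameAnnotatedSentence(
            tuple(f"w{i}" for i in range(n_words)),
            tuple(Frame(i + 1, "w0", ()) for i in range(n_frames)))

    @pytest.mark.parametrize("n_words,kept", [(5, False), (6, True),
                                              (15, True), (16, False)])
    def test_word_count_bounds(self, n_words, kept):
        out = filter_training_sentences([self._sent(n_words)])
        assert bool(out) is kept

    def test_frame_count_bound(self):
        assert not filter_training_sentences([self._sent(10, n_frames=9)])
        assert filter_training_sentences([self._sent(10, n_frames=8)])

    def test_empty_corpus(self):
        assert filter_training_sentences([]) == []

    @given(st.lists(st.tuples(st.integers(1, 20), st.integers(0, 10)),
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_subsequence_and_idempotent(self, sizes):
        corpus = [self._sent(w, f) if f else self._sent(w)
                  for w, f in [(w, max(f, 0)) for w, f in sizes]]
        out = filter_training_sentences(corpus)
        it = iter(corpus)
        assert all(any(s is t for t in it) for s in out)  # subsequence
        assert filter_training_sentences(out) == out      # idempotent


def test_default_role_inventory_has_26_labels():
    assert len(DEFAULT_ROLE_INVENTORY) == 26
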