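import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scholarprofiler.metrics_semantic import (
    RandomProjectionEmbedder,
    TermWeightVector,
    bert_score,
    kl_divergence,
    load_mesh_vocabulary,
    novel_term_count,
    profile_kl,
    profile_kl_batch,
    tfidf_weights,
    to_distribution,
)


class TestMeshVocabulary:
    def test_fixture_roundtrip_case_insensitive(self, mesh_fixture_xml):
        vocab = load_mesh_vocabulary(mesh_fixture_xml)
        assert len(vocab.descriptors) == 5
        assert "neoplasms" in vocab
        assert "NEOPLASMS" in vocab
        assert vocab.lookup("nlp") == "Natural Language Processing"

    def test_entry_terms_present(self, mesh_fixture_xml):
        vocab = load_mesh_vocabulary(mesh_fixture_xml)
        for term in ("Tumors", "Cancer", "Neoplasms"):
            assert term in vocab
        assert vocab.lookup("cancer") == "Neoplasms"

    def test_absent_term(self, mesh_fixture_xml):
        vocab = load_mesh_vocabulary(mesh_fixture_xml)
        assert "zebrafish" not in vocab
        assert vocab.lookup("zebrafish") is None

    def test_tree_numbers(self, mesh_fixture_vocab):
        assert mesh_fixture_vocab.tree_numbers("Neoplasms") == ["C04"]

    def test_malformed_xml(self):
        from scholarprofiler.records import ParseError

        with pytest.raises(ParseError):
            load_mesh_vocabulary(b"<DescriptorRecordSet><broken>")


class TestTfidf:
    def test_term_in_every_doc_weighs_zero(self):
        docs = [["shared", "x"], ["shared", "y"], ["shared", "z"]]
        vecs = tfidf_weights(docs, stop_words=())
        assert all(v.weights["shared"] == 0.0 for v in vecs)

    def test_hand_computed_weight(self):
        # term twice in doc1 of a 2-doc corpus -> 2*ln2 there, absent in doc2
        docs = [["term", "term", "other"], ["other"]]
        vecs = tfidf_weights(docs, stop_words=())
        assert vecs[0].weights["term"] == pytest.approx(2 * math.log(2))
        assert "term" not in vecs[1].weights

    def test_stopword_only_doc_is_empty(self):
        vecs = tfidf_weights([["the", "and"], ["signal", "term"]],
                             stop_words={"the", "and"})
        assert vecs[0].weights == {}

    def test_single_doc_corpus_rejected(self):
        with pytest.raises(ValueError, match="document frequency|df|>= 2"):
            tfidf_weights([["a"]])


class TestToDistribution:
    def test_uniform_weights(self):
        v = TermWeightVector("d", {t: 2.0 for t in "abcd"})
        dist = to_distribution(v, list("abcd"), epsilon=1e-9)
        for p in dist.probabilities.values():
            assert p == pytest.approx(0.25)

    def test_all_zero_vector_is_uniform(self):
        v = TermWeightVector("d", {})
        dist = to_distribution(v, list("abc"), epsilon=1e-9)
        for p in dist.probabilities.values():
            assert p == pytest.approx(1 / 3)

    def test_small_epsilon_limit(self):
        v = TermWeightVector("d", {"a": 3.0, "b": 1.0})
        dist = to_distribution(v, ["a", "b"], epsilon=1e-12)
        assert dist.probabilities["a"] == pytest.approx(0.75)
        assert dist.probabilities["b"] == pytest.approx(0.25)

    def test_bad_epsilon(self):
        v = TermWeightVector("d", {"a": 1.0})
        with pytest.raises(ValueError):
            to_distribution(v, ["a"], epsilon=0.0)


class TestKlDivergence:
    def test_identity_is_zero(self):
        p = to_distribution(TermWeightVector("d", {"a": 1, "b": 2}), ["a", "b"])
        assert kl_divergence(p, p) == 0.0

    def test_hand_evaluated_sum(self):
        p = to_distribution(TermWeightVector("p", {"a": 0.8, "b": 0.2}),
                            ["a", "b"], epsilon=1e-15)
        q = to_distribution(TermWeightVector("q", {"a": 0.5, "b": 0.5}),
                            ["a", "b"], epsilon=1e-15)
        expected = 0.8 * math.log(0.8 / 0.5) + 0.2 * math.log(0.2 / 0.5)
        assert kl_divergence(p, q) == pytest.approx(expected, rel=1e-6)

    def test_mismatched_support_rejected(self):
        p = to_distribution(TermWeightVector("p", {"a": 1}), ["a", "b"])
        q = to_distribution(TermWeightVector("q", {"c": 1}), ["c", "d"])
        with pytest.raises(ValueError):
            kl_divergence(p, q)

    @given(
        w1=st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=3),
        w2=st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegativity_property(self, w1, w2):
        vocab = ["a", "b", "c"]
        p = to_distribution(dict(zip(vocab, w1)), vocab, epsilon=1e-6)
        q = to_distribution(dict(zip(vocab, w2)), vocab, epsilon=1e-6)
        assert kl_divergence(p, q) >= 0.0


class TestProfileKl:
    CORPUS = [
        "genomic variants drive tumor evolution in melanoma",
        "deep learning models segment cardiac images",
        "microbiome diversity shapes gut immunity",
    ]

    def test_identical_texts_zero(self):
        text = "profiling research interests with language models"
        assert profile_kl(text, text, self.CORPUS) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_exceeds_half_overlap(self):
        human = "alpha beta gamma delta epsilon zeta"
        disjoint = "omega psi chi phi upsilon tau"
        half = "alpha beta gamma phi upsilon tau"
        kl_disjoint = profile_kl(human, disjoint, self.CORPUS)
        kl_half = profile_kl(human, half, self.CORPUS)
        assert kl_disjoint > kl_half

    def test_empty_after_stopwords_is_none(self):
        assert profile_kl("the and of", "signal words here", self.CORPUS) is None

    def test_batch_identical_pairs_zero_variance(self):
        pair = ("neural decoding of speech", "neural decoding of speech")
        values, mean, var = profile_kl_batch([pair] * 5)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_tf_mode_and_directions(self):
        h, m = "alpha beta beta gamma", "alpha delta delta"
        for mode in ("tf", "tfidf"):
            fwd = profile_kl(h, m, self.CORPUS, mode=mode)
            bwd = profile_kl(h, m, self.CORPUS, mode=mode, direction="machine_to_human")
            sym = profile_kl(h, m, self.CORPUS, mode=mode, direction="symmetric")
            assert sym == pytest.approx(0.5 * (fwd + bwd))


class TestNovelTermCount:
    def test_subset_vocabulary_gives_zero(self, mesh_fixture_vocab):
        human = "heart failure and machine learning"
        machine = ["we apply machine learning to heart failure cohorts"]
        count, terms = novel_term_count(human, machine, mesh_vocab=mesh_fixture_vocab)
        assert (count, terms) == (0, [])

    def test_planted_mesh_terms_counted_nonmesh_ignored(self, mesh_fixture_vocab):
        # 3 planted MeSH terms + 2 absent non-MeSH tokens -> count 3
        human = (
            "I pioneered precision medicine, natural language processing and "
            "deep learning, plus flibbertigibbet and quuxology."
        )
        machine = ["a profile about cardiac imaging only"]
        count, terms = novel_term_count(human, machine, mesh_vocab=mesh_fixture_vocab)
        assert count == 3
        assert set(terms) == {
            "precision medicine",
            "natural language processing",
            "deep learning",
        }

    def test_empty_machine_texts_count_all_mesh_terms(self, mesh_fixture_vocab):
        human = "cancer and heart failure research"
        count, terms = novel_term_count(human, [], mesh_vocab=mesh_fixture_vocab)
        assert count == 2
        assert set(terms) == {"cancer", "heart failure"}

    def test_antitone_in_machine_text(self, mesh_fixture_vocab):
        human = "cancer, heart failure, and precision medicine"
        base, _ = novel_term_count(human, ["nothing relevant"],
                                   mesh_vocab=mesh_fixture_vocab)
        grown, _ = novel_term_count(
            human, ["nothing relevant", "heart failure trials"],
            mesh_vocab=mesh_fixture_vocab,
        )
        assert grown <= base

    def test_empty_human_rejected(self, mesh_fixture_vocab):
        with pytest.raises(ValueError):
            novel_term_count("  ", ["x"], mesh_vocab=mesh_fixture_vocab)

    def test_hyphen_normalization_matches(self, mesh_fixture_vocab):
        count, terms = novel_term_count(
            "advances in natural-language-processing", [],
            mesh_vocab=mesh_fixture_vocab,
        )
        assert terms == ["natural language processing"]


class TestBertScore:
    def test_identical_sequences(self):
        emb = RandomProjectionEmbedder(seed=3)
        toks = "scalable researcher profiling".split()
        p, r, f1 = bert_score(toks, toks, emb)
        assert (p, r, f1) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_known_angles_hand_computed(self):
        class PlaneEmbedder:
            def embed(self, tokens):
                table = {
                    "c": np.array([1.0, 0.0]),
                    "r1": np.array([1.0, 0.0]),
                    "r2": np.array([0.0, 1.0]),
                }
                return np.stack([table[t] for t in tokens])

        p, r, f1 = bert_score(["c"], ["r1", "r2"], PlaneEmbedder())
        assert p == pytest.approx(1.0)  # c matches r1 at cos 1
        assert r == pytest.approx(0.5)  # r1 -> 1, r2 -> 0
        assert f1 == pytest.approx(2 * 1 * 0.5 / 1.5)

    def test_empty_sequence(self):
        emb = RandomProjectionEmbedder()
        assert bert_score([], ["a"], emb) == (0.0, 0.0, 0.0)

    def test_permutation_invariance(self):
        emb = RandomProjectionEmbedder(seed=5)
        cand = "one two three four".split()
        ref = "alpha two gamma".split()
        p0, r0, f0 = bert_score(cand, ref, emb)
        p1, r1, f1 = bert_score(cand, ref[::-1], emb)
        assert (p1, f1) == (pytest.approx(p0), pytest.approx(f0))
        p2, r2, _ = bert_score(cand[::-1], ref, emb)
        assert r2 == pytest.approx(r0)

    def test_greedy_equals_nested_loop_oracle(self):
        from oracles import greedy_bertscore_nested

        emb = RandomProjectionEmbedder(seed=11)
        rng = np.random.default_rng(0)
        vocab = ["t%d" % i for i in range(10)]
        for _ in range(25):
            cand = list(rng.choice(vocab, size=rng.integers(1, 7)))
            ref = list(rng.choice(vocab, size=rng.integers(1, 7)))
            got = bert_score(cand, ref, emb)
            want = greedy_bertscore_nested(emb.embed(cand), emb.embed(ref))
            assert got == pytest.approx(want, abs=1e-9)

    def test_embedder_deterministic_across_instances(self):
        a = RandomProjectionEmbedder(seed=7).embed(["profiling", "mesh"])
        b = RandomProjectionEmbedder(seed=7).embed(["profiling", "mesh"])
        assert np.allclose(a, b)
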