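import numpy as np
import pytest
from scipy.special import expit

from augimodels.embeddings import EmbeddingCache, make_hash_embedder, make_onehot_embedder
from augimodels.linear import (
    AugLinearConfig,
    AugLinearModel,
    CoefficientDictionary,
    compress,
    featurize_document,
    fit_aug_linear,
    hybrid_predict,
    infer_coefficient,
    predict,
    to_coefficient_dictionary,
)
from augimodels.synthetic import SyntheticSpec, generate_classification_corpus, vocab_word
from augimodels.text import LabeledCorpus, TokenizerConfig, build_vocabulary

from conftest import small_planted_corpus


class TestFeaturize:
    def test_onehot_counts(self):
        vocab = build_vocabulary(["a b"], orders={1})
        backend = make_onehot_embedder(vocab)
        np.testing.assert_array_equal(
            featurize_document("a b a", backend, {1}), [2, 1]
        )

    def test_empty_document_is_zero(self, hash_backend):
        np.testing.assert_array_equal(
            featurize_document("", hash_backend, {1, 2}), np.zeros(hash_backend.dim)
        )

    def test_additive_over_ngrams(self, hash_backend):
        total = featurize_document("x y", hash_backend, {1, 2})
        parts = (
            hash_backend.embed("x") + hash_backend.embed("y") + hash_backend.embed("x y")
        )
        np.testing.assert_allclose(total, parts)

    def test_dedupe_flag(self):
        vocab = build_vocabulary(["a b"], orders={1})
        backend = make_onehot_embedder(vocab)
        np.testing.assert_array_equal(
            featurize_document("a b a", backend, {1}, dedupe=True), [1, 1]
        )


class TestFit:
    def test_separable_corpus_perfect_training_accuracy(self, separable_corpus, separable_onehot):
        _, backend = separable_onehot
        config = AugLinearConfig(orders=(1,), reg_strengths=(1e-3,))
        model = fit_aug_linear(separable_corpus, backend, config)
        preds = predict(model, separable_corpus.documents, backend=backend, return_proba=False)
        assert np.mean(preds == separable_corpus.labels) == 1.0

    def test_permuted_labels_fall_to_chance(self):
        corpus, _ = small_planted_corpus(seed=5, n_docs=1200)
        rng = np.random.default_rng(0)
        shuffled = LabeledCorpus(corpus.documents, rng.permutation(corpus.labels))
        train = LabeledCorpus(shuffled.documents[:400], shuffled.labels[:400])
        backend = make_hash_embedder(dim=64, seed=1)
        config = AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        model = fit_aug_linear(train, backend, config)
        preds = predict(model, shuffled.documents[400:], backend=backend, return_proba=False)
        accuracy = np.mean(preds == shuffled.labels[400:])
        majority = max(np.mean(shuffled.labels[400:]), 1 - np.mean(shuffled.labels[400:]))
        assert abs(accuracy - majority) <= 0.05 + 1e-9

    def test_single_class_rejected(self, hash_backend):
        corpus = LabeledCorpus(["a", "b"], np.array([1, 1]))
        with pytest.raises(ValueError, match="distinct labels"):
            fit_aug_linear(corpus, hash_backend)

    def test_nonfinite_features_rejected(self):
        class BrokenBackend:
            backend_id = "broken"
            dim = 2

            def embed(self, text):
                return np.array([np.nan, 0.0])

        corpus = LabeledCorpus(["a", "b"], np.array([0, 1]))
        config = AugLinearConfig(reg_strengths=(1.0,))
        with pytest.raises(ValueError, match="non-finite"):
            fit_aug_linear(corpus, BrokenBackend(), config)

    def test_cv_selects_among_grid(self, separable_corpus, separable_onehot):
        _, backend = separable_onehot
        config = AugLinearConfig(orders=(1,), reg_strengths=(1e-2, 1.0), cv_folds=2)
        model = fit_aug_linear(separable_corpus, backend, config)
        assert model.reg_strength in (1e-2, 1.0)
        assert len(model.cv_results) == 2

    def test_cache_transparency(self, separable_corpus):
        backend = make_hash_embedder(dim=32, seed=0)
        config = AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        cached = EmbeddingCache()
        m1 = fit_aug_linear(separable_corpus, backend, config, cache=cached)
        m2 = fit_aug_linear(separable_corpus, backend, config, cache=None)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        p1 = predict(m1, separable_corpus.documents, backend=backend, cache=cached)
        p2 = predict(m2, separable_corpus.documents, backend=backend)
        np.testing.assert_array_equal(p1, p2)


class TestPredict:
    def _intercept_only_model(self, intercept):
        return AugLinearModel(
            task="classification",
            link="logit",
            classes=np.array([0, 1]),
            intercept=np.array([intercept]),
            coef=np.zeros((1, 4)),
            backend_id="hash-d4-s0",
            orders=(1,),
            tokenizer=TokenizerConfig(),
            reg_strength=1.0,
        )

    def test_empty_document_gets_intercept_response(self):
        model = self._intercept_only_model(0.7)
        backend = make_hash_embedder(dim=4, seed=0)
        proba = predict(model, [""], backend=backend)
        assert proba[0, 1] == pytest.approx(expit(0.7))

    def test_zero_score_is_half(self):
        model = self._intercept_only_model(0.0)
        backend = make_hash_embedder(dim=4, seed=0)
        proba = predict(model, ["anything at all"], backend=backend)
        assert proba[0, 1] == pytest.approx(0.5)

    def test_probabilities_valid(self):
        corpus, truth = small_planted_corpus(seed=2)
        backend = make_hash_embedder(dim=64, seed=2)
        model = fit_aug_linear(corpus, backend, AugLinearConfig(orders=(1,), reg_strengths=(1.0,)))
        proba = predict(model, corpus.documents, backend=backend)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)


class TestDictionary:
    @pytest.fixture()
    def fitted(self):
        corpus, truth = small_planted_corpus(seed=3)
        backend = make_hash_embedder(dim=64, seed=3)
        config = AugLinearConfig(orders=(1, 2), reg_strengths=(1.0,))
        model = fit_aug_linear(corpus, backend, config)
        vocab = build_vocabulary(corpus, (1, 2))
        dictionary = to_coefficient_dictionary(model, vocab, backend)
        return corpus, backend, model, vocab, dictionary

    def test_one_entry_per_vocab_ngram(self, fitted):
        _, _, _, vocab, dictionary = fitted
        assert len(dictionary) == vocab.p

    def test_onehot_entries_equal_weight_components(self, separable_corpus, separable_onehot):
        vocab, backend = separable_onehot
        config = AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        model = fit_aug_linear(separable_corpus, backend, config)
        dictionary = to_coefficient_dictionary(model, vocab, backend)
        for i, gram in enumerate(vocab.ngrams):
            assert dictionary.entries[gram.text][0] == pytest.approx(model.coef[0, i])

    def test_dictionary_path_equals_embedding_path(self, fitted):
        corpus, backend, model, _, dictionary = fitted
        p_embed = predict(model, corpus.documents[:50], backend=backend)
        p_dict = predict(model, corpus.documents[:50], dictionary=dictionary)
        np.testing.assert_allclose(p_dict, p_embed, rtol=1e-8)

    def test_additivity_of_contributions(self, fitted):
        corpus, _, _, _, dictionary = fitted
        for doc in corpus.documents[:10]:
            rows = dictionary.contributions(doc)
            total = dictionary.intercept + sum(v for _, v in rows)
            np.testing.assert_allclose(total, dictionary.score_document(doc), rtol=1e-8)

    def test_unseen_ngram_warns_and_contributes_zero(self, fitted):
        *_, dictionary = fitted
        with pytest.warns(UserWarning, match="not in the coefficient dictionary"):
            rows = dictionary.contributions("zebra xylophone")
        looked_up = {t: v for t, v in rows}
        np.testing.assert_array_equal(looked_up["zebra"], [0.0])

    def test_json_round_trip_exact(self, tmp_path, fitted):
        *_, dictionary = fitted
        path = dictionary.save(tmp_path / "dictionary.json")
        loaded = CoefficientDictionary.load(path)
        assert set(loaded.entries) == set(dictionary.entries)
        for key, vec in dictionary.entries.items():
            np.testing.assert_array_equal(loaded.entries[key], vec)
        np.testing.assert_array_equal(loaded.intercept, dictionary.intercept)
        assert loaded.orders == dictionary.orders

    def test_tsv_export(self, tmp_path, fitted):
        *_, dictionary = fitted
        path = dictionary.to_tsv(tmp_path / "dictionary.tsv")
        lines = path.read_text().splitlines()
        assert lines[0] == "ngram\tcount\tcoef_0"
        assert len(lines) == len(dictionary) + 1


class TestInferCoefficient:
    def test_oov_onehot_coefficient_is_zero(self, separable_corpus, separable_onehot):
        vocab, backend = separable_onehot
        config = AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        model = fit_aug_linear(separable_corpus, backend, config)
        np.testing.assert_array_equal(infer_coefficient(model, "zzz", backend), [0.0])

    def test_training_ngram_matches_dictionary(self, separable_corpus, separable_onehot):
        vocab, backend = separable_onehot
        config = AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        model = fit_aug_linear(separable_corpus, backend, config)
        dictionary = to_coefficient_dictionary(model, vocab, backend)
        for gram in vocab.ngrams:
            np.testing.assert_allclose(
                infer_coefficient(model, gram, backend), dictionary.entries[gram.text]
            )

    def test_phrase_coefficient_not_sum_of_parts(self, separable_corpus):
        backend = make_hash_embedder(dim=32, seed=0)
        config = AugLinearConfig(orders=(1, 2), reg_strengths=(1.0,))
        model = fit_aug_linear(separable_corpus, backend, config)
        phrase = infer_coefficient(model, "not bad", backend)
        parts = infer_coefficient(model, "not", backend) + infer_coefficient(
            model, "bad", backend
        )
        assert not np.allclose(phrase, parts)


class TestCompress:
    def _toy_dictionary(self, entries):
        return CoefficientDictionary(
            entries={k: np.array([v]) for k, v in entries.items()},
            intercept=np.array([0.1]),
            link="logit",
            classes=[0, 1],
            orders=(1,),
            tokenizer=TokenizerConfig(),
        )

    def test_zero_drop_identity_predictions(self, separable_corpus, separable_onehot):
        vocab, backend = separable_onehot
        model = fit_aug_linear(
            separable_corpus, backend, AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        )
        dictionary = to_coefficient_dictionary(model, vocab, backend)
        same = compress(dictionary, 0.0)
        np.testing.assert_array_equal(
            same.predict(separable_corpus.documents),
            dictionary.predict(separable_corpus.documents),
        )

    def test_smallest_absolute_dropped(self):
        dictionary = self._toy_dictionary({"a": 0.1, "b": -2.0})
        kept = compress(dictionary, 0.5)
        assert set(kept.entries) == {"b"}
        np.testing.assert_array_equal(kept.intercept, dictionary.intercept)

    def test_lexicographic_tie_break(self):
        dictionary = self._toy_dictionary({"b": 1.0, "a": -1.0, "c": 2.0})
        kept = compress(dictionary, 1 / 3)
        # |a| == |b|; 'a' sorts first and is dropped
        assert set(kept.entries) == {"b", "c"}

    def test_invalid_fraction(self):
        dictionary = self._toy_dictionary({"a": 1.0})
        with pytest.raises(ValueError):
            compress(dictionary, 1.0)


class TestHybrid:
    @pytest.fixture()
    def setting(self):
        corpus, truth = small_planted_corpus(seed=4, n_docs=300)
        train = LabeledCorpus(corpus.documents[:200], corpus.labels[:200])
        test_docs = corpus.documents[200:]
        test_labels = corpus.labels[200:]
        backend = make_hash_embedder(dim=64, seed=4)
        model = fit_aug_linear(
            train, backend, AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        )
        label_of = dict(zip(corpus.documents, corpus.labels))

        class OracleFallback:
            def predict(self, docs):
                return np.array([label_of[d] for d in docs])

        return model, backend, OracleFallback(), test_docs, test_labels

    def test_threshold_zero_routes_everything_to_linear(self, setting):
        model, backend, fallback, docs, labels = setting
        result = hybrid_predict(model, fallback, 0.0, docs, backend=backend)
        assert result.linear_fraction == 1.0
        pure = predict(model, docs, backend=backend, return_proba=False)
        assert np.array_equal(result.predictions.astype(int), pure)

    def test_threshold_one_routes_everything_to_fallback(self, setting):
        model, backend, fallback, docs, labels = setting
        result = hybrid_predict(model, fallback, 1.0, docs, backend=backend)
        assert result.linear_fraction == 0.0
        assert np.array_equal(result.predictions.astype(int), labels)

    def test_accuracy_nondecreasing_with_oracle_fallback(self, setting):
        model, backend, fallback, docs, labels = setting
        accuracies = []
        for threshold in [0.0, 0.6, 0.8, 0.9, 1.0]:
            result = hybrid_predict(model, fallback, threshold, docs, backend=backend)
            accuracies.append(np.mean(result.predictions.astype(int) == labels))
        assert all(b >= a - 1e-12 for a, b in zip(accuracies, accuracies[1:]))

    def test_fallback_failure_reports_sample_index(self, setting):
        model, backend, _, docs, _ = setting

        def broken(texts):
            raise RuntimeError("backend down")

        with pytest.raises(RuntimeError, match="sample index"):
            hybrid_predict(model, broken, 1.0, docs, backend=backend)

    def test_invalid_threshold(self, setting):
        model, backend, fallback, docs, _ = setting
        with pytest.raises(ValueError):
            hybrid_predict(model, fallback, 1.5, docs, backend=backend)


class TestMulticlass:
    @pytest.fixture()
    def three_class(self):
        spec = SyntheticSpec(
            vocab_size=30,
            n_docs=250,
            doc_length_mean=8.0,
            doc_length_sd=2.0,
            effects={vocab_word(3): 3.0, vocab_word(4): -3.0},
            noise_scale=1.0,
            seed=11,
        )
        corpus, truth = generate_classification_corpus(spec)
        terciles = np.quantile(truth.latent_scores, [1 / 3, 2 / 3])
        labels = np.digitize(truth.latent_scores, terciles)
        return LabeledCorpus(corpus.documents, labels)

    def test_softmax_probabilities_and_dictionary_agreement(self, three_class):
        backend = make_hash_embedder(dim=64, seed=5)
        model = fit_aug_linear(
            three_class, backend, AugLinearConfig(orders=(1,), reg_strengths=(1.0,))
        )
        assert model.link == "softmax"
        proba = predict(model, three_class.documents[:40], backend=backend)
        assert proba.shape[1] == 3
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        vocab = build_vocabulary(three_class, (1,))
        dictionary = to_coefficient_dictionary(model, vocab, backend)
        assert all(v.shape == (3,) for v in dictionary.entries.values())
        p_dict = predict(model, three_class.documents[:40], dictionary=dictionary)
        np.testing.assert_allclose(p_dict, proba, rtol=1e-8)


class TestRegression:
    def test_identity_link_fit_and_dictionary(self):
        spec = SyntheticSpec(
            vocab_size=30,
            n_docs=200,
            doc_length_mean=8.0,
            doc_length_sd=2.0,
            effects={vocab_word(3): 2.0},
            seed=6,
        )
        corpus, truth = generate_classification_corpus(spec)
        continuous = LabeledCorpus(corpus.documents, truth.latent_scores)
        vocab = build_vocabulary(continuous, (1,))
        backend = make_onehot_embedder(vocab)
        config = AugLinearConfig(task="regression", orders=(1,), reg_strengths=(1e-6,))
        model = fit_aug_linear(continuous, backend, config)
        preds = predict(model, continuous.documents, backend=backend)
        # latent scores are an exact linear function of unigram counts
        np.testing.assert_allclose(preds, truth.latent_scores, atol=1e-3)
        dictionary = to_coefficient_dictionary(model, vocab, backend)
        planted = vocab_word(3)
        assert dictionary.entries[planted][0] == pytest.approx(2.0, abs=1e-3)
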