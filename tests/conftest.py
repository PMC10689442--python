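import numpy as np
import pytest

from augimodels.embeddings import make_hash_embedder, make_onehot_embedder
from augimodels.text import LabeledCorpus, build_vocabulary


@pytest.fixture(scope="session")
def hash_backend():
    return make_hash_embedder(dim=64, seed=7)


@pytest.fixture()
def separable_corpus():
    """Tiny binary corpus where one word ('good'/'bad') decides the label."""
    docs = [
        "a good movie overall",
        "good fun and good pacing",
        "what a good ending",
        "good good good",
        "a bad movie overall",
        "bad acting and bad pacing",
        "what a bad ending",
        "bad bad bad",
    ]
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    return LabeledCorpus(documents=docs, labels=labels)


@pytest.fixture()
def separable_onehot(separable_corpus):
    vocab = build_vocabulary(separable_corpus, orders={1})
    return vocab, make_onehot_embedder(vocab)


def small_planted_corpus(seed: int, n_docs: int = 200, vocab_size: int = 30):
    """Small planted-effect corpus for oracle-equivalence checks."""
    from augimodels.synthetic import SyntheticSpec, generate_classification_corpus, vocab_word

    spec = SyntheticSpec(
        vocab_size=vocab_size,
        n_docs=n_docs,
        doc_length_mean=8.0,
        doc_length_sd=2.0,
        effects={vocab_word(3): 2.0, vocab_word(4): -2.0},
        noise_scale=1.0,
        seed=seed,
    )
    return generate_classification_corpus(spec)
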