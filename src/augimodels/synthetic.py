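"""Synthetic corpora and response streams with planted, recoverable structure.

The classification generator emulates the statistical features the text
models have to cope with on real corpora:

* Zipfian token frequencies, so higher-order ngrams are dominated by
  rare (often singleton) combinations;
* additive planted ngram effects: a document's latent score is the sum
  of signed effects of the ngrams it contains, and its label is drawn
  Bernoulli(logistic(score / noise));
* sign-flipping negation bigrams — when the modifier immediately
  precedes its target the target's effect is replaced by a flipped
  value, so only bigram-aware models can capture it;
* synonym clusters sharing a single effect, with one member sampled per
  mention, guaranteeing that some members occur only in held-out
  documents — the regime in which expansion-augmented trees should
  generalize and plain CART cannot.

The regression generator produces a word stream plus per-timepoint
continuous responses driven by planted word weights inside a lagged
window (matching the encoding stage's 20-word window, 4-word delay
geometry), with Gaussian noise.

Every generated artifact ships with a ``GroundTruth`` recording the
planted parameters, latent scores and train/test partition; identical
specs and seeds yield byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .text import LabeledCorpus

__all__ = [
    "SyntheticSpec",
    "StreamSpec",
    "GroundTruth",
    "generate_classification_corpus",
    "generate_regression_stream",
    "default_classification_spec",
    "recovery_spec",
    "synonym_cluster_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-effect classification corpus.

    ``effects`` maps ngram text (members drawn from the token
    vocabulary, space-joined for higher orders) to a signed additive
    effect. ``negation_pairs`` are (modifier, target, flipped_effect)
    triples: an occurrence of ``target`` immediately preceded by
    ``modifier`` contributes ``flipped_effect`` instead of the target's
    base effect. ``synonym_clusters`` are (members, effect) pairs; on
    each mention one member is sampled uniformly.
    """

    vocab_size: int = 5000
    zipf_exponent: float = 1.1
    n_docs: int = 2000
    doc_length_mean: float = 25.0
    doc_length_sd: float = 5.0
    effects: dict = field(default_factory=dict)
    negation_pairs: tuple = ()
    synonym_clusters: tuple = ()
    effect_insert_prob: float = 0.3
    negation_insert_prob: float = 0.15
    cluster_mention_prob: float = 0.3
    noise_scale: float = 1.0
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for value in self.effects.values():
            if not np.isfinite(value):
                raise ValueError("planted effects must be finite")
        members_seen: set[str] = set()
        for members, _ in self.synonym_clusters:
            if members_seen & set(members):
                raise ValueError("synonym clusters must be disjoint")
            members_seen |= set(members)


@dataclass(frozen=True)
class StreamSpec:
    """Parameters of the lagged-window regression stream."""

    vocab_size: int = 1000
    zipf_exponent: float = 1.1
    n_timepoints: int = 1000
    words_per_timepoint: int = 4
    window: int = 20
    delay: int = 4
    n_effect_words: int = 10
    effect_scale: float = 1.0
    noise_sd: float = 0.1
    train_fraction: float = 0.8
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted parameters exported alongside every generated dataset."""

    effects: dict
    latent_scores: np.ndarray | None
    train_indices: np.ndarray
    test_indices: np.ndarray
    params: dict

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "effects": {k: float(v) for k, v in self.effects.items()},
            "latent_scores": None
            if self.latent_scores is None
            else [float(v) for v in self.latent_scores],
            "train_indices": [int(i) for i in self.train_indices],
            "test_indices": [int(i) for i in self.test_indices],
            "params": self.params,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks**-exponent
    return p / p.sum()


def vocab_word(rank: int) -> str:
    """Deterministic surface form for the vocabulary word of a given rank."""
    return f"w{rank:05d}"


def generate_classification_corpus(
    spec: SyntheticSpec,
) -> tuple[LabeledCorpus, GroundTruth]:
    """Draw a labeled corpus under the planted-effect model.

    Background tokens are iid Zipfian. Planted effect ngrams, negation
    pairs and one sampled synonym-cluster member are inserted at random
    positions with the spec's per-document probabilities (they may also
    occur by chance). The latent score sums effect contributions over
    the realized token sequence; labels are Bernoulli(logistic(score /
    noise_scale)). Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _zipf_probs(spec.vocab_size, spec.zipf_exponent)
    vocab = [vocab_word(r) for r in range(1, spec.vocab_size + 1)]

    # full effect table: explicit effects + per-member cluster effects
    effect_table: dict[str, float] = {k: float(v) for k, v in spec.effects.items()}
    for members, effect in spec.synonym_clusters:
        for m in members:
            effect_table[m] = float(effect)
    negation = {(mod, tgt): float(flip) for mod, tgt, flip in spec.negation_pairs}

    documents: list[str] = []
    scores = np.empty(spec.n_docs)
    labels = np.empty(spec.n_docs, dtype=int)
    for d in range(spec.n_docs):
        length = max(3, int(round(rng.normal(spec.doc_length_mean, spec.doc_length_sd))))
        tokens = [vocab[i] for i in rng.choice(spec.vocab_size, size=length, p=probs)]

        def insert(fragment: list[str]):
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens[pos:pos] = fragment

        for ngram in spec.effects:
            if rng.random() < spec.effect_insert_prob:
                insert(ngram.split())
        for mod, tgt, _ in spec.negation_pairs:
            if rng.random() < spec.negation_insert_prob:
                insert([mod, tgt])
        for members, _ in spec.synonym_clusters:
            if rng.random() < spec.cluster_mention_prob:
                insert([members[int(rng.integers(0, len(members)))]])

        score = _latent_score(tokens, effect_table, negation)
        scores[d] = score
        labels[d] = int(rng.random() < expit(score / spec.noise_scale))
        documents.append(" ".join(tokens))

    perm = rng.permutation(spec.n_docs)
    n_train = int(round(spec.train_fraction * spec.n_docs))
    truth = GroundTruth(
        effects=effect_table,
        latent_scores=scores,
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
        params={
            "kind": "classification",
            "vocab_size": spec.vocab_size,
            "zipf_exponent": spec.zipf_exponent,
            "n_docs": spec.n_docs,
            "noise_scale": spec.noise_scale,
            "negation_pairs": [list(p) for p in spec.negation_pairs],
            "synonym_clusters": [
                {"members": list(m), "effect": float(e)} for m, e in spec.synonym_clusters
            ],
            "seed": spec.seed,
        },
    )
    return LabeledCorpus(documents=documents, labels=labels), truth


def _latent_score(
    tokens: list[str],
    effect_table: dict[str, float],
    negation: dict[tuple[str, str], float],
) -> float:
    """Additive score with negation pairs overriding the target's effect."""
    max_order = max((len(k.split()) for k in effect_table), default=1)
    score = 0.0
    n = len(tokens)
    for i, tok in enumerate(tokens):
        # unigram effect, possibly flipped by an immediately preceding modifier
        base = effect_table.get(tok)
        if base is not None:
            if i > 0 and (tokens[i - 1], tok) in negation:
                score += negation[(tokens[i - 1], tok)]
            else:
                score += base
        # higher-order planted ngrams
        for k in range(2, max_order + 1):
            if i + k > n:
                break
            effect = effect_table.get(" ".join(tokens[i : i + k]))
            if effect is not None:
                score += effect
    return score


def generate_regression_stream(
    spec: StreamSpec,
) -> tuple[list[str], np.ndarray, np.ndarray, GroundTruth]:
    """Word stream + continuous responses from planted weights in a lagged window.

    Returns ``(words, offsets, responses, truth)`` where ``offsets[t]``
    is the number of words observed up to timepoint ``t`` (non-
    decreasing) and ``responses[t]`` is the weighted count of planted
    words inside the window that ends ``delay`` words before
    ``offsets[t]``, plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _zipf_probs(spec.vocab_size, spec.zipf_exponent)
    n_words = spec.n_timepoints * spec.words_per_timepoint
    word_idx = rng.choice(spec.vocab_size, size=n_words, p=probs)
    words = [vocab_word(i + 1) for i in word_idx]

    # planted weights on the most frequent words so the signal is expressed
    effect_ranks = np.arange(1, spec.n_effect_words + 1)
    weights = rng.normal(0.0, spec.effect_scale, size=spec.n_effect_words)
    effect_table = {vocab_word(r): float(w) for r, w in zip(effect_ranks, weights)}

    offsets = (np.arange(spec.n_timepoints) + 1) * spec.words_per_timepoint
    responses = np.empty(spec.n_timepoints)
    for t, m in enumerate(offsets):
        stop = max(0, m - spec.delay)
        start = max(0, stop - spec.window)
        signal = sum(effect_table.get(w, 0.0) for w in words[start:stop])
        responses[t] = signal + rng.normal(0.0, spec.noise_sd)

    n_train = int(round(spec.train_fraction * spec.n_timepoints))
    truth = GroundTruth(
        effects=effect_table,
        latent_scores=None,
        train_indices=np.arange(n_train),
        test_indices=np.arange(n_train, spec.n_timepoints),
        params={
            "kind": "regression_stream",
            "vocab_size": spec.vocab_size,
            "zipf_exponent": spec.zipf_exponent,
            "n_timepoints": spec.n_timepoints,
            "words_per_timepoint": spec.words_per_timepoint,
            "window": spec.window,
            "delay": spec.delay,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )
    return words, offsets, responses, truth


# ---------------------------------------------------------------------------
# canonical study conditions


def default_classification_spec(seed: int = 0) -> SyntheticSpec:
    """Corpus-scale conditions: Zipf 1.1 over 5000 types, 2000 documents.

    At these settings the trigram spectrum is dominated by singletons,
    mirroring real text-classification corpora.
    """
    return SyntheticSpec(seed=seed)


def recovery_spec(seed: int = 0) -> SyntheticSpec:
    """Planted-effect recovery regime: |effect| = 2, n = 2000, small vocab.

    Six planted unigrams (three positive, three negative), two planted
    bigrams, and two negation pairs; paired with a hash backend of
    dimension 4x the token vocabulary (400) in the recovery tests.
    """
    pos = [vocab_word(r) for r in (3, 5, 7)]
    neg = [vocab_word(r) for r in (4, 6, 8)]
    effects = {w: 2.0 for w in pos}
    effects.update({w: -2.0 for w in neg})
    effects[f"{vocab_word(9)} {vocab_word(10)}"] = 2.0
    effects[f"{vocab_word(11)} {vocab_word(12)}"] = -2.0
    negation_pairs = (
        (vocab_word(2), pos[0], -2.0),
        (vocab_word(2), neg[0], 2.0),
    )
    return SyntheticSpec(
        vocab_size=100,
        n_docs=2000,
        doc_length_mean=20.0,
        doc_length_sd=4.0,
        effects=effects,
        negation_pairs=negation_pairs,
        noise_scale=1.0,
        seed=seed,
    )


def synonym_cluster_spec(seed: int = 0, n_members: int = 6) -> SyntheticSpec:
    """Synonym-cluster regime for expansion-augmented trees.

    Two clusters of ``n_members`` unigrams with strong opposite effects;
    one member is sampled per mention, so with a 70/30 split several
    members of each cluster appear only in test documents.
    """
    pos_members = tuple(f"pos{i}" for i in range(n_members))
    neg_members = tuple(f"neg{i}" for i in range(n_members))
    return SyntheticSpec(
        vocab_size=200,
        n_docs=400,
        doc_length_mean=15.0,
        doc_length_sd=3.0,
        synonym_clusters=((pos_members, 3.0), (neg_members, -3.0)),
        cluster_mention_prob=0.5,
        noise_scale=0.25,
        seed=seed,
    )
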