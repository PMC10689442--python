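# augimodels

Augmented interpretable models for text: transparent prediction models
that may consult a large language model while they are *fitted*, but
never at inference time. The result is a model you can inspect
completely — a lookup table of coefficients, or a small tree of
keyphrase tests — that still benefits from the world knowledge of a
modern language model. The package targets practitioners who need
interpretable text classifiers or regression models (e.g. for auditing,
deployment on constrained hardware, or scientific analysis of language
stimuli such as fMRI encoding studies).

## Models

**Augmented linear model.** A GLM over the sum of *decoupled* ngram
embeddings. For a document with ngrams x₁, …, extracted by a word-level
tokenizer:

    g(E[y]) = β + wᵀ Σᵢ φ(xᵢ)

where φ embeds each ngram *in isolation* (one-hot over a vocabulary,
seeded hash vectors, mean word vectors in GloVe format, or mean-pooled
transformer hidden states) and g is logit/softmax for classification,
identity for regression. Fitting minimizes cross-entropy or squared
error with an ℓ2 penalty on w by L-BFGS; the penalty (and optionally
the ngram orders) is chosen by cross-validation. Because the model is
additive over ngrams, it converts *exactly* to a coefficient dictionary
βᵢ = wᵀφ(xᵢ): prediction is then a dictionary lookup and a sum, and
coefficients for ngrams never seen in training can be inferred by
embedding them with the same φ. With the one-hot φ the model reduces
exactly to a classical ℓ2 bag-of-ngrams GLM.

**Augmented tree.** A CART-style tree whose split criterion is the
usual impurity decrease

    Δ̂(s, t, y) = Σ_{i∈t} h(yᵢ, ȳ_t) − Σ_{i∈t_L} h(yᵢ, ȳ_{t_L}) − Σ_{i∈t_R} h(yᵢ, ȳ_{t_R})

(Gini-based for classification, squared error for regression), but
whose splits are *disjunctions* of ngrams: after the best single ngram
is found, an expansion backend proposes similar keyphrases (a
generative-model prompt, embedding nearest neighbours, or a static
dictionary) and each candidate is greedily kept iff it does not
increase the split's impurity. Candidates absent from the training set
are kept — at test time a document containing *any* ngram of the
disjunction, including a synonym never seen in training, takes the
presence branch. Bagging ensembles average trees fit on same-size
bootstrap resamples.

Also included: a confidence-gated hybrid predictor (answer with the
transparent model when its top-class probability clears a threshold,
fall back to any black-box otherwise), coefficient-dictionary
compression by pruning the smallest coefficients, a synthetic-data
generator with planted recoverable structure, and a voxelwise encoding
module (lagged 20-word window skipping the 4 most recent words →
per-target ridge regression → test-correlation summaries).

## Worked example

```python
import numpy as np
from augimodels import (
    AugLinearConfig, LabeledCorpus, fit_aug_linear,
    to_coefficient_dictionary, build_vocabulary, make_hash_embedder,
)
from augimodels.synthetic import SyntheticSpec, generate_classification_corpus, vocab_word

# corpus with two planted unigram effects (+3 on w00003, -3 on w00004)
spec = SyntheticSpec(
    vocab_size=40, n_docs=400, doc_length_mean=8, doc_length_sd=2,
    effects={vocab_word(3): 3.0, vocab_word(4): -3.0},
    noise_scale=0.5, seed=0,
)
corpus, truth = generate_classification_corpus(spec)
train = LabeledCorpus(corpus.documents[:300], corpus.labels[:300])

backend = make_hash_embedder(dim=128, seed=0)
model = fit_aug_linear(train, backend,
                       AugLinearConfig(orders=(1, 2), reg_strengths=(0.1, 1.0, 10.0)))
print("selected l2 strength:", model.reg_strength)

vocab = build_vocabulary(train.documents, (1, 2))
dictionary = to_coefficient_dictionary(model, vocab, backend)
print("dictionary size:", len(dictionary))
for ngram, coef in dictionary.top_ngrams(3) + dictionary.bottom_ngrams(3):
    print(f"  {ngram:>14s}  {coef:+.3f}")
acc = np.mean(dictionary.predict(corpus.documents[300:]) == corpus.labels[300:])
print(f"test accuracy (dictionary only): {acc:.3f}")
```

Output:

```
selected l2 strength: 1.0
dictionary size: 597
          w00003  +2.847
  w00004 w00012  +1.678
  w00028 w00001  +1.303
          w00004  -2.958
  w00012 w00004  -1.525
  w00030 w00003  -1.485
test accuracy (dictionary only): 0.790
```

The two largest-magnitude coefficients are the planted effects, with
signs and rough magnitudes recovered; prediction at the end uses only
the exported dictionary — no embedding backend. A CLI mirrors the
library (`augimodels fit-linear / fit-tree / predict / interpret /
compress / expand / simulate / encode`).

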