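# Methods

This note documents the models implemented in `augimodels`, the
assumptions they make, the defaults and why, what the synthetic data
does and does not emulate, and the numerical choices that affect
reproducibility.

## Augmented linear model

The model is a generalized linear model on an additive text
representation. A document is tokenized by a deterministic word-level
regex tokenizer (words with internal apostrophes; punctuation marks as
their own tokens), every contiguous ngram whose order is in the
configured set is extracted with multiset semantics, each ngram is
embedded *in isolation* by a backend φ, and the embeddings are summed:

g(E[y]) = β + wᵀ Σᵢ φ(xᵢ).

Decoupling is the load-bearing assumption: because φ never sees the
document context, the link-scale score decomposes exactly into one
contribution wᵀφ(xᵢ) per ngram occurrence, so the fitted model *is* a
coefficient dictionary — there is no approximation in the conversion,
and the dictionary path and the embedding path agree to floating-point
precision. The price is that interactions are captured only insofar as
they occur inside a single ngram (the embedding of "not bad" is not the
sum of "not" and "bad").

Fitting and defaults:

- Loss: cross-entropy with the logit link (softmax, one weight vector
  per class, for more than two classes); squared error with the
  identity link for regression. ℓ2 penalty λ/2‖w‖² on the weights only.
- Optimizer: L-BFGS (scikit-learn's solver for classification, the
  closed-form Cholesky path for ridge regression), gradient tolerance
  1e-6, max 1000 iterations, fixed data order — runs are reproducible.
- λ grid: decadic, 1e-3…1e3 (7 points), selected by 3-fold seeded
  cross-validation on the training set; a single-element grid skips CV.
  Ngram-order candidates, when given, are selected jointly with λ in
  the same grid search (sequential selection is available by running
  two searches).
- Ngram orders default to {1, 2} (all orders up to the maximum, not
  exactly-k; an exact-k run is just `orders=(k,)`).
- Each occurrence of an ngram contributes once (multiset); this makes
  the one-hot limit equal to count features. Set-semantics and
  mean-instead-of-sum are flags.
- Documents are lowercased before extraction by default (the default
  backends are uncased); punctuation tokens are kept.

Embedding backends share one contract: a stable `backend_id`, a fixed
`dim`, and a deterministic `embed(text) -> vector`. The one-hot backend
reproduces bag-of-ngrams exactly (out-of-vocabulary → zero vector); the
hash backend draws a unit vector per string from a BLAKE2b-seeded RNG
(identical across processes; near-orthogonal at large dim) and is the
workhorse of the test corpus experiments; the word-vector backend
averages per-word vectors from a GloVe-format table, with missing words
contributing zero vectors so φ stays total; the transformer backend
runs the model's own preprocessing (e.g. [CLS] … [SEP]) and averages
the chosen layer's hidden states over token positions — special tokens
are included in the mean by default (a flag excludes them), and the
default layer is the final hidden layer. The embedding cache is keyed
by (backend_id, ngram) so reconfigured backends can never serve stale
vectors, and enabling it never changes a prediction.

Dictionary operations: compression drops the requested fraction of
entries with smallest |coefficient| (max over classes for multiclass),
ties at the cutoff broken lexicographically; unseen ngrams at
dictionary-only inference contribute 0 and accumulate a warning, with
on-the-fly embedding opt-in when a backend is attached. The hybrid
predictor routes a sample to the linear model iff its top-class
probability strictly exceeds the threshold, so thresholds 0 and 1
reproduce the pure linear model and the pure fallback exactly.

## Augmented tree

Node costs are the summed per-sample forms whose difference is the
impurity decrease: N·Gini for classification, the sum of squared
deviations from the node mean for regression. The seed split is found
by exhaustive search over binary document-level presence features
(candidates default to bigrams with corpus count ≥ 2 to bound the
search; features are scanned in lexicographic order and only a strictly
larger decrease replaces the incumbent, so ties resolve to the
lexicographically smallest ngram — the same rule the test oracles use).

Expansion candidates are screened greedily in the order proposed:
a candidate joins the disjunction iff the split's total child impurity
does not increase (weak inequality, tolerance 1e-12). The weak
inequality is deliberate: a candidate absent from every training
document changes nothing and is *kept*, which is precisely the
mechanism by which the tree generalizes to out-of-vocabulary synonyms.
A candidate that would absorb the entire absence branch is rejected as
degenerate. The seed is never re-chosen after augmentation, only
extended, and the disjunction is capped at 100 accepted candidates.
Nodes may re-expand ngrams already expanded at ancestors; the expansion
cache makes this free.

Expansion backends: the generative backend builds the prompt
"Generate 100 concise phrases that are very similar to the keyphrase…"
around the seed ngram, parses the numbered-list completion (strip
numbering/quotes/trailing punctuation, lowercase, deduplicate
preserving order), and caches responses as JSON keyed by ngram; the
completion call itself is an injected callable, so fits are replayable
offline from the cache. The embedding-neighbour backend ranks
vocabulary ngrams by cosine similarity under any embedding backend;
the static-dictionary backend maps ngrams to fixed synonym lists and is
the deterministic mock used in tests.

Defaults: max depth 3 for single interpretable trees, 8 for ensemble
members; min_samples_leaf 1; recursion also stops at pure nodes and
when no split achieves a positive decrease. Bagging fits each member on
a same-size bootstrap resample seeded from master_seed + index and
averages predicted probabilities (or values); 10 members is the quick
default, 40 matches the interpretation-scale ensembles.

## Synthetic data

The classification generator draws iid Zipfian background tokens
(default exponent 1.1 over 5000 types, 2000 documents of length
~N(25, 5²)) and plants three kinds of structure, all exported in a
`GroundTruth`: signed additive ngram effects (inserted with probability
0.3 per document, also counted when they occur by chance); negation
pairs, where a modifier immediately preceding its target replaces the
target's effect with a flipped value — representable by bigram features
but invisible to unigrams; and synonym clusters sharing one effect,
with one member sampled uniformly per mention so that, at realistic
sizes, some members occur only in held-out documents. The label is
Bernoulli(logistic(score/noise)). At the default corpus scale the
trigram vocabulary is ~95% singletons, reproducing the rare-ngram
regime that motivates fixed-dimension embeddings over per-ngram
coefficients.

Two canonical regimes are frozen as named specs. The recovery regime
(vocab 100, n = 2000, six ±2 unigram effects, two ±2 bigram effects,
two negation pairs, noise 1) pairs with a hash backend of dimension
4× the token vocabulary; the recovery claim is that the *sign* of every
planted effect's dictionary entry matches the plant. The synonym
regime (two 6-member clusters with effects ±3, mention probability
0.5, noise 0.25, n = 400, 70/30 split) is the condition under which
expansion-augmented trees should beat plain CART out of sample.

The regression stream draws a Zipfian word sequence (4 words per
timepoint), plants Gaussian weights on the 10 most frequent words, and
emits response(t) = weighted count of planted words in the lagged
window + N(0, noise²), with the window geometry recorded in the ground
truth.

What the generator does *not* emulate: syntax, topicality, burstiness,
document-level dependence, polysemy, or any real corpus's content.
Passing the recovery tests therefore shows that the estimators recover
the structure they model under their own assumptions at desk scale —
not that they attain any particular accuracy on natural language.

## Encoding models

For a timepoint whose word offset is m (words observed so far), the
feature window is words max(1, m−delay−window+1)…m−delay (1-based,
inclusive), defaults window = 20, delay = 4 — the delay approximates
the lag of a haemodynamic response; fewer available words truncate the
window and an empty window featurizes to the zero vector. Features
depend only on words at index ≤ m−delay, which the tests verify by
perturbing excluded words.

Ridge is solved in closed form per target through one SVD of the
centered design shared across all targets and penalties (per CV fold),
so cost is dominated by a single decomposition rather than the voxel
count. The penalty is chosen per target from a decadic grid
(0.01…1000) by 5-fold seeded CV on mean squared error, smaller penalty
winning ties; a zero penalty on a rank-deficient design raises an error
directing λ > 0. The fitted weights satisfy the ridge normal equations
to better than 1e-8 relative residual.

Scoring reports per-target Pearson r on the test partition
(zero-variance targets score 0 and are flagged) plus the mean over all
targets and over the top 1%/5% of targets *ranked by test correlation*.
Ranking on the test set mirrors the summary convention of the encoding
literature but is selection-biased as an absolute performance estimate;
rank on a held-out split of the training data when an unbiased summary
is needed. Word-to-scan-time alignment (TR interpolation) is out of
scope: inputs arrive as an already aligned (stream, offsets) pair.

## Problem sizes and runtime

The test suite and the acceptance script run everything at desk scale,
chosen so each claim is measured with adequate statistical power:
20 replicate corpora (n = 120–500) for the oracle equivalences, 20
seeds for sign recovery and the tree-vs-CART comparison, 10 seeds for
the ensemble comparison, 5000 training timepoints for ridge recovery,
and a single full-scale (5000-type, 2000-document) corpus for the
singleton-trigram statistic. The whole suite completes in about a
minute on one CPU, as does the acceptance script.

## Known limitations

- The linear model captures only within-ngram interactions; long-range
  dependence needs the tree's disjunctions or larger ngram orders.
- Greedy screening is order-dependent: an early mediocre candidate can
  block a later better one at the same node.
- Hash embeddings carry no semantics — inferred coefficients for unseen
  ngrams are only meaningful under a semantic backend (word vectors or
  a transformer).
- Calibration of the hybrid router is inherited from the linear model;
  it is not recalibrated.
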