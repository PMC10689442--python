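"""Augmented linear models over summed, decoupled ngram embeddings.

The model is an ordinary GLM whose feature vector for a document is the
sum of the embeddings of every ngram it contains:

    g(E[y]) = beta + w^T sum_i phi(x_i)

Because each ngram is embedded in isolation (decoupled from its
context), the link-scale score decomposes exactly into one additive
contribution ``w^T phi(x_i)`` per ngram. After fitting, the model is
therefore convertible to a plain coefficient dictionary
``ngram -> w^T phi(ngram)`` that reproduces its predictions without the
embedding backend, and coefficients for ngrams never seen in training
can be inferred by embedding them and taking the same dot product.

Fitting minimizes cross-entropy (logit/softmax link) or squared error
(identity link) with an l2 penalty on ``w`` via L-BFGS, with the penalty
strength — and optionally the set of ngram orders — chosen by
cross-validation on the training set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit, softmax
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold

from .embeddings import EmbeddingBackend, EmbeddingCache, embed_ngram
from .text import (
    LabeledCorpus,
    Ngram,
    NgramVocabulary,
    TokenizerConfig,
    extract_ngrams,
    tokenize,
)

__all__ = [
    "AugLinearConfig",
    "AugLinearModel",
    "CoefficientDictionary",
    "HybridResult",
    "featurize_document",
    "featurize_corpus",
    "fit_aug_linear",
    "predict",
    "to_coefficient_dictionary",
    "infer_coefficient",
    "compress",
    "hybrid_predict",
]

DEFAULT_REG_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 4))


@dataclass(frozen=True)
class AugLinearConfig:
    """Hyperparameters for fitting an augmented linear model.

    ``reg_strengths`` is the l2 penalty grid (the objective is
    ``sum loss + lambda/2 * ||w||^2``); a single-element grid skips
    cross-validation. ``order_candidates`` optionally lists alternative
    ngram-order sets to select jointly with the penalty.
    """

    task: str = "classification"  # or "regression"
    orders: tuple[int, ...] = (1, 2)
    order_candidates: tuple[tuple[int, ...], ...] | None = None
    reg_strengths: tuple[float, ...] = DEFAULT_REG_GRID
    cv_folds: int = 3
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    dedupe_ngrams: bool = False  # set semantics instead of multiset
    average_embeddings: bool = False  # mean instead of sum over ngrams
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.task not in {"classification", "regression"}:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.reg_strengths:
            raise ValueError("reg_strengths must be non-empty")


def featurize_document(
    doc: str,
    backend: EmbeddingBackend,
    orders: Iterable[int],
    tokenizer: TokenizerConfig | None = None,
    cache: EmbeddingCache | None = None,
    dedupe: bool = False,
    average: bool = False,
) -> np.ndarray:
    """Sum (default) or average of phi over the document's ngram multiset.

    An empty document yields the zero vector. With ``dedupe`` each
    distinct ngram contributes once regardless of repetition.
    """
    ngrams = extract_ngrams(tokenize(doc, tokenizer), orders)
    if dedupe:
        seen: dict[str, Ngram] = {}
        for g in ngrams:
            seen.setdefault(g.text, g)
        ngrams = list(seen.values())
    acc = np.zeros(backend.dim)
    for g in ngrams:
        acc += embed_ngram(backend, g, cache)
    if average and ngrams:
        acc /= len(ngrams)
    return acc


def featurize_corpus(
    docs: Sequence[str],
    backend: EmbeddingBackend,
    orders: Iterable[int],
    tokenizer: TokenizerConfig | None = None,
    cache: EmbeddingCache | None = None,
    dedupe: bool = False,
    average: bool = False,
) -> np.ndarray:
    """Stack `featurize_document` over a corpus into an (n, dim) matrix."""
    orders = tuple(sorted(set(orders)))
    local = cache if cache is not None else EmbeddingCache()
    X = np.empty((len(docs), backend.dim))
    for i, doc in enumerate(docs):
        X[i] = featurize_document(
            doc, backend, orders, tokenizer, local, dedupe=dedupe, average=average
        )
    return X


@dataclass
class AugLinearModel:
    """A fitted GLM over summed ngram embeddings.

    ``coef`` has one row per weight vector (a single row for binary
    classification and regression, one per class for multiclass) and
    ``intercept`` one entry per row. ``link`` is ``logit``, ``softmax``
    or ``identity``.
    """

    task: str
    link: str
    classes: np.ndarray | None
    intercept: np.ndarray
    coef: np.ndarray
    backend_id: str
    orders: tuple[int, ...]
    tokenizer: TokenizerConfig
    reg_strength: float
    dedupe_ngrams: bool = False
    average_embeddings: bool = False
    cv_results: list[dict] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.coef.shape[1]

    def model_hash(self) -> str:
        h = hashlib.blake2b(digest_size=8)
        h.update(self.coef.tobytes())
        h.update(self.intercept.tobytes())
        return h.hexdigest()

    # --- link-scale scores and responses from a feature matrix ---------

    def scores_from_features(self, X: np.ndarray) -> np.ndarray:
        """Link-scale scores, shape (n, n_weight_vectors)."""
        return np.asarray(X) @ self.coef.T + self.intercept

    def proba_from_scores(self, scores: np.ndarray) -> np.ndarray:
        if self.link == "logit":
            p1 = expit(scores[:, 0])
            return np.column_stack([1.0 - p1, p1])
        if self.link == "softmax":
            return softmax(scores, axis=1)
        raise ValueError("probabilities are undefined for the identity link")

    def predict_proba_from_features(self, X: np.ndarray) -> np.ndarray:
        return self.proba_from_scores(self.scores_from_features(X))

    def predict_from_features(self, X: np.ndarray) -> np.ndarray:
        scores = self.scores_from_features(X)
        if self.task == "regression":
            return scores[:, 0]
        proba = self.proba_from_scores(scores)
        return self.classes[np.argmax(proba, axis=1)]


def _feature_settings(model_or_config) -> dict:
    return {
        "orders": model_or_config.orders,
        "tokenizer": model_or_config.tokenizer,
        "dedupe": getattr(model_or_config, "dedupe_ngrams", False),
        "average": getattr(model_or_config, "average_embeddings", False),
    }


def _fit_glm(X: np.ndarray, y: np.ndarray, config: AugLinearConfig, reg: float):
    if config.task == "classification":
        est = LogisticRegression(
            C=1.0 / reg,
            solver="lbfgs",
            tol=config.tol,
            max_iter=config.max_iter,
        )
    else:
        est = Ridge(alpha=reg, solver="cholesky")
    est.fit(X, y)
    return est


def _cv_score(X, y, config: AugLinearConfig, reg: float) -> float:
    if config.task == "classification":
        splitter = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
    else:
        splitter = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    scores = []
    for train_idx, val_idx in splitter.split(X, y):
        est = _fit_glm(X[train_idx], y[train_idx], config, reg)
        if config.task == "classification":
            scores.append(np.mean(est.predict(X[val_idx]) == y[val_idx]))
        else:
            resid = est.predict(X[val_idx]) - y[val_idx]
            scores.append(-float(np.mean(resid**2)))
    return float(np.mean(scores))


def fit_aug_linear(
    corpus: LabeledCorpus,
    backend: EmbeddingBackend,
    config: AugLinearConfig | None = None,
    cache: EmbeddingCache | None = None,
) -> AugLinearModel:
    """Fit the augmented GLM, selecting l2 strength (and ngram orders) by CV.

    Deterministic given (corpus order, backend, config): the solver is
    L-BFGS with fixed tolerances and the CV splitter is seeded from
    ``config.seed``.
    """
    if config is None:
        config = AugLinearConfig()
    y = np.asarray(corpus.labels)
    if config.task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification needs at least 2 distinct labels")

    candidates = config.order_candidates or (config.orders,)
    candidates = tuple(tuple(sorted(set(c))) for c in candidates)
    cache = cache if cache is not None else EmbeddingCache()

    feature_matrices: dict[tuple[int, ...], np.ndarray] = {}
    for orders in candidates:
        X = featurize_corpus(
            corpus.documents,
            backend,
            orders,
            config.tokenizer,
            cache,
            dedupe=config.dedupe_ngrams,
            average=config.average_embeddings,
        )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite document features; check the backend")
        feature_matrices[orders] = X

    cv_results: list[dict] = []
    if len(candidates) == 1 and len(config.reg_strengths) == 1:
        best_orders, best_reg = candidates[0], config.reg_strengths[0]
    else:
        if corpus.n < config.cv_folds:
            raise ValueError("need n >= cv_folds samples for cross-validation")
        best = None
        for orders in candidates:
            for reg in config.reg_strengths:
                score = _cv_score(feature_matrices[orders], y, config, reg)
                cv_results.append({"orders": orders, "reg_strength": reg, "score": score})
                # strict > keeps the first (smallest-orders, largest-C first
                # in grid order) maximizer: deterministic tie-break
                if best is None or score > best[0]:
                    best = (score, orders, reg)
        _, best_orders, best_reg = best

    X = feature_matrices[best_orders]
    est = _fit_glm(X, y, config, best_reg)

    if config.task == "classification":
        link = "logit" if len(est.classes_) == 2 else "softmax"
        coef = np.asarray(est.coef_, dtype=float)
        intercept = np.asarray(est.intercept_, dtype=float)
        classes = np.asarray(est.classes_)
        if link == "softmax" and coef.shape[0] != len(classes):  # pragma: no cover
            raise RuntimeError("unexpected multinomial coefficient shape")
    else:
        link = "identity"
        coef = np.asarray(est.coef_, dtype=float).reshape(1, -1)
        intercept = np.atleast_1d(np.asarray(est.intercept_, dtype=float))
        classes = None

    return AugLinearModel(
        task=config.task,
        link=link,
        classes=classes,
        intercept=intercept,
        coef=coef,
        backend_id=backend.backend_id,
        orders=best_orders,
        tokenizer=config.tokenizer,
        reg_strength=float(best_reg),
        dedupe_ngrams=config.dedupe_ngrams,
        average_embeddings=config.average_embeddings,
        cv_results=cv_results,
    )


def predict(
    model: AugLinearModel,
    docs: Sequence[str],
    backend: EmbeddingBackend | None = None,
    dictionary: "CoefficientDictionary | None" = None,
    cache: EmbeddingCache | None = None,
    return_proba: bool | None = None,
) -> np.ndarray:
    """Predict through the embedding path (``backend``) or the dictionary path.

    Both paths compute the same link-scale score — ``w`` dotted with the
    summed embeddings, versus the sum of per-ngram dictionary entries —
    so they agree to numerical precision on training-vocabulary text.
    """
    if (backend is None) == (dictionary is None):
        raise ValueError("provide exactly one of backend or dictionary")
    if dictionary is not None:
        scores = dictionary.scores(docs)
    else:
        X = featurize_corpus(
            docs,
            backend,
            model.orders,
            model.tokenizer,
            cache,
            dedupe=model.dedupe_ngrams,
            average=model.average_embeddings,
        )
        scores = model.scores_from_features(X)
    if model.task == "regression":
        return scores[:, 0]
    proba = model.proba_from_scores(scores)
    if return_proba or return_proba is None:
        return proba
    return model.classes[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# coefficient dictionary


@dataclass
class CoefficientDictionary:
    """The transparent, backend-free form of a fitted augmented GLM.

    ``entries[ngram]`` is ``w^T phi(ngram)`` — a length-1 array for
    binary/regression models, one value per class for multiclass.
    Prediction looks up each ngram of a document, sums the entries with
    the intercept and applies the inverse link; ngrams absent from the
    dictionary contribute zero (or are embedded on the fly when a
    backend is attached).
    """

    entries: dict[str, np.ndarray]
    intercept: np.ndarray
    link: str
    classes: list | None
    orders: tuple[int, ...]
    tokenizer: TokenizerConfig
    counts: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    dedupe_ngrams: bool = False
    average_embeddings: bool = False
    backend: EmbeddingBackend | None = None  # opt-in on-the-fly inference

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_outputs(self) -> int:
        return len(self.intercept)

    def contributions(self, doc: str) -> list[tuple[str, np.ndarray]]:
        """Per-ngram additive contributions to the link-scale score."""
        ngrams = extract_ngrams(tokenize(doc, self.tokenizer), self.orders)
        if self.dedupe_ngrams:
            seen: dict[str, Ngram] = {}
            for g in ngrams:
                seen.setdefault(g.text, g)
            ngrams = list(seen.values())
        rows: list[tuple[str, np.ndarray]] = []
        unseen: list[str] = []
        for g in ngrams:
            entry = self.entries.get(g.text)
            if entry is None:
                if self.backend is not None:
                    entry = self.backend.embed(g.text) @ self._weights_for_backend()
                else:
                    unseen.append(g.text)
                    entry = np.zeros(self.n_outputs)
            rows.append((g.text, np.atleast_1d(np.asarray(entry, dtype=float))))
        if unseen:
            warnings.warn(
                f"{len(unseen)} ngram(s) not in the coefficient dictionary "
                f"contributed 0 (e.g. {unseen[0]!r})",
                stacklevel=2,
            )
        if self.average_embeddings and rows:
            rows = [(t, v / len(rows)) for t, v in rows]
        return rows

    def _weights_for_backend(self) -> np.ndarray:
        w = self.provenance.get("_coef")
        if w is None:
            raise ValueError("on-the-fly inference needs the fitted weights attached")
        return np.asarray(w).T

    def score_document(self, doc: str) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = self.contributions(doc)
        total = self.intercept.astype(float).copy()
        for _, v in rows:
            total = total + v
        return total

    def scores(self, docs: Sequence[str]) -> np.ndarray:
        return np.vstack([self.score_document(d) for d in docs])

    def predict_proba(self, docs: Sequence[str]) -> np.ndarray:
        scores = self.scores(docs)
        if self.link == "logit":
            p1 = expit(scores[:, 0])
            return np.column_stack([1.0 - p1, p1])
        if self.link == "softmax":
            return softmax(scores, axis=1)
        raise ValueError("probabilities are undefined for the identity link")

    def predict(self, docs: Sequence[str]) -> np.ndarray:
        if self.link == "identity":
            return self.scores(docs)[:, 0]
        proba = self.predict_proba(docs)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    def top_ngrams(self, k: int, output: int = -1) -> list[tuple[str, float]]:
        """The ``k`` largest (signed) coefficients for one output column.

        ``output=-1`` uses the last column (the positive class for
        binary models, the response for regression).
        """
        items = [(t, float(v[output] if v.ndim else v)) for t, v in self.entries.items()]
        items.sort(key=lambda kv: (-kv[1], kv[0]))
        return items[:k]

    def bottom_ngrams(self, k: int, output: int = -1) -> list[tuple[str, float]]:
        items = [(t, float(v[output] if v.ndim else v)) for t, v in self.entries.items()]
        items.sort(key=lambda kv: (kv[1], kv[0]))
        return items[:k]

    # --- serialization -------------------------------------------------

    def to_tsv(self, path: str | Path) -> Path:
        """Write entries as TSV: ngram, count, one coefficient per output."""
        path = Path(path)
        headers = ["ngram", "count"] + [f"coef_{i}" for i in range(self.n_outputs)]
        with path.open("w") as fh:
            fh.write("\t".join(headers) + "\n")
            for text in sorted(self.entries):
                v = np.atleast_1d(self.entries[text])
                row = [text, str(self.counts.get(text, 0))] + [repr(float(c)) for c in v]
                fh.write("\t".join(row) + "\n")
        return path

    def to_json(self) -> dict:
        return {
            "entries": {t: [float(c) for c in np.atleast_1d(v)] for t, v in self.entries.items()},
            "counts": self.counts,
            "intercept": [float(c) for c in self.intercept],
            "link": self.link,
            "classes": None if self.classes is None else [_plain(c) for c in self.classes],
            "orders": list(self.orders),
            "tokenizer": {
                "lowercase": self.tokenizer.lowercase,
                "keep_punctuation": self.tokenizer.keep_punctuation,
                "tokenizer_id": self.tokenizer.tokenizer_id,
            },
            "dedupe_ngrams": self.dedupe_ngrams,
            "average_embeddings": self.average_embeddings,
            "provenance": {k: v for k, v in self.provenance.items() if not k.startswith("_")},
        }

    @classmethod
    def from_json(cls, payload: dict) -> "CoefficientDictionary":
        return cls(
            entries={t: np.asarray(v, dtype=float) for t, v in payload["entries"].items()},
            counts={t: int(c) for t, c in payload.get("counts", {}).items()},
            intercept=np.asarray(payload["intercept"], dtype=float),
            link=payload["link"],
            classes=payload["classes"],
            orders=tuple(payload["orders"]),
            tokenizer=TokenizerConfig(**payload["tokenizer"]),
            dedupe_ngrams=payload.get("dedupe_ngrams", False),
            average_embeddings=payload.get("average_embeddings", False),
            provenance=payload.get("provenance", {}),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CoefficientDictionary":
        return cls.from_json(json.loads(Path(path).read_text()))


def _plain(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def infer_coefficient(
    model: AugLinearModel,
    ngram: Ngram | str,
    backend: EmbeddingBackend,
    cache: EmbeddingCache | None = None,
) -> np.ndarray:
    """``w^T phi(ngram)`` — works for ngrams never seen in training.

    With a compositional backend this is generally *not* the sum of the
    constituent ngrams' coefficients; the embedding of the full phrase
    carries the interaction.
    """
    phi = embed_ngram(backend, ngram, cache)
    return model.coef @ phi


def to_coefficient_dictionary(
    model: AugLinearModel,
    vocab: NgramVocabulary,
    backend: EmbeddingBackend,
    cache: EmbeddingCache | None = None,
    attach_backend: bool = False,
) -> CoefficientDictionary:
    """Export the fitted model as one coefficient per vocabulary ngram."""
    if backend.backend_id != model.backend_id:
        raise ValueError(
            f"model was fitted with backend {model.backend_id!r}, got {backend.backend_id!r}"
        )
    entries = {
        g.text: infer_coefficient(model, g, backend, cache) for g in vocab.ngrams
    }
    provenance = {
        "backend_id": model.backend_id,
        "model_hash": model.model_hash(),
        "reg_strength": model.reg_strength,
    }
    if attach_backend:
        provenance["_coef"] = model.coef
    return CoefficientDictionary(
        entries=entries,
        counts=dict(vocab.counts),
        intercept=model.intercept.astype(float),
        link=model.link,
        classes=None if model.classes is None else list(model.classes),
        orders=model.orders,
        tokenizer=model.tokenizer,
        dedupe_ngrams=model.dedupe_ngrams,
        average_embeddings=model.average_embeddings,
        provenance=provenance,
        backend=backend if attach_backend else None,
    )


def compress(
    dictionary: CoefficientDictionary, drop_fraction: float
) -> CoefficientDictionary:
    """Drop the ``drop_fraction`` of entries with smallest absolute coefficient.

    Multiclass entries are ranked by their maximum absolute value over
    classes. Ties at the cutoff are broken by lexicographic ngram order
    (smaller sorts first, hence is dropped first). The intercept is kept.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    ranked = sorted(
        dictionary.entries,
        key=lambda t: (float(np.max(np.abs(dictionary.entries[t]))), t),
    )
    n_drop = int(np.floor(drop_fraction * len(ranked)))
    kept = set(ranked[n_drop:])
    return replace(
        dictionary,
        entries={t: v for t, v in dictionary.entries.items() if t in kept},
        counts={t: c for t, c in dictionary.counts.items() if t in kept},
    )


# ---------------------------------------------------------------------------
# confidence-gated hybrid prediction


@dataclass
class HybridResult:
    """Predictions of the two-step transparent-first procedure."""

    predictions: np.ndarray
    routed_to_linear: np.ndarray  # boolean mask
    linear_fraction: float


def hybrid_predict(
    model: AugLinearModel,
    fallback,
    threshold: float,
    docs: Sequence[str],
    backend: EmbeddingBackend | None = None,
    dictionary: CoefficientDictionary | None = None,
    cache: EmbeddingCache | None = None,
) -> HybridResult:
    """Two-step prediction: transparent model when confident, fallback otherwise.

    A sample is answered by the augmented linear model iff its top-class
    predicted probability exceeds ``threshold``; the rest go to
    ``fallback`` (anything exposing ``predict(list_of_texts)``, or a
    callable). At threshold 0 everything is routed to the linear model;
    at threshold 1 nothing is (probabilities never exceed 1).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if model.task != "classification":
        raise ValueError("hybrid prediction is defined for classification")
    proba = predict(model, docs, backend=backend, dictionary=dictionary, cache=cache)
    confident = np.max(proba, axis=1) > threshold
    predictions = np.asarray(model.classes)[np.argmax(proba, axis=1)].astype(object)
    fallback_idx = np.flatnonzero(~confident)
    if fallback_idx.size:
        fallback_docs = [docs[i] for i in fallback_idx]
        predict_fn: Callable = fallback.predict if hasattr(fallback, "predict") else fallback
        try:
            fallback_preds = np.asarray(predict_fn(fallback_docs))
        except Exception as exc:
            raise RuntimeError(
                f"fallback predictor failed on sample index {int(fallback_idx[0])}: {exc}"
            ) from exc
        predictions[fallback_idx] = fallback_preds
    return HybridResult(
        predictions=predictions,
        routed_to_linear=confident,
        linear_fraction=float(np.mean(confident)),
    )
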