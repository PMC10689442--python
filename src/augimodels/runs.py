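"""Run configuration, logging and model-bundle persistence.

A ``RunConfig`` fully determines a fit: task, tokenizer, ngram orders,
embedding-backend spec, model family and hyperparameters, CV settings
and seed. ``run_fit`` executes it and writes a bundle directory —
model JSON, coefficient-dictionary TSV (or tree JSON + rendering),
backend manifest, a copy of the config, metrics and a log recording the
backend id, seed and config hash — so a persisted config plus the same
cache state reproduces the artifact byte-for-byte. ``run_interpret``
reads a bundle back and reports global top/bottom coefficients or a
per-document contribution table whose rows (plus intercept) sum to the
link-scale score.

Every function here is a thin shell over the library modules; no
modeling logic lives only in this layer.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import linear, synthetic, tree
from .embeddings import (
    BackendError,
    EmbeddingBackend,
    make_hash_embedder,
    make_onehot_embedder,
    make_transformer_backend,
    load_word_vector_backend,
)
from .text import LabeledCorpus, TokenizerConfig, build_vocabulary, read_corpus, write_corpus

__all__ = ["RunConfig", "run_fit", "run_interpret", "run_predict", "load_bundle"]

logger = logging.getLogger("augimodels")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one fitting run."""

    task: str = "classification"
    model: str = "aug_linear"  # or "aug_tree"
    orders: tuple[int, ...] = (1, 2)
    backend: dict = field(default_factory=lambda: {"kind": "hash", "dim": 256, "seed": 0})
    lowercase: bool = True
    keep_punctuation: bool = True
    reg_strengths: tuple[float, ...] = linear.DEFAULT_REG_GRID
    cv_folds: int = 3
    min_count: int = 1
    max_depth: int = 3
    n_estimators: int = 1
    seed: int = 0

    def tokenizer(self) -> TokenizerConfig:
        return TokenizerConfig(lowercase=self.lowercase, keep_punctuation=self.keep_punctuation)

    def to_json(self) -> dict:
        payload = asdict(self)
        payload["orders"] = list(self.orders)
        payload["reg_strengths"] = list(self.reg_strengths)
        return payload

    @classmethod
    def from_json(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"invalid config fields: {sorted(unknown)}")
        if "orders" in payload:
            payload["orders"] = tuple(payload["orders"])
        if "reg_strengths" in payload:
            payload["reg_strengths"] = tuple(payload["reg_strengths"])
        return cls(**payload)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_json(), sort_keys=True)
        return hashlib.blake2b(canonical.encode(), digest_size=8).hexdigest()


def _build_backend(config: RunConfig, corpus: LabeledCorpus) -> EmbeddingBackend:
    spec = dict(config.backend)
    kind = spec.pop("kind", "hash")
    if kind == "hash":
        return make_hash_embedder(dim=spec.get("dim", 256), seed=spec.get("seed", 0))
    if kind == "onehot":
        vocab = build_vocabulary(
            corpus, config.orders, min_count=config.min_count, tokenizer=config.tokenizer()
        )
        return make_onehot_embedder(vocab)
    if kind == "word_vectors":
        return load_word_vector_backend(spec["path"])
    if kind == "transformer":
        return make_transformer_backend(
            spec["checkpoint"],
            layer=spec.get("layer", -1),
            include_special_tokens=spec.get("include_special_tokens", True),
        )
    raise BackendError(f"unknown backend kind {kind!r}")


def _setup_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_fit(
    config: RunConfig,
    corpus_path: str | Path,
    out_dir: str | Path,
    test_path: str | Path | None = None,
) -> Path:
    """Fit the configured model on a corpus file and persist a bundle directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out_dir)
    try:
        corpus = read_corpus(corpus_path)
        backend = _build_backend(config, corpus)
        logger.info(
            "fit model=%s backend=%s seed=%d config_hash=%s n=%d",
            config.model, backend.backend_id, config.seed, config.config_hash(), corpus.n,
        )
        metrics: dict = {"n_train": corpus.n}
        if config.model == "aug_linear":
            lin_config = linear.AugLinearConfig(
                task=config.task,
                orders=config.orders,
                reg_strengths=config.reg_strengths,
                cv_folds=config.cv_folds,
                tokenizer=config.tokenizer(),
                seed=config.seed,
            )
            model = linear.fit_aug_linear(corpus, backend, lin_config)
            vocab = build_vocabulary(
                corpus, model.orders, min_count=config.min_count, tokenizer=config.tokenizer()
            )
            dictionary = linear.to_coefficient_dictionary(model, vocab, backend)
            dictionary.to_tsv(out_dir / "dictionary.tsv")
            dictionary.save(out_dir / "dictionary.json")
            (out_dir / "model.json").write_text(json.dumps(_linear_model_json(model), indent=1))
            metrics["cv_results"] = [
                {"orders": list(r["orders"]), "reg_strength": r["reg_strength"], "score": r["score"]}
                for r in model.cv_results
            ]
            metrics["reg_strength"] = model.reg_strength
            metrics["vocab_size"] = vocab.p
            if config.task == "classification":
                preds = linear.predict(model, corpus.documents, backend=backend, return_proba=False)
                metrics["train_accuracy"] = float(np.mean(preds == corpus.labels))
            if model.cv_results:
                metrics["cv_score"] = max(r["score"] for r in model.cv_results)
            if test_path is not None:
                test = read_corpus(test_path)
                preds = linear.predict(model, test.documents, backend=backend, return_proba=False)
                if config.task == "classification":
                    metrics["test_accuracy"] = float(np.mean(preds == test.labels))
                else:
                    metrics["test_mse"] = float(np.mean((preds - test.labels) ** 2))
        elif config.model == "aug_tree":
            tree_config = tree.AugTreeConfig(
                task=config.task,
                feature_orders=config.orders,
                min_count=max(config.min_count, 2),
                max_depth=config.max_depth,
                tokenizer=config.tokenizer(),
            )
            if config.n_estimators > 1:
                ensemble = tree.fit_bagging_ensemble(
                    corpus.documents, corpus.labels,
                    n_estimators=config.n_estimators, config=tree_config,
                    master_seed=config.seed,
                )
                payload = {
                    "kind": "bagging_ensemble",
                    "seeds": ensemble.seeds,
                    "estimators": [tree.tree_to_json(t) for t in ensemble.estimators],
                }
                fitted = ensemble
            else:
                single = tree.fit_aug_tree(corpus.documents, corpus.labels, config=tree_config)
                payload = {"kind": "tree", "tree": tree.tree_to_json(single)}
                (out_dir / "tree.txt").write_text(tree.render_tree(single) + "\n")
                fitted = single
            (out_dir / "model.json").write_text(json.dumps(payload, indent=1))
            preds = fitted.predict(corpus.documents)
            if config.task == "classification":
                metrics["train_accuracy"] = float(np.mean(preds == corpus.labels))
            if test_path is not None:
                test = read_corpus(test_path)
                preds = fitted.predict(test.documents)
                if config.task == "classification":
                    metrics["test_accuracy"] = float(np.mean(preds == test.labels))
                else:
                    metrics["test_mse"] = float(np.mean((preds - test.labels) ** 2))
        else:
            raise ValueError(f"unknown model family {config.model!r}")

        (out_dir / "config.json").write_text(json.dumps(config.to_json(), indent=1))
        (out_dir / "backend_manifest.json").write_text(
            json.dumps({"backend_id": backend.backend_id, "dim": backend.dim}, indent=1)
        )
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
        logger.info("bundle written to %s", out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir


def _linear_model_json(model: linear.AugLinearModel) -> dict:
    return {
        "task": model.task,
        "link": model.link,
        "classes": None if model.classes is None else [linear._plain(c) for c in model.classes],
        "intercept": [float(v) for v in model.intercept],
        "coef": [[float(v) for v in row] for row in model.coef],
        "backend_id": model.backend_id,
        "orders": list(model.orders),
        "reg_strength": model.reg_strength,
        "tokenizer": {
            "lowercase": model.tokenizer.lowercase,
            "keep_punctuation": model.tokenizer.keep_punctuation,
            "tokenizer_id": model.tokenizer.tokenizer_id,
        },
    }


@dataclass
class Bundle:
    """A fitted artifact read back from disk."""

    config: RunConfig
    dictionary: linear.CoefficientDictionary | None = None
    tree_model: "tree.AugTree | None" = None
    ensemble: "tree.BaggingEnsemble | None" = None

    def predict(self, docs):
        if self.dictionary is not None:
            return self.dictionary.predict(docs)
        fitted = self.tree_model if self.tree_model is not None else self.ensemble
        return fitted.predict(docs)


def load_bundle(bundle_dir: str | Path) -> Bundle:
    bundle_dir = Path(bundle_dir)
    if not bundle_dir.exists():
        raise FileNotFoundError(f"no bundle at {bundle_dir}")
    config = RunConfig.from_json(json.loads((bundle_dir / "config.json").read_text()))
    bundle = Bundle(config=config)
    if config.model == "aug_linear":
        bundle.dictionary = linear.CoefficientDictionary.load(bundle_dir / "dictionary.json")
    else:
        payload = json.loads((bundle_dir / "model.json").read_text())
        if payload["kind"] == "tree":
            bundle.tree_model = tree.tree_from_json(payload["tree"])
        else:
            estimators = [tree.tree_from_json(p) for p in payload["estimators"]]
            first = estimators[0]
            bundle.ensemble = tree.BaggingEnsemble(
                estimators=estimators,
                seeds=payload["seeds"],
                task=first.config.task,
                classes=first.classes,
            )
    return bundle


def run_interpret(
    bundle_dir: str | Path, k: int = 10, document: str | None = None
) -> dict:
    """Top/bottom coefficients of a bundle, or a per-document contribution table."""
    bundle = load_bundle(bundle_dir)
    if bundle.dictionary is None:
        raise ValueError("interpretation reports require an aug_linear bundle")
    dictionary = bundle.dictionary
    report: dict = {"bundle": str(bundle_dir), "n_entries": len(dictionary)}
    if document is None:
        if k > len(dictionary):
            report["notice"] = (
                f"k={k} exceeds dictionary size {len(dictionary)}; truncated"
            )
            k = len(dictionary)
        report["top"] = dictionary.top_ngrams(k)
        report["bottom"] = dictionary.bottom_ngrams(k)
    else:
        rows = dictionary.contributions(document)
        report["document"] = document
        report["intercept"] = [float(v) for v in dictionary.intercept]
        report["contributions"] = [
            {"ngram": t, "contribution": [float(v) for v in vec]} for t, vec in rows
        ]
        report["score"] = [float(v) for v in dictionary.score_document(document)]
    return report


def run_predict(bundle_dir: str | Path, corpus_path: str | Path) -> dict:
    """Predict a corpus file with a persisted bundle."""
    bundle = load_bundle(bundle_dir)
    corpus = read_corpus(corpus_path)
    preds = bundle.predict(corpus.documents)
    out = {"predictions": [linear._plain(p) for p in np.asarray(preds).tolist()]}
    if bundle.config.task == "classification":
        out["accuracy"] = float(np.mean(np.asarray(preds) == corpus.labels))
    else:
        out["mse"] = float(np.mean((np.asarray(preds) - corpus.labels) ** 2))
    return out


def run_simulate(
    kind: str, out_path: str | Path, seed: int = 0, spec_overrides: dict | None = None
) -> Path:
    """Generate a synthetic corpus (plus ground truth JSON) to disk."""
    out_path = Path(out_path)
    overrides = spec_overrides or {}
    if kind == "classification":
        spec = synthetic.SyntheticSpec(seed=seed, **overrides)
        corpus, truth = synthetic.generate_classification_corpus(spec)
        write_corpus(corpus, out_path)
    elif kind == "stream":
        spec = synthetic.StreamSpec(seed=seed, **overrides)
        words, offsets, responses, truth = synthetic.generate_regression_stream(spec)
        with out_path.open("w") as fh:
            fh.write("word\ttimepoint_index\n")
            t = 0
            for i, w in enumerate(words):
                while t < len(offsets) and i >= offsets[t]:
                    t += 1
                fh.write(f"{w}\t{t}\n")
        np.savetxt(out_path.with_suffix(".responses.tsv"), responses, delimiter="\t")
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    truth.save(out_path.with_suffix(".truth.json"))
    return out_path
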