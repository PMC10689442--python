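"""Decision trees whose splits are disjunctions of ngrams.

A CART-style greedy tree is grown on binary ngram-presence features
(does the document contain the ngram anywhere?). At every node the
single ngram maximizing the impurity decrease

    delta(s, t, y) = sum_{i in t} h(y_i, ybar_t)
                     - sum_{i in t_L} h(y_i, ybar_{t_L})
                     - sum_{i in t_R} h(y_i, ybar_{t_R})

is found exactly as CART would (h: Gini-based node cost for
classification, squared deviation from the node mean for regression).
The seed ngram is then *expanded*: a pluggable backend proposes similar
keyphrases (a generative-model prompt, embedding nearest neighbours, or
a static dictionary), and each candidate is greedily screened — it joins
the split's disjunction iff adding it does not increase the split's
child impurity. Candidates absent from every training document leave the
impurity unchanged and are therefore kept: they are exactly the
mechanism by which the tree generalizes to synonyms never seen in
training. A document routes to the "present" branch if it contains ANY
ngram of the disjunction.

Bagging ensembles average trees fit on same-size bootstrap resamples,
sharing one expansion cache across members.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .embeddings import EmbeddingBackend
from .text import NgramVocabulary, TokenizerConfig, build_vocabulary, tokenize

__all__ = [
    "AugTreeConfig",
    "Split",
    "TreeNode",
    "AugTree",
    "BaggingEnsemble",
    "ExpansionBackend",
    "NoOpExpander",
    "StaticDictionaryExpander",
    "EmbeddingNeighborExpander",
    "LLMExpander",
    "EXPANSION_PROMPT",
    "parse_numbered_list",
    "node_cost",
    "impurity_decrease",
    "find_best_single_split",
    "screen_expansion",
    "fit_aug_tree",
    "predict_tree",
    "fit_bagging_ensemble",
]

_SCREEN_TOL = 1e-12


# ---------------------------------------------------------------------------
# impurity


def node_cost(y: np.ndarray, task: str) -> float:
    """Summed per-sample cost of a node: N*Gini (classification) or SSE.

    Zero for a pure (or empty) node.
    """
    y = np.asarray(y)
    n = len(y)
    if n == 0:
        return 0.0
    if task == "classification":
        _, counts = np.unique(y, return_counts=True)
        return float(n - np.sum(counts.astype(float) ** 2) / n)
    if task == "regression":
        return float(np.sum((y - y.mean()) ** 2))
    raise ValueError(f"unknown task {task!r}")


def impurity_decrease(y: np.ndarray, left_mask: np.ndarray, task: str) -> float:
    """Parent cost minus summed child costs for the partition ``left_mask``."""
    y = np.asarray(y)
    left_mask = np.asarray(left_mask, dtype=bool)
    if left_mask.shape != y.shape:
        raise ValueError("left_mask must have the same shape as y")
    if not left_mask.any() or left_mask.all():
        raise ValueError("both sides of the partition must be non-empty")
    return (
        node_cost(y, task)
        - node_cost(y[left_mask], task)
        - node_cost(y[~left_mask], task)
    )


# ---------------------------------------------------------------------------
# splits


@dataclass
class Split:
    """A disjunction split: present-branch iff the document contains ANY ngram.

    ``ngrams[0]`` is the seed found by plain exhaustive search;
    subsequent entries are accepted expansion candidates in screening
    order. ``screened_out`` records rejected candidates with reasons.
    """

    ngrams: list[str]
    delta: float
    screened_out: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.ngrams:
            raise ValueError("a split needs at least one ngram")
        if len(set(self.ngrams)) != len(self.ngrams):
            raise ValueError("split ngrams must be duplicate-free")


@dataclass
class TreeNode:
    """A node of a fitted tree: either a split with two children or a leaf.

    ``value`` holds class frequencies (summing to 1) for classification
    or the mean response for regression; left child = present branch.
    """

    value: np.ndarray
    n_samples: int
    depth: int
    split: Split | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


def find_best_single_split(
    presence: np.ndarray,
    y: np.ndarray,
    task: str,
    feature_names: Sequence[str],
) -> Split | None:
    """Exhaustive search for the single ngram maximizing the impurity decrease.

    Returns None (leaf signal) if the node is pure or no feature varies.
    Ties are broken by lexicographically smallest ngram: features are
    scanned in lexicographic order and only a strictly larger decrease
    replaces the incumbent.
    """
    presence = np.asarray(presence, dtype=bool)
    y = np.asarray(y)
    n = len(y)
    parent = node_cost(y, task)
    if parent <= 0.0:
        return None
    order = np.argsort(np.asarray(feature_names, dtype=object))
    best: tuple[float, str] | None = None
    for j in order:
        col = presence[:, j]
        n_left = int(col.sum())
        if n_left == 0 or n_left == n:
            continue
        delta = parent - node_cost(y[col], task) - node_cost(y[~col], task)
        if best is None or delta > best[0] + _SCREEN_TOL:
            best = (delta, feature_names[j])
    if best is None or best[0] <= _SCREEN_TOL:
        return None
    return Split(ngrams=[best[1]], delta=best[0])


def screen_expansion(
    seed_split: Split,
    candidates: Sequence[str],
    presence_of: Callable[[str], np.ndarray],
    y: np.ndarray,
    task: str,
    max_disjunction: int = 100,
) -> Split:
    """Greedily extend the seed split with candidates that do not hurt purity.

    Candidates are visited in the given order. Each is tentatively added
    to the disjunction; it is kept iff the split's total child impurity
    does not increase (weak inequality — candidates absent from every
    training document change nothing and are retained, which is the
    out-of-vocabulary generalization mechanism). A candidate whose
    addition would absorb the entire absence branch is rejected as
    degenerate. The seed is never re-chosen, only extended.
    """
    y = np.asarray(y)
    parent = node_cost(y, task)
    current = np.asarray(presence_of(seed_split.ngrams[0]), dtype=bool)
    for extra in seed_split.ngrams[1:]:
        current = current | np.asarray(presence_of(extra), dtype=bool)
    child_cost = node_cost(y[current], task) + node_cost(y[~current], task)

    kept = list(seed_split.ngrams)
    rejected = list(seed_split.screened_out)
    for cand in candidates:
        if len(kept) >= max_disjunction:
            break
        if cand in kept:
            rejected.append((cand, "duplicate"))
            continue
        trial = current | np.asarray(presence_of(cand), dtype=bool)
        if trial.all():
            rejected.append((cand, "degenerate"))
            continue
        trial_cost = node_cost(y[trial], task) + node_cost(y[~trial], task)
        if trial_cost <= child_cost + _SCREEN_TOL:
            kept.append(cand)
            current = trial
            child_cost = trial_cost
        else:
            rejected.append((cand, "impurity_increase"))
    return Split(ngrams=kept, delta=parent - child_cost, screened_out=rejected)


# ---------------------------------------------------------------------------
# expansion backends


EXPANSION_PROMPT = (
    "Generate 100 concise phrases that are very similar to the keyphrase:\n"
    'Keyphrase: "{keyphrase}"\n1.'
)

_ITEM_RE = re.compile(r"^\s*(?:\d+[.)]\s*)?(.*?)\s*$")


def parse_numbered_list(completion: str) -> list[str]:
    """Parse a numbered-list completion into clean, deduplicated phrases.

    Phrases are stripped of numbering, surrounding quotes and trailing
    punctuation, lowercased, and returned in generation order with
    duplicates removed. An unparseable completion yields an empty list.
    """
    phrases: list[str] = []
    seen: set[str] = set()
    for line in completion.splitlines():
        m = _ITEM_RE.match(line)
        if not m:
            continue
        phrase = m.group(1).strip().strip('"“”\'').rstrip(".,;:").strip()
        phrase = phrase.lower()
        if phrase and phrase not in seen:
            seen.add(phrase)
            phrases.append(phrase)
    return phrases


class ExpansionBackend:
    """Maps a seed ngram to an ordered list of similar candidate ngrams."""

    expander_id: str = "base"

    def expand(self, ngram_text: str) -> list[str]:  # pragma: no cover - interface
        raise NotImplementedError


class NoOpExpander(ExpansionBackend):
    """Never proposes candidates; reduces the tree to plain CART."""

    expander_id = "noop"

    def expand(self, ngram_text: str) -> list[str]:
        return []


class StaticDictionaryExpander(ExpansionBackend):
    """Fixed ngram -> synonym-list mapping (deterministic test/mock backend)."""

    def __init__(self, mapping: dict[str, Sequence[str]], expander_id: str = "static"):
        self.mapping = {k: list(v) for k, v in mapping.items()}
        self.expander_id = expander_id

    def expand(self, ngram_text: str) -> list[str]:
        return list(self.mapping.get(ngram_text, []))


class EmbeddingNeighborExpander(ExpansionBackend):
    """Vocabulary ngrams ranked by cosine similarity under an embedding backend."""

    def __init__(
        self,
        vocab: NgramVocabulary,
        backend: EmbeddingBackend,
        top_k: int = 10,
        min_similarity: float = 0.0,
    ):
        self.vocab_texts = [g.text for g in vocab.ngrams]
        self.top_k = top_k
        self.min_similarity = min_similarity
        self.expander_id = f"embed-nn-{backend.backend_id}-k{top_k}"
        matrix = np.vstack([backend.embed(t) for t in self.vocab_texts])
        norms = np.linalg.norm(matrix, axis=1)
        norms[norms == 0] = 1.0
        self._unit = matrix / norms[:, None]
        self._backend = backend

    def expand(self, ngram_text: str) -> list[str]:
        v = self._backend.embed(ngram_text)
        norm = np.linalg.norm(v)
        if norm == 0:
            return []
        sims = self._unit @ (v / norm)
        order = np.argsort(-sims, kind="stable")
        out = []
        for i in order:
            if self.vocab_texts[i] == ngram_text or sims[i] < self.min_similarity:
                continue
            out.append(self.vocab_texts[i])
            if len(out) >= self.top_k:
                break
        return out


class LLMExpander(ExpansionBackend):
    """Keyphrase expansion through a generative-model completion endpoint.

    ``completion_fn(prompt) -> str`` performs the actual API call and is
    injected so the component is testable offline; responses are cached
    by (expander_id, ngram) and the cache persists as JSON, making
    repeat fits and bagging ensembles free of extra calls.
    """

    def __init__(
        self,
        completion_fn: Callable[[str], str] | None = None,
        expander_id: str = "llm",
        cache_path: str | Path | None = None,
    ):
        self.completion_fn = completion_fn
        self.expander_id = expander_id
        self.cache_path = Path(cache_path) if cache_path else None
        self.cache: dict[str, list[str]] = {}
        if self.cache_path and self.cache_path.exists():
            self.cache = json.loads(self.cache_path.read_text())

    def expand(self, ngram_text: str) -> list[str]:
        if not ngram_text:
            raise ValueError("cannot expand an empty ngram")
        if ngram_text in self.cache:
            return list(self.cache[ngram_text])
        if self.completion_fn is None:
            raise RuntimeError(
                f"no completion endpoint configured and {ngram_text!r} is not cached"
            )
        prompt = EXPANSION_PROMPT.format(keyphrase=ngram_text)
        completion = self.completion_fn(prompt)
        candidates = parse_numbered_list(completion)
        if completion.strip() and not candidates:
            import warnings

            warnings.warn(f"unparseable expansion completion for {ngram_text!r}")
        candidates = [c for c in candidates if c != ngram_text]
        self.cache[ngram_text] = candidates
        if self.cache_path:
            self.cache_path.write_text(json.dumps(self.cache, indent=1, sort_keys=True))
        return list(candidates)


# ---------------------------------------------------------------------------
# tree fitting


@dataclass(frozen=True)
class AugTreeConfig:
    """Tree hyperparameters.

    Split candidates default to bigram features with ``min_count`` 2 to
    keep the exhaustive seed search tractable; single interpretable
    trees default to depth 3 (ensemble members are grown to depth 8).
    """

    task: str = "classification"
    feature_orders: tuple[int, ...] = (2,)
    min_count: int = 2
    max_depth: int = 3
    min_samples_leaf: int = 1
    max_disjunction: int = 100
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)


@dataclass
class AugTree:
    """A fitted disjunction-split tree plus the metadata needed to predict."""

    root: TreeNode
    config: AugTreeConfig
    classes: np.ndarray | None
    feature_names: list[str]

    def predict_proba(self, docs: Sequence[str]) -> np.ndarray:
        return predict_tree(self, docs, return_value=True)

    def predict(self, docs: Sequence[str]) -> np.ndarray:
        values = predict_tree(self, docs, return_value=True)
        if self.config.task == "regression":
            return values[:, 0]
        return self.classes[np.argmax(values, axis=1)]


def _doc_search_strings(docs: Sequence[str], tokenizer: TokenizerConfig) -> list[str]:
    # padded token strings so " ngram " membership equals contiguous-run presence
    return [" " + " ".join(tokenize(d, tokenizer)) + " " for d in docs]


def _leaf_value(y: np.ndarray, task: str, classes: np.ndarray | None) -> np.ndarray:
    if task == "regression":
        return np.array([float(np.mean(y))])
    freq = np.array([np.mean(y == c) for c in classes], dtype=float)
    return freq


def fit_aug_tree(
    docs: Sequence[str],
    y: np.ndarray,
    expander: ExpansionBackend | None = None,
    config: AugTreeConfig | None = None,
) -> AugTree:
    """Grow a disjunction-split tree: seed split -> expand -> screen -> recurse.

    Recursion stops at ``max_depth``, at pure nodes, when no split
    achieves a positive impurity decrease, or when a child would fall
    below ``min_samples_leaf``.
    """
    if config is None:
        config = AugTreeConfig()
    if expander is None:
        expander = NoOpExpander()
    y = np.asarray(y)
    if len(docs) != len(y):
        raise ValueError("docs and y must have the same length")
    if len(docs) < 2:
        raise ValueError("need at least 2 samples to fit a tree")
    classes = None if config.task == "regression" else np.unique(y)

    vocab = build_vocabulary(
        list(docs), config.feature_orders, min_count=config.min_count,
        tokenizer=config.tokenizer,
    )
    feature_names = [g.text for g in vocab.ngrams]
    search_strings = _doc_search_strings(docs, config.tokenizer)
    presence = np.zeros((len(docs), len(feature_names)), dtype=bool)
    for j, name in enumerate(feature_names):
        needle = f" {name} "
        presence[:, j] = [needle in s for s in search_strings]

    presence_cache: dict[str, np.ndarray] = {}

    def presence_vector(ngram_text: str) -> np.ndarray:
        vec = presence_cache.get(ngram_text)
        if vec is None:
            needle = " " + " ".join(ngram_text.split()) + " "
            vec = np.fromiter(
                (needle in s for s in search_strings), dtype=bool, count=len(search_strings)
            )
            presence_cache[ngram_text] = vec
        return vec

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node_y = y[idx]
        node = TreeNode(
            value=_leaf_value(node_y, config.task, classes),
            n_samples=len(idx),
            depth=depth,
        )
        if depth >= config.max_depth or len(idx) < 2 * config.min_samples_leaf:
            return node
        seed = find_best_single_split(
            presence[idx], node_y, config.task, feature_names
        )
        if seed is None:
            return node
        candidates = expander.expand(seed.ngrams[0])
        split = screen_expansion(
            seed,
            candidates,
            lambda t: presence_vector(t)[idx],
            node_y,
            config.task,
            max_disjunction=config.max_disjunction,
        )
        present = presence_vector(split.ngrams[0])[idx]
        for extra in split.ngrams[1:]:
            present = present | presence_vector(extra)[idx]
        n_left = int(present.sum())
        if (
            n_left < config.min_samples_leaf
            or len(idx) - n_left < config.min_samples_leaf
            or split.delta <= _SCREEN_TOL
        ):
            return node
        node.split = split
        node.left = grow(idx[present], depth + 1)
        node.right = grow(idx[~present], depth + 1)
        return node

    root = grow(np.arange(len(docs)), 0)
    return AugTree(root=root, config=config, classes=classes, feature_names=feature_names)


def predict_tree(
    tree: AugTree, docs: Sequence[str], return_value: bool = False
) -> np.ndarray:
    """Route documents through disjunction-presence tests to leaf values.

    A document containing ANY ngram of a split's disjunction — including
    augmented synonyms never seen in training — takes the presence
    branch; an empty document follows the all-absence path.
    """
    search_strings = _doc_search_strings(docs, tree.config.tokenizer)

    def route(s: str) -> np.ndarray:
        node = tree.root
        while not node.is_leaf:
            present = any(f" {g} " in s for g in node.split.ngrams)
            node = node.left if present else node.right
        return node.value

    values = np.vstack([route(s) for s in search_strings])
    if return_value:
        return values
    if tree.config.task == "regression":
        return values[:, 0]
    return tree.classes[np.argmax(values, axis=1)]


# ---------------------------------------------------------------------------
# bagging


@dataclass
class BaggingEnsemble:
    """Mean-aggregated trees fit on same-size bootstrap resamples."""

    estimators: list[AugTree]
    seeds: list[int]
    task: str
    classes: np.ndarray | None

    def predict_proba(self, docs: Sequence[str]) -> np.ndarray:
        stacked = np.stack([t.predict_proba(docs) for t in self.estimators])
        return stacked.mean(axis=0)

    def predict(self, docs: Sequence[str]) -> np.ndarray:
        agg = self.predict_proba(docs)
        if self.task == "regression":
            return agg[:, 0]
        return self.classes[np.argmax(agg, axis=1)]


def fit_bagging_ensemble(
    docs: Sequence[str],
    y: np.ndarray,
    expander: ExpansionBackend | None = None,
    n_estimators: int = 10,
    config: AugTreeConfig | None = None,
    master_seed: int = 0,
    bootstrap: bool = True,
) -> BaggingEnsemble:
    """Fit ``n_estimators`` trees on seeded bootstrap resamples of size n.

    With ``bootstrap=False`` and one estimator this reduces exactly to a
    single `fit_aug_tree`. Expansion caching lives in the expander, so
    repeated seeds across members cost nothing extra.
    """
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    if config is None:
        config = AugTreeConfig()
    y = np.asarray(y)
    estimators: list[AugTree] = []
    seeds: list[int] = []
    for i in range(n_estimators):
        seed = master_seed + i
        seeds.append(seed)
        if bootstrap:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, len(docs), size=len(docs))
        else:
            idx = np.arange(len(docs))
        boot_docs = [docs[j] for j in idx]
        estimators.append(fit_aug_tree(boot_docs, y[idx], expander, config))
    classes = None if config.task == "regression" else np.unique(y)
    return BaggingEnsemble(estimators=estimators, seeds=seeds, task=config.task, classes=classes)


# ---------------------------------------------------------------------------
# serialization / rendering


def _node_to_json(node: TreeNode) -> dict:
    payload = {
        "value": [float(v) for v in node.value],
        "n_samples": node.n_samples,
        "depth": node.depth,
    }
    if not node.is_leaf:
        payload["split"] = {
            "ngrams": node.split.ngrams,
            "delta": node.split.delta,
            "screened_out": [list(pair) for pair in node.split.screened_out],
        }
        payload["left"] = _node_to_json(node.left)
        payload["right"] = _node_to_json(node.right)
    return payload


def _node_from_json(payload: dict) -> TreeNode:
    node = TreeNode(
        value=np.asarray(payload["value"], dtype=float),
        n_samples=payload["n_samples"],
        depth=payload["depth"],
    )
    if "split" in payload:
        node.split = Split(
            ngrams=list(payload["split"]["ngrams"]),
            delta=float(payload["split"]["delta"]),
            screened_out=[tuple(pair) for pair in payload["split"]["screened_out"]],
        )
        node.left = _node_from_json(payload["left"])
        node.right = _node_from_json(payload["right"])
    return node


def tree_to_json(tree: AugTree) -> dict:
    return {
        "task": tree.config.task,
        "classes": None if tree.classes is None else [_plain(c) for c in tree.classes],
        "config": {
            "feature_orders": list(tree.config.feature_orders),
            "min_count": tree.config.min_count,
            "max_depth": tree.config.max_depth,
            "min_samples_leaf": tree.config.min_samples_leaf,
            "max_disjunction": tree.config.max_disjunction,
            "tokenizer": {
                "lowercase": tree.config.tokenizer.lowercase,
                "keep_punctuation": tree.config.tokenizer.keep_punctuation,
                "tokenizer_id": tree.config.tokenizer.tokenizer_id,
            },
        },
        "feature_names": tree.feature_names,
        "root": _node_to_json(tree.root),
    }


def tree_from_json(payload: dict) -> AugTree:
    cfg = payload["config"]
    config = AugTreeConfig(
        task=payload["task"],
        feature_orders=tuple(cfg["feature_orders"]),
        min_count=cfg["min_count"],
        max_depth=cfg["max_depth"],
        min_samples_leaf=cfg["min_samples_leaf"],
        max_disjunction=cfg["max_disjunction"],
        tokenizer=TokenizerConfig(**cfg["tokenizer"]),
    )
    classes = None if payload["classes"] is None else np.asarray(payload["classes"])
    return AugTree(
        root=_node_from_json(payload["root"]),
        config=config,
        classes=classes,
        feature_names=list(payload["feature_names"]),
    )


def render_tree(tree: AugTree, max_ngrams: int = 4) -> str:
    """Human-readable indented rendering of the tree."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str):
        if node.is_leaf:
            if tree.config.task == "regression":
                desc = f"mean={node.value[0]:.4g}"
            else:
                desc = "p=[" + ", ".join(f"{v:.2f}" for v in node.value) + "]"
            lines.append(f"{prefix}leaf n={node.n_samples} {desc}")
            return
        shown = node.split.ngrams[:max_ngrams]
        more = len(node.split.ngrams) - len(shown)
        disj = " | ".join(repr(g) for g in shown) + (f" | +{more} more" if more else "")
        lines.append(
            f"{prefix}contains {disj}? (delta={node.split.delta:.4g}, n={node.n_samples})"
        )
        walk(node.left, prefix + "  [yes] ")
        walk(node.right, prefix + "  [no]  ")

    walk(tree.root, "")
    return "\n".join(lines)


def _plain(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value
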