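"""Embedding backends: the map φ from an ngram string to a fixed-length vector.

The augmented linear model is a GLM on the *sum* of per-ngram embeddings,
so everything downstream only needs a deterministic callable
``embed(ngram_text) -> vector`` with a stable ``backend_id`` and constant
``dim``. Four backends are provided:

* ``OneHotEmbedder`` — basis vectors over a fixed vocabulary; recovers the
  classical bag-of-ngrams GLM exactly (out-of-vocabulary ngrams map to the
  zero vector).
* ``HashEmbedder`` — seeded pseudo-random unit vectors keyed on the ngram
  string; a fast, dependency-free stand-in with near-orthogonal vectors,
  used throughout the test corpus experiments.
* ``WordVectorBackend`` — mean of per-word vectors from a GloVe-format
  text table (missing words contribute zero vectors to the mean).
* ``TransformerBackend`` — hidden states of a language-model checkpoint,
  mean-pooled over token positions; requires torch + transformers.

An ``EmbeddingCache`` memoizes vectors keyed on ``(backend_id, ngram)``
and round-trips losslessly through disk; enabling it never changes any
downstream prediction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .text import Ngram, NgramVocabulary

__all__ = [
    "BackendError",
    "EmbeddingBackend",
    "EmbeddingCache",
    "HashEmbedder",
    "OneHotEmbedder",
    "WordVectorBackend",
    "TransformerBackend",
    "embed_ngram",
    "make_hash_embedder",
    "make_onehot_embedder",
    "load_word_vector_backend",
    "make_transformer_backend",
]


class BackendError(RuntimeError):
    """An embedding backend is unavailable or failed; never silently zeros."""


class EmbeddingBackend:
    """Deterministic map from an ngram string to a length-``dim`` vector."""

    backend_id: str
    dim: int

    def embed(self, ngram_text: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class EmbeddingCache:
    """Memo table ``(backend_id, ngram) -> vector`` with optional persistence.

    Persisted as a ``.npz`` of vectors plus a JSON manifest recording the
    backend ids and dims present, so stale vectors from a differently
    configured backend can never be served.
    """

    entries: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    path: Path | None = None

    def get(self, backend_id: str, ngram_text: str) -> np.ndarray | None:
        return self.entries.get((backend_id, ngram_text))

    def put(self, backend_id: str, ngram_text: str, vector: np.ndarray) -> None:
        self.entries[(backend_id, ngram_text)] = np.asarray(vector)

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path | None = None) -> Path:
        path = Path(path or self.path)
        if path is None:
            raise ValueError("no persistence path configured")
        keys = sorted(self.entries)
        arrays = {str(i): self.entries[k] for i, k in enumerate(keys)}
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = {
            "keys": [[b, t] for b, t in keys],
            "backends": sorted({b for b, _ in keys}),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingCache":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as data:
            entries = {
                (b, t): data[str(i)]
                for i, (b, t) in enumerate(manifest["keys"])
            }
        return cls(entries=entries, path=path)


def embed_ngram(
    backend: EmbeddingBackend,
    ngram: Ngram | str,
    cache: EmbeddingCache | None = None,
) -> np.ndarray:
    """Embed one ngram, consulting/populating ``cache`` when provided."""
    text = ngram.text if isinstance(ngram, Ngram) else ngram
    if not text:
        raise ValueError("cannot embed an empty ngram")
    if cache is not None:
        hit = cache.get(backend.backend_id, text)
        if hit is not None:
            return hit
    vector = backend.embed(text)
    if cache is not None:
        cache.put(backend.backend_id, text, vector)
    return vector


# ---------------------------------------------------------------------------
# hash backend


class HashEmbedder(EmbeddingBackend):
    """Pseudo-random unit vectors keyed on a seeded hash of the ngram string.

    Distinct strings get independent (near-orthogonal at large ``dim``)
    directions; the mapping is identical across processes and platforms
    because the per-ngram RNG is seeded from a BLAKE2b digest.
    """

    def __init__(self, dim: int, seed: int = 0):
        if dim < 2:
            raise ValueError("hash embedder needs dim >= 2")
        self.dim = int(dim)
        self.seed = int(seed)
        self.backend_id = f"hash-d{dim}-s{seed}"

    def embed(self, ngram_text: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}\x00{ngram_text}".encode("utf-8"), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)


def make_hash_embedder(dim: int, seed: int = 0) -> HashEmbedder:
    return HashEmbedder(dim=dim, seed=seed)


# ---------------------------------------------------------------------------
# one-hot backend


class OneHotEmbedder(EmbeddingBackend):
    """Basis vectors over a fixed ngram vocabulary (dim = vocabulary size).

    Summing these per-document recovers the bag-of-ngrams count vector
    exactly; out-of-vocabulary ngrams embed to the zero vector.
    """

    def __init__(self, vocab: NgramVocabulary):
        if len(vocab) == 0:
            raise ValueError("one-hot embedder needs a non-empty vocabulary")
        self.vocab = vocab
        self.dim = vocab.p
        self._index = vocab.index()
        fingerprint = hashlib.blake2b(
            "\x00".join(g.text for g in vocab.ngrams).encode("utf-8"), digest_size=6
        ).hexdigest()
        self.backend_id = f"onehot-p{vocab.p}-{fingerprint}"

    def embed(self, ngram_text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        i = self._index.get(ngram_text)
        if i is not None:
            v[i] = 1.0
        return v


def make_onehot_embedder(vocab: NgramVocabulary) -> OneHotEmbedder:
    return OneHotEmbedder(vocab)


# ---------------------------------------------------------------------------
# word-vector (GloVe text format) backend


class WordVectorBackend(EmbeddingBackend):
    """Mean of per-word vectors from a GloVe-format table.

    Words missing from the table contribute zero vectors to the mean, so
    φ stays total over arbitrary ngrams.
    """

    def __init__(self, table: dict[str, np.ndarray], dim: int, source: str = "wordvec"):
        self.table = table
        self.dim = dim
        self.backend_id = f"wordvec-{source}-d{dim}"

    def embed(self, ngram_text: str) -> np.ndarray:
        words = ngram_text.split()
        acc = np.zeros(self.dim)
        for w in words:
            vec = self.table.get(w)
            if vec is not None:
                acc += vec
        return acc / len(words)


def load_word_vector_backend(path: str | Path) -> WordVectorBackend:
    """Load a GloVe text table: one ``token v1 v2 ... vd`` line per word."""
    path = Path(path)
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(" ")
            token, values = parts[0], parts[1:]
            try:
                vec = np.array([float(v) for v in values])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed vector line ({exc})"
                ) from exc
            if dim is None:
                dim = len(vec)
                if dim == 0:
                    raise ValueError(f"{path.name}:{lineno}: no vector components")
            elif len(vec) != dim:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {dim} components, got {len(vec)}"
                )
            table[token] = vec
    if dim is None:
        raise ValueError(f"{path.name}: empty word-vector table")
    fingerprint = hashlib.blake2b(path.name.encode(), digest_size=4).hexdigest()
    return WordVectorBackend(table=table, dim=dim, source=fingerprint)


# ---------------------------------------------------------------------------
# transformer backend


def mean_pool_hidden_states(
    hidden: np.ndarray, special_mask: np.ndarray, include_special_tokens: bool
) -> np.ndarray:
    """Average hidden states over the token-position dimension.

    ``hidden`` is (n_tokens, dim); ``special_mask`` flags special tokens
    (e.g. [CLS]/[SEP]). With ``include_special_tokens`` every position is
    averaged; otherwise special positions are dropped (falling back to
    all positions if nothing remains).
    """
    hidden = np.asarray(hidden, dtype=float)
    if not include_special_tokens:
        keep = ~np.asarray(special_mask, dtype=bool)
        if keep.any():
            hidden = hidden[keep]
    return hidden.mean(axis=0)


class TransformerBackend(EmbeddingBackend):
    """Mean-pooled hidden states of a language-model checkpoint.

    The ngram is prepared with the model's own preprocessing (for BERT
    style models: prepend [CLS], append [SEP], word-piece tokenize), run
    through the model in eval mode, and the configured layer's hidden
    states are averaged over the token-position dimension.
    """

    def __init__(
        self,
        checkpoint: str,
        layer: int = -1,
        include_special_tokens: bool = True,
        _loader=None,
    ):
        self.checkpoint = checkpoint
        self.layer = layer
        self.include_special_tokens = include_special_tokens
        loader = _loader if _loader is not None else _default_transformer_loader
        self._tokenizer, self._model = loader(checkpoint)
        probe = self._hidden_states("a")
        self.dim = probe.shape[-1]
        pooling = "all" if include_special_tokens else "nospecial"
        self.backend_id = f"transformer-{checkpoint}-L{layer}-{pooling}"

    def _hidden_states(self, text: str) -> np.ndarray:
        encoded = self._tokenizer(text)
        layers = self._model(encoded["input_ids"])
        return np.asarray(layers[self.layer], dtype=float)

    def _special_mask(self, text: str) -> np.ndarray:
        return np.asarray(self._tokenizer(text)["special_tokens_mask"], dtype=bool)

    def embed(self, ngram_text: str) -> np.ndarray:
        hidden = self._hidden_states(ngram_text)
        return mean_pool_hidden_states(
            hidden, self._special_mask(ngram_text), self.include_special_tokens
        )


def _default_transformer_loader(checkpoint: str):
    try:
        import torch  # noqa: F401
        from transformers import AutoModel, AutoTokenizer
    except ImportError as exc:
        raise BackendError(
            f"transformer backend for {checkpoint!r} requires torch and "
            "transformers; install them or use a hash/one-hot/word-vector backend"
        ) from exc

    import torch

    try:
        hf_tokenizer = AutoTokenizer.from_pretrained(checkpoint)
        model = AutoModel.from_pretrained(checkpoint, output_hidden_states=True)
    except Exception as exc:  # missing/corrupt checkpoint
        raise BackendError(f"could not load checkpoint {checkpoint!r}: {exc}") from exc
    model.eval()

    def tokenizer(text: str) -> dict:
        enc = hf_tokenizer(text, return_special_tokens_mask=True, return_tensors="pt")
        return {
            "input_ids": enc["input_ids"],
            "special_tokens_mask": enc["special_tokens_mask"][0].numpy(),
        }

    def forward(input_ids) -> list[np.ndarray]:
        with torch.no_grad():
            out = model(input_ids)
        return [h[0].numpy() for h in out.hidden_states]

    return tokenizer, forward


def make_transformer_backend(
    checkpoint: str,
    layer: int = -1,
    include_special_tokens: bool = True,
    _loader=None,
) -> TransformerBackend:
    """Build a transformer embedding backend (default layer: final hidden layer)."""
    return TransformerBackend(
        checkpoint=checkpoint,
        layer=layer,
        include_special_tokens=include_special_tokens,
        _loader=_loader,
    )
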