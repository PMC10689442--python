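"""Word-level tokenization, ngram extraction and vocabulary building.

Every model in this package operates on ngrams: contiguous runs of
word-level tokens. Documents are tokenized with a deterministic regex
word tokenizer (words, including internal apostrophes, and individual
punctuation marks), ngrams of the configured orders are enumerated with
multiset semantics (one entry per occurrence), and a corpus-level
vocabulary records occurrence counts and the fraction of ngrams seen
exactly once — the quantity that explodes as the ngram order grows.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TokenizerConfig",
    "Ngram",
    "NgramVocabulary",
    "LabeledCorpus",
    "tokenize",
    "extract_ngrams",
    "build_vocabulary",
    "read_corpus",
    "write_corpus",
]

# Words keep internal apostrophes ("don't"); every other non-space
# character is emitted as its own punctuation token.
_TOKEN_RE = re.compile(r"\w+(?:'\w+)*|[^\w\s]", re.UNICODE)
_WORD_RE = re.compile(r"\w", re.UNICODE)


@dataclass(frozen=True)
class TokenizerConfig:
    """Configuration of the word-level tokenizer.

    Parameters
    ----------
    lowercase
        Lowercase text before tokenization (default True; the default
        embedding backends are uncased).
    keep_punctuation
        Emit punctuation marks as tokens (default True; word-level
        tokenizers emit them).
    tokenizer_id
        Stable identifier of the tokenizer in use, recorded in model
        provenance.
    """

    lowercase: bool = True
    keep_punctuation: bool = True
    tokenizer_id: str = "regex-word-v1"


def tokenize(text: str, config: TokenizerConfig | None = None) -> list[str]:
    """Split ``text`` into word-level tokens.

    Deterministic: the same string under the same config always yields
    the same token list. Empty input yields an empty list.
    """
    if config is None:
        config = TokenizerConfig()
    if config.lowercase:
        text = text.lower()
    tokens = _TOKEN_RE.findall(text)
    if not config.keep_punctuation:
        tokens = [t for t in tokens if _WORD_RE.search(t)]
    return tokens


@dataclass(frozen=True)
class Ngram:
    """A contiguous run of word-level tokens.

    ``text`` is the space-joined surface form and ``order`` the number
    of tokens; the two must agree.
    """

    text: str
    order: int

    def __post_init__(self) -> None:
        n_tokens = len(self.text.split())
        if n_tokens != self.order:
            raise ValueError(
                f"ngram order {self.order} does not match token count "
                f"{n_tokens} of {self.text!r}"
            )

    @classmethod
    def from_tokens(cls, tokens: Sequence[str]) -> "Ngram":
        return cls(text=" ".join(tokens), order=len(tokens))


def extract_ngrams(tokens: Sequence[str], orders: Iterable[int]) -> list[Ngram]:
    """Enumerate every contiguous run of ``tokens`` whose length is in ``orders``.

    Multiset semantics: each occurrence produces one entry, in document
    order (order of the run start, then increasing run length). Runs
    never cross document boundaries because extraction is per document.

    Raises
    ------
    ValueError
        If ``orders`` is empty or contains a non-positive order.
    """
    orders = sorted(set(orders))
    if not orders:
        raise ValueError("orders must contain at least one ngram order")
    if orders[0] < 1:
        raise ValueError(f"ngram orders must be >= 1, got {orders[0]}")
    out: list[Ngram] = []
    n = len(tokens)
    for start in range(n):
        for k in orders:
            if start + k > n:
                break
            out.append(Ngram(" ".join(tokens[start : start + k]), k))
    return out


@dataclass(frozen=True)
class NgramVocabulary:
    """Ordered ngram vocabulary with corpus occurrence counts.

    Entries are sorted lexicographically by surface form so that the
    column order of any derived feature matrix is deterministic.
    """

    ngrams: tuple[Ngram, ...]
    counts: dict[str, int] = field(compare=False)

    def __post_init__(self) -> None:
        texts = [g.text for g in self.ngrams]
        if texts != sorted(texts):
            raise ValueError("vocabulary entries must be in lexicographic order")
        if any(self.counts[t] < 1 for t in texts):
            raise ValueError("vocabulary counts must be >= 1")

    @property
    def p(self) -> int:
        """Number of unique ngrams."""
        return len(self.ngrams)

    @property
    def singleton_fraction(self) -> float:
        """Fraction of vocabulary ngrams occurring exactly once in the corpus."""
        if not self.ngrams:
            return 0.0
        return sum(1 for g in self.ngrams if self.counts[g.text] == 1) / self.p

    def index(self) -> dict[str, int]:
        return {g.text: i for i, g in enumerate(self.ngrams)}

    def __contains__(self, text: str) -> bool:
        return text in self.counts

    def __len__(self) -> int:
        return self.p


@dataclass
class LabeledCorpus:
    """Documents paired with class labels or continuous responses."""

    documents: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.documents) != len(self.labels):
            raise ValueError(
                f"{len(self.documents)} documents but {len(self.labels)} labels"
            )
        if len(self.documents) < 1:
            raise ValueError("corpus must contain at least one document")

    @property
    def n(self) -> int:
        return len(self.documents)


def build_vocabulary(
    corpus: LabeledCorpus | Sequence[str],
    orders: Iterable[int],
    min_count: int = 1,
    tokenizer: TokenizerConfig | None = None,
) -> NgramVocabulary:
    """Collect all corpus ngrams with count >= ``min_count``.

    Invariant to document order (counts are a sum over documents and the
    result is sorted lexicographically).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    docs = corpus.documents if isinstance(corpus, LabeledCorpus) else list(corpus)
    if not docs:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    orders = sorted(set(orders))
    counts: Counter[str] = Counter()
    order_of: dict[str, int] = {}
    for doc in docs:
        for g in extract_ngrams(tokenize(doc, tokenizer), orders):
            counts[g.text] += 1
            order_of[g.text] = g.order
    kept = sorted(t for t, c in counts.items() if c >= min_count)
    return NgramVocabulary(
        ngrams=tuple(Ngram(t, order_of[t]) for t in kept),
        counts={t: counts[t] for t in kept},
    )


# ---------------------------------------------------------------------------
# corpus I/O — CSV/TSV with (text, label) columns, or JSONL with
# {"text": ..., "label": ...} per line


def _coerce_labels(values: pd.Series) -> np.ndarray:
    arr = values.to_numpy()
    numeric = pd.to_numeric(values, errors="coerce")
    if not numeric.isna().any():
        arr = numeric.to_numpy()
        # integer-valued numeric labels are treated as class labels
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(int)
    return arr


def read_corpus(
    path: str | Path,
    text_column: str = "text",
    label_column: str = "label",
) -> LabeledCorpus:
    """Read a labeled corpus from CSV, TSV or JSONL (by file extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson"}:
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        frame = pd.DataFrame(rows)
    elif suffix == ".tsv":
        frame = pd.read_csv(path, sep="\t")
    elif suffix == ".csv":
        frame = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported corpus format: {path.name}")
    for column in (text_column, label_column):
        if column not in frame.columns:
            raise ValueError(f"corpus file {path.name} is missing column {column!r}")
    docs = frame[text_column].fillna("").astype(str).tolist()
    return LabeledCorpus(documents=docs, labels=_coerce_labels(frame[label_column]))


def write_corpus(
    corpus: LabeledCorpus,
    path: str | Path,
    text_column: str = "text",
    label_column: str = "label",
) -> Path:
    """Write a corpus in any of the dialects `read_corpus` accepts."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson"}:
        with path.open("w") as fh:
            for doc, label in zip(corpus.documents, corpus.labels):
                fh.write(json.dumps({text_column: doc, label_column: _json_scalar(label)}))
                fh.write("\n")
    elif suffix in {".csv", ".tsv"}:
        sep = "\t" if suffix == ".tsv" else ","
        frame = pd.DataFrame({text_column: corpus.documents, label_column: corpus.labels})
        frame.to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unsupported corpus format: {path.name}")
    return path


def _json_scalar(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value
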