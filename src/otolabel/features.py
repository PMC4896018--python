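"""N-gram feature space construction and document vectorization.

The vocabulary is every word or character n-gram (n in [1, 3]) occurring in
at least one *training* document; test documents are mapped onto that fixed
vocabulary and out-of-vocabulary n-grams are dropped.  Vectors are sparse,
either binary presence indicators or occurrence counts.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "FeatureConfig",
    "FeatureSpace",
    "FeatureVector",
    "extract_ngrams",
    "fit_feature_space",
    "vectorize",
    "vectorize_all",
]

UNITS = ("word", "character")
VALUE_MODES = ("binary", "count")


@dataclass(frozen=True)
class FeatureConfig:
    """N-gram featurization settings: unit, n range and value mode."""

    unit: str = "word"
    n_min: int = 1
    n_max: int = 1
    value_mode: str = "count"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if self.value_mode not in VALUE_MODES:
            raise ValueError(
                f"value_mode must be one of {VALUE_MODES}, got {self.value_mode!r}")
        if not (1 <= self.n_min <= self.n_max <= 3):
            raise ValueError("n range must satisfy 1 <= n_min <= n_max <= 3")

    def as_dict(self) -> dict:
        return {"unit": self.unit, "n_min": self.n_min, "n_max": self.n_max,
                "value_mode": self.value_mode}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


def extract_ngrams(tokens: Sequence[str], config: FeatureConfig) -> Counter:
    """Multiset of n-grams of a normalized token sequence.

    Word n-grams are contiguous token runs joined by single spaces; character
    n-grams are taken from the space-joined token string and may span the
    joining spaces (preserving cross-word character context).
    """
    grams: Counter = Counter()
    if config.unit == "word":
        for n in range(config.n_min, config.n_max + 1):
            for i in range(len(tokens) - n + 1):
                grams[" ".join(tokens[i: i + n])] += 1
    else:
        text = " ".join(tokens)
        for n in range(config.n_min, config.n_max + 1):
            for i in range(len(text) - n + 1):
                grams[text[i: i + n]] += 1
    return grams


@dataclass(frozen=True)
class FeatureSpace:
    """An ordered n-gram vocabulary fitted on training documents."""

    config: FeatureConfig
    vocabulary: tuple[str, ...]
    index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.index is None:
            object.__setattr__(
                self, "index", {g: i for i, g in enumerate(self.vocabulary)})

    def __len__(self) -> int:
        return len(self.vocabulary)

    def to_json(self) -> str:
        return json.dumps({"version": 1, "config": self.config.as_dict(),
                           "vocabulary": list(self.vocabulary)})

    @classmethod
    def from_json(cls, payload: str) -> "FeatureSpace":
        obj = json.loads(payload)
        return cls(config=FeatureConfig.from_dict(obj["config"]),
                   vocabulary=tuple(obj["vocabulary"]))


@dataclass(frozen=True)
class FeatureVector:
    """Sparse representation of one document over a fitted feature space."""

    dimension: int
    values: dict  # index -> value (1 for binary mode, positive int for count)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.dimension)
        for i, v in self.values.items():
            arr[i] = v
        return arr


def fit_feature_space(train_docs: Sequence[Sequence[str]],
                      config: FeatureConfig) -> FeatureSpace:
    """Fit the vocabulary on training documents only.

    The vocabulary is the union of the documents' n-grams in lexicographic
    order, so refitting on a permutation of the corpus is reproducible.
    """
    if not train_docs:
        raise ValueError("cannot fit a feature space on an empty training set")
    vocab: set[str] = set()
    for doc in train_docs:
        vocab.update(extract_ngrams(doc, config).keys())
    return FeatureSpace(config=config, vocabulary=tuple(sorted(vocab)))


def vectorize(doc: Sequence[str], space: FeatureSpace) -> FeatureVector:
    """Map one document onto the feature space (OOV n-grams dropped)."""
    grams = extract_ngrams(doc, space.config)
    values: dict[int, int] = {}
    binary = space.config.value_mode == "binary"
    for gram, count in grams.items():
        idx = space.index.get(gram)
        if idx is not None:
            values[idx] = 1 if binary else count
    return FeatureVector(dimension=len(space), values=values)


def vectorize_all(docs: Sequence[Sequence[str]],
                  space: FeatureSpace) -> sparse.csr_matrix:
    """Vectorize a batch of documents into a CSR matrix (rows = documents)."""
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    binary = space.config.value_mode == "binary"
    for doc in docs:
        grams = extract_ngrams(doc, space.config)
        for gram, count in grams.items():
            idx = space.index.get(gram)
            if idx is not None:
                indices.append(idx)
                data.append(1 if binary else count)
        indptr.append(len(indices))
    mat = sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64), np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int32)),
        shape=(len(docs), len(space)))
    mat.sort_indices()
    return mat
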