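"""Sentence-embedding providers for the semantic title-similarity feature.

The semantic feature only needs a mapping from a token sequence to a fixed
dimension vector; which embedding model supplies it is a deployment choice,
so providers are pluggable.  Two are shipped:

* :class:`WordTableEmbeddingProvider` — mean of per-token vectors read from a
  plain-text word-vector table (word2vec text format: optional count/dim
  header, then ``token v1 v2 ...`` per line).
* :class:`HashingEmbeddingProvider` — a deterministic, training-free provider
  that draws each token's unit vector from a hash of the token.  Sentences
  sharing tokens get correlated vectors, which is the property the feature
  exploits; used as the default when no table is configured and as the test
  fixture provider.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np


@runtime_checkable
class EmbeddingProvider(Protocol):
    dimension: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        """Map a token sequence to a vector of length ``dimension``.

        Must be deterministic; an empty sequence maps to the zero vector.
        """
        ...


class HashingEmbeddingProvider:
    """Deterministic hash-seeded token vectors, mean-pooled over a sentence."""

    def __init__(self, dimension: int = 64):
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        key = token.lower()
        vec = self._cache.get(key)
        if vec is None:
            digest = hashlib.sha256(key.encode("utf-8")).digest()
            rng = np.random.Generator(np.random.PCG64(
                int.from_bytes(digest[:8], "little")))
            vec = rng.standard_normal(self.dimension)
            vec /= np.linalg.norm(vec)
            self._cache[key] = vec
        return vec

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros(self.dimension)
        return np.mean([self._token_vector(t) for t in tokens], axis=0)


class WordTableEmbeddingProvider:
    """Mean of per-token vectors from a word -> vector lookup table."""

    def __init__(self, table: dict[str, np.ndarray], dimension: int):
        self.table = {k.lower(): np.asarray(v, dtype=float) for k, v in table.items()}
        self.dimension = dimension
        for word, vec in self.table.items():
            if vec.shape != (dimension,):
                raise ValueError(
                    f"vector for {word!r} has shape {vec.shape}, "
                    f"expected ({dimension},)")

    @classmethod
    def from_text_file(cls, path: str | Path) -> "WordTableEmbeddingProvider":
        table: dict[str, np.ndarray] = {}
        dimension: int | None = None
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().rstrip("\n")
            parts = first.split()
            # word2vec text format may open with a "count dim" header line
            if len(parts) == 2 and all(p.isdigit() for p in parts):
                dimension = int(parts[1])
            elif parts:
                table[parts[0]] = np.array([float(x) for x in parts[1:]])
                dimension = len(parts) - 1
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                vec = np.array([float(x) for x in parts[1:]])
                if dimension is None:
                    dimension = vec.size
                table[parts[0]] = vec
        if not table or not dimension:
            raise ValueError(f"{path}: empty embedding table")
        return cls(table, dimension)

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        vecs = [self.table[t.lower()] for t in tokens if t.lower() in self.table]
        if not vecs:
            return np.zeros(self.dimension)
        return np.mean(vecs, axis=0)
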