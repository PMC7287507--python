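"""Title-to-sentence similarity: shared word n-grams and embedding cosine.

The lexical feature counts exact word n-grams (n = 8 down to 1) shared by the
title and an abstract sentence, greedily longest-first: each matched n-gram
contributes n**2 to the score and its tokens are removed from both sequences
before shorter n-grams are sought, so no token is credited twice.  A stop-word
list is applied only before single-word comparison, so shared function words
and ubiquitous terms do not inflate the score.

Example: a title and sentence sharing only the 5-gram "injection of bovine
vaccine into" score 5*5 = 25.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingProvider

MAX_N = 8


def load_stop_words(path: str | Path | None = None) -> frozenset[str]:
    """Load a one-term-per-line stop-word list (default: packaged list)."""
    if path is None:
        text = (importlib.resources.files("mainfinder.data") / "stopwords.txt"
                ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = {line.strip().lower() for line in text.splitlines()
             if line.strip() and not line.startswith("#")}
    return frozenset(words)


@dataclass
class NgramScore:
    """Summed n*n lexical similarity, with the matched spans kept for audit."""

    value: int
    matches: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.value == sum(n * n for n, _ in self.matches)


def ngram_similarity(title_tokens: Sequence[str],
                     sentence_tokens: Sequence[str],
                     stop_words: frozenset[str] = frozenset()) -> NgramScore:
    """Greedy longest-first shared-n-gram score between title and sentence.

    Matching is case-insensitive.  For n from 8 down to 2, the sentence is
    scanned left-to-right for an n-gram also present in the title (leftmost
    title occurrence); the match adds n**2 and its tokens are removed from
    both sequences, splitting them into fragments that later n-grams may not
    bridge.  At n = 1, stop words are removed from both sides and every
    remaining shared word adds 1 (with multiset multiplicity, i.e. repeated
    matching with removal).
    """
    if not title_tokens:
        raise ValueError("title token list is empty")
    if not sentence_tokens:
        raise ValueError("sentence token list is empty")
    title_frags = [[t.lower() for t in title_tokens]]
    sent_frags = [[t.lower() for t in sentence_tokens]]
    matches: list[tuple[int, tuple[str, ...]]] = []

    for n in range(MAX_N, 1, -1):
        while True:
            found = _find_match(sent_frags, title_frags, n)
            if found is None:
                break
            (si, sj), (ti, tj), gram = found
            matches.append((n, gram))
            _remove(sent_frags, si, sj, n)
            _remove(title_frags, ti, tj, n)

    sent_left = [t for frag in sent_frags for t in frag if t not in stop_words]
    title_left = [t for frag in title_frags for t in frag if t not in stop_words]
    title_counts: dict[str, int] = {}
    for t in title_left:
        title_counts[t] = title_counts.get(t, 0) + 1
    for t in sent_left:
        if title_counts.get(t, 0) > 0:
            title_counts[t] -= 1
            matches.append((1, (t,)))

    return NgramScore(value=sum(n * n for n, _ in matches), matches=matches)


def _find_match(sent_frags: list[list[str]], title_frags: list[list[str]],
                n: int):
    """Leftmost sentence n-gram that occurs in the title, with its positions."""
    for si, sfrag in enumerate(sent_frags):
        for sj in range(len(sfrag) - n + 1):
            gram = tuple(sfrag[sj:sj + n])
            for ti, tfrag in enumerate(title_frags):
                for tj in range(len(tfrag) - n + 1):
                    if tuple(tfrag[tj:tj + n]) == gram:
                        return (si, sj), (ti, tj), gram
    return None


def _remove(frags: list[list[str]], fi: int, start: int, n: int) -> None:
    frag = frags[fi]
    left, right = frag[:start], frag[start + n:]
    repl = [p for p in (left, right) if p]
    frags[fi:fi + 1] = repl


def semantic_similarity(title_tokens: Sequence[str],
                        sentence_tokens: Sequence[str],
                        provider: EmbeddingProvider,
                        stop_words: frozenset[str] = frozenset()) -> float:
    """Cosine similarity between stop-word-filtered title and sentence vectors.

    Returns 0.0 when either filtered sequence embeds to the zero vector.
    """
    t_toks = [t for t in title_tokens if t.lower() not in stop_words]
    s_toks = [t for t in sentence_tokens if t.lower() not in stop_words]
    v1 = np.asarray(provider.embed(t_toks), dtype=float)
    v2 = np.asarray(provider.embed(s_toks), dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(
            f"provider returned mismatched dimensions {v1.shape} vs {v2.shape}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
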