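"""Abstract-level decision rules over per-sentence probabilities.

An abstract may state its main finding in zero, one or several sentences.
Sentences scoring above an upper threshold (default 0.9) are accepted
outright; those below a lower threshold (default 0.1) are rejected.  For the
mid-range the rules are: if any sentence was already accepted, predict no
further sentences; otherwise predict the single highest-scoring sentence.
An abstract whose sentences all score below the lower threshold yields no
prediction.

Titles occasionally bear no relation to the main finding; when no sentence
reaches a semantic title similarity of 0.15, the title-similarity features
are uninformative and a reduced 3-feature model (patterns, word lists,
location) scores the abstract instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotatedCorpus, Document
from .embeddings import EmbeddingProvider
from .model import ModelArtifact, predict_proba
from .normalize import ApplyMode
from .similarity import semantic_similarity

DEFAULT_LOWER = 0.1
DEFAULT_UPPER = 0.9
DEFAULT_SIM_FLOOR = 0.15


@dataclass
class AbstractPrediction:
    probabilities: np.ndarray
    predicted_indices: set[int]
    used_fallback: bool = False
    thresholds: tuple[float, float] = (DEFAULT_LOWER, DEFAULT_UPPER)

    def as_records(self, doc_id: str) -> list[dict]:
        return [
            {"doc_id": doc_id, "sent_index": i, "probability": float(p),
             "predicted": i in self.predicted_indices,
             "used_fallback": self.used_fallback}
            for i, p in enumerate(self.probabilities)
        ]


def decide_indices(probabilities: Sequence[float], lower: float = DEFAULT_LOWER,
                   upper: float = DEFAULT_UPPER) -> set[int]:
    """Apply the threshold rules to a probability vector.

    Ties at the mid-range argmax break toward the earliest sentence.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.size == 0:
        return set()
    accepted = {int(i) for i in np.flatnonzero(probs > upper)}
    if accepted:
        return accepted
    if bool((probs < lower).all()):
        return set()
    return {int(np.argmax(probs))}


def predict_abstract(document: Document, artifact: ModelArtifact,
                     fallback_artifact: ModelArtifact | None = None,
                     lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER,
                     sim_floor: float = DEFAULT_SIM_FLOOR,
                     provider: EmbeddingProvider | None = None,
                     mode: ApplyMode = "frozen",
                     tagger: Callable | None = None) -> AbstractPrediction:
    """Predict which sentence(s) of one abstract state the main finding."""
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError(f"thresholds ({lower}, {upper}) must satisfy "
                         "0 <= lower < upper <= 1")
    if provider is None:
        raise ValueError("an embedding provider is required")
    if not document.sentences:
        return AbstractPrediction(np.empty(0), set(), False, (lower, upper))

    used_fallback = False
    chosen = artifact
    if fallback_artifact is not None:
        sims = [semantic_similarity(document.title_tokens, s.tokens, provider,
                                    artifact.stop_words)
                for s in document.sentences if s.tokens]
        if not sims or max(sims) < sim_floor:
            chosen = fallback_artifact
            used_fallback = True
    probs = predict_proba(chosen, document, provider, mode, tagger)
    indices = decide_indices(probs, lower, upper)
    return AbstractPrediction(probs, indices, used_fallback, (lower, upper))


def predict_corpus(corpus: AnnotatedCorpus, artifact: ModelArtifact,
                   fallback_artifact: ModelArtifact | None,
                   provider: EmbeddingProvider,
                   lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER,
                   sim_floor: float = DEFAULT_SIM_FLOOR,
                   mode: ApplyMode = "frozen",
                   tagger: Callable | None = None,
                   ) -> dict[str, AbstractPrediction]:
    return {
        doc.doc_id: predict_abstract(doc, artifact, fallback_artifact, lower,
                                     upper, sim_floor, provider, mode, tagger)
        for doc in corpus
    }


def sweep_thresholds(corpus: AnnotatedCorpus, artifact: ModelArtifact,
                     fallback_artifact: ModelArtifact | None,
                     lower_grid: Sequence[float], upper_grid: Sequence[float],
                     provider: EmbeddingProvider,
                     sim_floor: float = DEFAULT_SIM_FLOOR,
                     mode: ApplyMode = "frozen") -> pd.DataFrame:
    """Sentence-level metrics for every (lower, upper) threshold pair.

    Probabilities are computed once per abstract and re-thresholded, so a
    grid sweep costs one prediction pass.  Pairs with lower >= upper are
    skipped with a warning.
    """
    from .evaluate import sentence_metrics

    base = predict_corpus(corpus, artifact, fallback_artifact, provider,
                          mode=mode, sim_floor=sim_floor)
    rows = []
    for lo in lower_grid:
        for up in upper_grid:
            if lo >= up:
                warnings.warn(f"skipping invalid threshold pair ({lo}, {up})")
                continue
            pred, gold = [], []
            for doc in corpus:
                indices = decide_indices(base[doc.doc_id].probabilities, lo, up)
                for sent in doc.sentences:
                    pred.append(1 if sent.index in indices else 0)
                    gold.append(1 if corpus.is_positive(doc.doc_id, sent.index)
                                else 0)
            m = sentence_metrics(pred, gold)
            rows.append({"lower": lo, "upper": up, "accuracy": m["accuracy"],
                         "precision": m["precision"], "recall": m["recall"],
                         "f1": m["f1"]})
    return pd.DataFrame(rows)
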