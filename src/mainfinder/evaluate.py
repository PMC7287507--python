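"""Evaluation: sentence- and abstract-level metrics, baselines, error tags.

Sentence-level metrics follow the usual confusion-table definitions —
accuracy (Tp+Tn)/N, precision Tp/(Tp+Fp), recall Tp/(Tp+Fn), F1 = 2PR/(P+R)
— plus AUC over the raw probabilities.  Abstract-level accuracy is Ta/Na:
the fraction of abstracts whose predicted positive set consists of gold
positive sentences (an abstract with no gold finding counts as correct only
when nothing is predicted; when the gold finding spans two adjacent
sentences, predicting either one counts as correct with the miss tallied
separately as a partial).

Five single-sentence baselines give the comparison floor: first sentence,
last sentence, random sentence, longest sentence, and highest n-gram title
similarity.
"""

from __future__ import annotations

import random
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .abstract_level import AbstractPrediction
from .corpus import AnnotatedCorpus, Document
from .similarity import ngram_similarity

BASELINE_KINDS = ("first", "last", "random", "longest", "title_ngram")


@dataclass
class EvaluationReport:
    sentence_level: dict[str, float]
    abstract_level: dict[str, float]
    confusion: dict[str, int]
    error_categories: Counter = field(default_factory=Counter)

    def to_dict(self) -> dict:
        return {"sentence_level": self.sentence_level,
                "abstract_level": self.abstract_level,
                "confusion": self.confusion,
                "error_categories": dict(self.error_categories)}


def sentence_metrics(predicted: Sequence[int], gold: Sequence[int]
                     ) -> dict[str, float]:
    """Confusion-table metrics over binary per-sentence predictions."""
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(gold, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    tp = int(((pred == 1) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    n = len(pred)
    accuracy = (tp + tn) / n if n else 0.0
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no gold positives; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "tp": tp, "tn": tn, "fp": fp, "fn": fn}


def auc(gold: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC with midrank tie handling."""
    return float(roc_auc_score(np.asarray(gold, dtype=int),
                               np.asarray(scores, dtype=float)))


def _adjacent_groups(indices: set[int]) -> list[set[int]]:
    """Group gold positive indices into runs of adjacent sentences."""
    groups: list[set[int]] = []
    for idx in sorted(indices):
        if groups and idx - 1 in groups[-1]:
            groups[-1].add(idx)
        else:
            groups.append({idx})
    return groups


def _abstract_correct(predicted: set[int], gold: set[int]) -> bool:
    if not gold:
        return not predicted
    if not predicted:
        return False
    # every predicted sentence must belong to a gold finding; for a finding
    # spanning adjacent sentences, hitting any of its sentences suffices
    return predicted <= gold


def abstract_accuracy(predictions: dict[str, AbstractPrediction],
                      gold: AnnotatedCorpus,
                      include_no_finding: bool = True) -> float:
    """Fraction of abstracts whose prediction matches the gold finding.

    ``include_no_finding=False`` restricts the denominator to abstracts that
    have at least one gold main-finding sentence.
    """
    correct = 0
    total = 0
    for doc in gold:
        if doc.doc_id not in predictions:
            raise KeyError(f"no prediction for document {doc.doc_id!r}")
        gold_pos = gold.positive_indices(doc.doc_id)
        if not gold_pos and not include_no_finding:
            continue
        total += 1
        if _abstract_correct(predictions[doc.doc_id].predicted_indices,
                             gold_pos):
            correct += 1
    return correct / total if total else 0.0


def evaluate_predictions(predictions: dict[str, AbstractPrediction],
                         gold: AnnotatedCorpus) -> EvaluationReport:
    """Full report: sentence metrics + AUC, abstract accuracy, error tags."""
    pred_flat, gold_flat, scores = [], [], []
    for doc in gold:
        pred = predictions[doc.doc_id]
        for sent in doc.sentences:
            pred_flat.append(1 if sent.index in pred.predicted_indices else 0)
            gold_flat.append(1 if gold.is_positive(doc.doc_id, sent.index)
                             else 0)
            scores.append(float(pred.probabilities[sent.index])
                          if sent.index < len(pred.probabilities) else 0.0)
    sm = sentence_metrics(pred_flat, gold_flat)
    sl = {k: sm[k] for k in ("accuracy", "precision", "recall", "f1")}
    if len(set(gold_flat)) == 2:
        sl["auc"] = auc(gold_flat, scores)
    report = EvaluationReport(
        sentence_level=sl,
        abstract_level={
            "accuracy": abstract_accuracy(predictions, gold),
            "accuracy_with_finding_only": abstract_accuracy(
                predictions, gold, include_no_finding=False),
        },
        confusion={k: sm[k] for k in ("tp", "tn", "fp", "fn")},
        error_categories=categorize_errors(predictions, gold),
    )
    return report


def categorize_errors(predictions: dict[str, AbstractPrediction],
                      gold: AnnotatedCorpus) -> Counter:
    """Tally machine-checkable abstract-level error categories."""
    cats: Counter = Counter()
    for doc in gold:
        pred = predictions[doc.doc_id].predicted_indices
        gold_pos = gold.positive_indices(doc.doc_id)
        if _abstract_correct(pred, gold_pos):
            if gold_pos and len(_adjacent_groups(gold_pos)) == 1 \
                    and len(gold_pos) > 1 and pred < gold_pos:
                cats["adjacent_partial"] += 1
            continue
        if not gold_pos and pred:
            cats["no_gold_but_predicted"] += 1
        elif gold_pos and not pred:
            cats["gold_but_none_predicted"] += 1
        elif gold_pos and pred and not pred & gold_pos:
            cats["wrong_sentence_predicted"] += 1
        else:
            cats["partial_overlap"] += 1
    return cats


# ----------------------------------------------------------------------
# Baselines
# ----------------------------------------------------------------------

def _baseline_choice(doc: Document, kind: str, rng: random.Random,
                     stop_words: frozenset[str]) -> int:
    n = len(doc.sentences)
    if kind == "first":
        return 0
    if kind == "last":
        return n - 1
    if kind == "random":
        return rng.randrange(n)
    if kind == "longest":
        lengths = [len(s.tokens) for s in doc.sentences]
        return int(np.argmax(lengths))
    if kind == "title_ngram":
        scores = [ngram_similarity(doc.title_tokens, s.tokens, stop_words).value
                  if s.tokens else -1
                  for s in doc.sentences]
        return int(np.argmax(scores))
    raise ValueError(f"unknown baseline {kind!r}; choose from {BASELINE_KINDS}")


def run_baseline(corpus: AnnotatedCorpus, kind: str, seed: int = 0,
                 stop_words: frozenset[str] = frozenset()) -> EvaluationReport:
    """Evaluate a single-sentence-per-abstract baseline predictor."""
    rng = random.Random(seed)
    predictions: dict[str, AbstractPrediction] = {}
    for doc in corpus:
        if not doc.sentences:
            predictions[doc.doc_id] = AbstractPrediction(np.empty(0), set())
            continue
        choice = _baseline_choice(doc, kind, rng, stop_words)
        probs = np.zeros(len(doc.sentences))
        probs[choice] = 1.0
        predictions[doc.doc_id] = AbstractPrediction(probs, {choice})
    return evaluate_predictions(predictions, corpus)
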