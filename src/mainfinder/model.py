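"""Sentence-level classification: feature assembly, training, CV.

Each sentence is represented by nine coordinates: the log-normalized n-gram
title similarity, the raw embedding cosine (already bounded), the
log-normalized frequent-pattern score, the linearly normalized differential
word score, and the five location indicators.  Six classifier configurations
are supported (two SVM kernels, nu-SVM, logistic regression, a one-hidden-
layer perceptron with 150 units, and a random forest), all emitting class-1
probabilities.  A reduced "fallback" representation drops the two title-
similarity coordinates for abstracts whose title carries no usable signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, NuSVC

from .corpus import AnnotatedCorpus, Document
from .embeddings import EmbeddingProvider
from .location import document_locations, encode_location
from .normalize import ApplyMode, NormalizerState, linear_normalize, log_normalize
from .patterns import PatternTable, score_patterns, score_word_frequency
from .similarity import ngram_similarity, semantic_similarity

FeatureSubset = Literal["full", "fallback"]
CVScheme = Literal["tenfold", "half_split_x10"]

N_FEATURES = 9
FULL_COLUMNS = tuple(range(N_FEATURES))
# fallback drops the n-gram and semantic title-similarity coordinates
FALLBACK_COLUMNS = (2, 3, 4, 5, 6, 7, 8)

CLASSIFIER_KINDS = ("svc_linear", "svc_rbf", "nu_svc", "logistic_regression",
                    "mlp", "random_forest")


def make_classifier(kind: str, seed: int | None = None,
                    y: np.ndarray | None = None):
    """Instantiate one of the six supported classifier configurations.

    For ``nu_svc`` the nominal ``nu = 0.5`` is clamped to the largest value
    feasible for the class balance of ``y`` (libsvm requires
    ``nu <= 2 * min(n_pos, n_neg) / n``, which an imbalanced sentence corpus
    violates); a warning reports the clamped value.
    """
    if kind == "svc_linear":
        return SVC(C=1.0, kernel="linear", probability=True, tol=1e-3,
                   class_weight=None, random_state=seed)
    if kind == "svc_rbf":
        return SVC(C=1.0, kernel="rbf", degree=3, gamma="auto", coef0=0.0,
                   shrinking=True, probability=True, tol=1e-3,
                   class_weight=None, random_state=seed)
    if kind == "nu_svc":
        nu = 0.5
        if y is not None:
            counts = np.bincount(np.asarray(y, dtype=int))
            minority_frac = counts.min() / counts.sum()
            if nu > minority_frac:
                # libsvm feasibility requires nu <= 2*minority_frac; fits at
                # the boundary are numerically fragile, so clamp to half of it
                nu = float(minority_frac)
                warnings.warn(f"nu=0.5 infeasible for this class balance; "
                              f"clamped to {nu:.3f}")
        return NuSVC(nu=nu, kernel="rbf", degree=3, gamma="auto", coef0=0.0,
                     shrinking=True, probability=True, tol=1e-3,
                     class_weight=None, random_state=seed)
    if kind == "logistic_regression":
        return LogisticRegression(penalty="l2", dual=False, tol=1e-4, C=1.0,
                                  fit_intercept=True, solver="liblinear",
                                  max_iter=100, random_state=seed)
    if kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(150,), activation="relu",
                             solver="adam", alpha=1e-4, learning_rate="constant",
                             learning_rate_init=1e-3, max_iter=200,
                             random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, criterion="gini",
                                      max_depth=None, max_features=None,
                                      random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; "
                     f"choose one of {CLASSIFIER_KINDS}")


@dataclass
class FeatureNormalizer:
    """Per-column normalizer states for the raw 9-column feature matrix."""

    f1_state: NormalizerState | None = None
    f3_state: NormalizerState | None = None
    f4_state: NormalizerState | None = None

    def fit_transform(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.array(X_raw, dtype=float, copy=True)
        X[:, 0], self.f1_state = log_normalize(X[:, 0])
        X[:, 2], self.f3_state = log_normalize(X[:, 2])
        X[:, 3], self.f4_state = linear_normalize(X[:, 3])
        return X

    def transform(self, X_raw: np.ndarray, mode: ApplyMode = "frozen"
                  ) -> np.ndarray:
        if self.f1_state is None:
            raise RuntimeError("normalizer has not been fitted")
        X = np.array(X_raw, dtype=float, copy=True)
        if X.size == 0:
            return X
        X[:, 0] = self.f1_state.apply(X[:, 0], mode)
        X[:, 2] = self.f3_state.apply(X[:, 2], mode)
        X[:, 3] = self.f4_state.apply(X[:, 3], mode)
        return X


def featurize_document(doc: Document, table: PatternTable,
                       provider: EmbeddingProvider,
                       stop_words: frozenset[str],
                       tagger: Callable | None = None) -> np.ndarray:
    """Raw (unnormalized) 9-column feature rows for every sentence of a doc."""
    rows = []
    locations = document_locations(doc)
    for sent, loc in zip(doc.sentences, locations):
        if sent.tokens:
            f1 = float(ngram_similarity(doc.title_tokens, sent.tokens,
                                        stop_words).value)
            f2 = semantic_similarity(doc.title_tokens, sent.tokens, provider,
                                     stop_words)
        else:
            f1, f2 = 0.0, 0.0
        f3 = score_patterns(sent, table, tagger)
        f4 = score_word_frequency(sent, table)
        rows.append(np.concatenate([[f1, f2, f3, f4], encode_location(loc)]))
    return np.array(rows).reshape(len(rows), N_FEATURES)


def build_feature_matrix(corpus: AnnotatedCorpus, table: PatternTable,
                         provider: EmbeddingProvider,
                         stop_words: frozenset[str],
                         tagger: Callable | None = None,
                         ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """One raw feature row and binary label per sentence of the corpus."""
    blocks, labels, keys = [], [], []
    for doc in corpus:
        if doc.sentences:
            blocks.append(featurize_document(doc, table, provider, stop_words,
                                             tagger))
        for sent in doc.sentences:
            labels.append(1 if corpus.is_positive(doc.doc_id, sent.index) else 0)
            keys.append((doc.doc_id, sent.index))
    X = (np.vstack(blocks) if blocks
         else np.empty((0, N_FEATURES)))
    return X, np.array(labels, dtype=int), keys


@dataclass
class ModelArtifact:
    """A trained sentence scorer plus everything needed to featurize new text."""

    classifier_kind: str
    estimator: object
    normalizer: FeatureNormalizer
    table: PatternTable
    stop_words: frozenset[str]
    feature_subset: FeatureSubset = "full"
    meta: dict = field(default_factory=dict)

    @property
    def columns(self) -> tuple[int, ...]:
        return FULL_COLUMNS if self.feature_subset == "full" else FALLBACK_COLUMNS

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        artifact = joblib.load(path)
        if not isinstance(artifact, cls):
            raise TypeError(f"{path} does not contain a ModelArtifact")
        return artifact


def train(X_raw: np.ndarray, y: np.ndarray, classifier_kind: str, seed: int,
          table: PatternTable | None = None,
          stop_words: frozenset[str] = frozenset(),
          feature_subset: FeatureSubset = "full") -> ModelArtifact:
    """Fit normalizers and a classifier on a raw feature matrix."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    normalizer = FeatureNormalizer()
    X = normalizer.fit_transform(np.asarray(X_raw, dtype=float))
    cols = FULL_COLUMNS if feature_subset == "full" else FALLBACK_COLUMNS
    est = make_classifier(classifier_kind, seed=seed % (2**31), y=y)
    est.fit(X[:, cols], y)
    return ModelArtifact(classifier_kind, est, normalizer,
                         table if table is not None else PatternTable([]),
                         frozenset(stop_words), feature_subset,
                         meta={"seed": seed, "n_train": int(len(y))})


def predict_proba(artifact: ModelArtifact, document: Document,
                  provider: EmbeddingProvider,
                  mode: ApplyMode = "frozen",
                  tagger: Callable | None = None) -> np.ndarray:
    """Main-finding probability for every sentence of a document."""
    if not document.sentences:
        return np.empty(0)
    X_raw = featurize_document(document, artifact.table, provider,
                               artifact.stop_words, tagger)
    X = artifact.normalizer.transform(X_raw, mode)
    return artifact.estimator.predict_proba(X[:, artifact.columns])[:, 1]


def _fold_metrics(y_true: np.ndarray, probs: np.ndarray) -> dict[str, float]:
    preds = (probs >= 0.5).astype(int)
    return {
        "auc": float(roc_auc_score(y_true, probs)),
        "accuracy": float(accuracy_score(y_true, preds)),
        "precision": float(precision_score(y_true, preds, zero_division=0)),
        "recall": float(recall_score(y_true, preds, zero_division=0)),
        "f1": float(f1_score(y_true, preds, zero_division=0)),
    }


def cross_validate(X_raw: np.ndarray, y: np.ndarray, classifier_kind: str,
                   scheme: CVScheme = "tenfold", seed: int = 0,
                   feature_subset: FeatureSubset = "full") -> dict[str, float]:
    """Cross-validated sentence-level metrics.

    ``tenfold`` is stratified 10-fold CV; ``half_split_x10`` repeats a random
    half/half train-test split ten times.  Normalizers are fitted on each
    training fold and applied frozen to its test fold.  Returns the mean of
    AUC, accuracy, precision, recall and F1 over folds.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 20:
        raise ValueError("need at least 20 rows for cross-validation")
    seed = seed % (2**31)
    if scheme == "tenfold":
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    elif scheme == "half_split_x10":
        splitter = StratifiedShuffleSplit(n_splits=10, test_size=0.5,
                                          random_state=seed)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    cols = FULL_COLUMNS if feature_subset == "full" else FALLBACK_COLUMNS
    per_fold: list[dict[str, float]] = []
    for k, (tr, te) in enumerate(splitter.split(X_raw, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            warnings.warn(f"fold {k}: a class is absent; fold skipped")
            continue
        normalizer = FeatureNormalizer()
        X_tr = normalizer.fit_transform(X_raw[tr])
        X_te = normalizer.transform(X_raw[te], mode="frozen")
        est = make_classifier(classifier_kind, seed=seed + k, y=y[tr])
        est.fit(X_tr[:, cols], y[tr])
        probs = est.predict_proba(X_te[:, cols])[:, 1]
        per_fold.append(_fold_metrics(y[te], probs))
    if not per_fold:
        raise ValueError("no usable folds")
    summary = {m: float(np.mean([f[m] for f in per_fold]))
               for m in per_fold[0]}
    summary["n_folds"] = len(per_fold)
    return summary


def fit_pipeline(corpus: AnnotatedCorpus, classifier_kind: str, seed: int,
                 provider: EmbeddingProvider,
                 stop_words: frozenset[str],
                 table: PatternTable | None = None,
                 tagger: Callable | None = None,
                 ) -> tuple[ModelArtifact, ModelArtifact]:
    """Mine (if needed), featurize, and train the main + fallback models."""
    from .patterns import mine_pattern_table
    if table is None:
        table = mine_pattern_table(corpus, tagger)
    X_raw, y, _ = build_feature_matrix(corpus, table, provider, stop_words,
                                       tagger)
    main = train(X_raw, y, classifier_kind, seed, table, stop_words, "full")
    fallback = train(X_raw, y, classifier_kind, seed, table, stop_words,
                     "fallback")
    return main, fallback
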