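"""Feature-score normalization onto [0, 1].

Two rules are used.  The linear rule rescales by the training range,
``(score - smin) / (smax - smin)``, and suits scores that can be negative
(the differential word-list feature).  The log rule,
``k * log(factor * score + 1)`` with ``k = 1 / log(vmax + 1)``, compresses
the heavy right tails of the n-gram and frequent-pattern scores; ``factor``
flips an all-negative score vector positive before the log is taken.

When a fitted normalizer is applied to new data it can either recompute
``vmax`` from the new scores (per-dataset mode, which makes outputs relative
to the dataset at hand) or keep the training ``vmax`` and clip (frozen mode,
needed for meaningful single-abstract prediction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

ApplyMode = Literal["frozen", "per_dataset"]


@dataclass
class NormalizerState:
    kind: Literal["linear", "log"]
    smin: float = 0.0
    smax: float = 0.0
    vmax: float = 0.0
    factor: float = 1.0
    degenerate: bool = False

    def apply(self, scores: Sequence[float],
              mode: ApplyMode = "frozen") -> np.ndarray:
        """Normalize new scores with this fitted state."""
        arr = np.asarray(scores, dtype=float)
        if arr.size == 0:
            return arr
        if self.kind == "linear":
            if self.degenerate:
                return np.zeros_like(arr)
            out = (arr - self.smin) / (self.smax - self.smin)
            return np.clip(out, 0.0, 1.0)
        if self.degenerate:
            return np.zeros_like(arr)
        vmax = self.vmax
        if mode == "per_dataset":
            new_vmax = float(np.max(self.factor * arr))
            if new_vmax > 0:
                vmax = new_vmax
        k = 1.0 / math.log(vmax + 1.0)
        out = k * np.log(np.maximum(self.factor * arr, 0.0) + 1.0)
        return np.clip(out, 0.0, 1.0)


def linear_normalize(scores: Sequence[float]) -> tuple[np.ndarray, NormalizerState]:
    """Fit and apply range normalization; all-equal input degenerates to zeros."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one score")
    smin, smax = float(arr.min()), float(arr.max())
    if smax == smin:
        warnings.warn("all scores equal; linear normalization degenerates "
                      "to zeros")
        state = NormalizerState("linear", smin=smin, smax=smax, degenerate=True)
        return np.zeros_like(arr), state
    state = NormalizerState("linear", smin=smin, smax=smax)
    return (arr - smin) / (smax - smin), state


def log_normalize(scores: Sequence[float]) -> tuple[np.ndarray, NormalizerState]:
    """Fit and apply log compression; the maximum score maps to 1, zero to 0.

    An all-negative score vector is flipped by ``factor = -1`` first; mixed
    signs are rejected (route such features to the linear rule instead).  An
    all-zero vector degenerates to zeros with a warning.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one score")
    has_neg, has_pos = bool((arr < 0).any()), bool((arr > 0).any())
    if has_neg and has_pos:
        raise ValueError("log normalization requires scores of a single sign")
    factor = -1.0 if has_neg else 1.0
    values = factor * arr
    vmax = float(values.max())
    if vmax <= 0.0:
        warnings.warn("all scores are zero; log normalization degenerates "
                      "to zeros")
        state = NormalizerState("log", factor=factor, vmax=0.0, degenerate=True)
        return np.zeros_like(arr), state
    k = 1.0 / math.log(vmax + 1.0)
    state = NormalizerState("log", factor=factor, vmax=vmax)
    return k * np.log(values + 1.0), state
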