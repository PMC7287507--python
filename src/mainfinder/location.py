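"""Positional feature: five sentence-location categories, one-hot encoded.

Main findings cluster at the edges of an abstract, so each sentence is
assigned one of five categories — first, second, middle, second-to-last,
last — from its own position in an unstructured abstract, or from its
section's position in a structured one.  Positions can overlap (the only
sentence of a one-sentence abstract is both first and last); overlaps are
resolved by the fixed priority ranking first > second > last >
second-to-last > middle, so every sentence gets exactly one category.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .corpus import Document


class LocationCategory(str, Enum):
    FIRST = "first"
    SECOND = "second"
    MIDDLE = "middle"
    SECOND_TO_LAST = "second_to_last"
    LAST = "last"


# Index order of the one-hot encoding (middle is the third coordinate).
CATEGORY_ORDER = (LocationCategory.FIRST, LocationCategory.SECOND,
                  LocationCategory.MIDDLE, LocationCategory.SECOND_TO_LAST,
                  LocationCategory.LAST)


def assign_location(index: int, unit_count: int,
                    section_index: int | None = None) -> LocationCategory:
    """Categorize a sentence by position, resolving overlaps by priority.

    ``unit_count`` is the number of sentences (unstructured) or sections
    (structured); for structured abstracts pass the sentence's
    ``section_index`` and every sentence inherits its section's category.
    """
    pos = index if section_index is None else section_index
    if not 0 <= pos < unit_count:
        raise IndexError(f"position {pos} out of range for {unit_count} units")
    if pos == 0:
        return LocationCategory.FIRST
    if pos == 1:
        return LocationCategory.SECOND
    if pos == unit_count - 1:
        return LocationCategory.LAST
    if pos == unit_count - 2:
        return LocationCategory.SECOND_TO_LAST
    return LocationCategory.MIDDLE


def encode_location(category: LocationCategory) -> np.ndarray:
    """One-hot indicator vector over the five categories."""
    vec = np.zeros(5)
    vec[CATEGORY_ORDER.index(category)] = 1.0
    return vec


def document_locations(doc: Document) -> list[LocationCategory]:
    """Location category for every sentence of a document."""
    n = doc.n_units
    out = []
    for sent in doc.sentences:
        sec = doc.section_of.get(sent.index) if doc.is_structured else None
        out.append(assign_location(sent.index, n, sec))
    return out
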