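"""Discriminative pattern mining and scoring (frequent patterns, word lists).

Items are selected from an annotated corpus by their *discriminative ratio*:

    ratio = (I_mf / N_mf) / (I_os / N_os)

where I_mf / I_os count the main-finding / other sentences containing the
item and N_mf / N_os are the class sizes.  Three pattern subtypes feed the
frequent-patterns feature — string patterns (single words and ``w1 * w2``
gap patterns), syntactic ``we + verb`` pairs, and sentence-initial trigrams —
each kept only with ratio > 2.  The differential word lists feed a separate
feature: words with >= 25 occurrences in the negative sentence set and ratio
> 2 (positive list) or < 0.5 (negative list), excluding words already used by
a frequent pattern.

A sentence's frequent-pattern score is the sum of the ratios of the items it
contains (each item once); its word-frequency score adds each contained
positive word's ratio and subtracts each contained negative word's 1/ratio,
again counting every word at most once.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from .corpus import AnnotatedCorpus, Sentence

Subtype = Literal["string", "syntactic", "first_trigram",
                  "word_positive", "word_negative"]

FEATURE3_SUBTYPES = ("string", "syntactic", "first_trigram")
WORD_SUBTYPES = ("word_positive", "word_negative")

# Surface verb forms that plausibly head a "we + verb" reporting pattern;
# used by the positional detection mode in lieu of a dependency parse.
_VERB_LEXICON = frozenset("""
report reports reported present presents presented describe describes
described discuss discusses discussed show shows showed demonstrate
demonstrates demonstrated found find propose proposed suggest suggested
observe observed review reviewed examine examined evaluate evaluated
performed conclude concluded highlight highlighted identify identified
treat treated diagnose diagnosed encountered managed admitted saw
""".split())


@dataclass(frozen=True)
class PatternItem:
    subtype: Subtype
    pattern: str | tuple[str, str]
    ratio: float

    def __post_init__(self) -> None:
        if self.subtype == "word_negative":
            if not self.ratio < 0.5:
                raise ValueError(
                    f"word_negative item {self.pattern!r} requires ratio < 0.5")
        elif self.ratio <= 2.0 and not math.isinf(self.ratio):
            raise ValueError(
                f"{self.subtype} item {self.pattern!r} requires ratio > 2")

    @property
    def pattern_str(self) -> str:
        if isinstance(self.pattern, tuple):
            return "+".join(self.pattern)
        return self.pattern


@dataclass
class PatternTable:
    """Mined items grouped by subtype, with mining provenance."""

    items: list[PatternItem]
    provenance: str = ""
    _by_subtype: dict[str, list[PatternItem]] = field(default_factory=dict,
                                                      repr=False)

    def __post_init__(self) -> None:
        self._by_subtype = {}
        for item in self.items:
            self._by_subtype.setdefault(item.subtype, []).append(item)
        feat3_words = _feature3_words(self.by_subtypes(FEATURE3_SUBTYPES))
        for item in self.by_subtypes(WORD_SUBTYPES):
            if item.pattern in feat3_words:
                raise ValueError(
                    f"word item {item.pattern!r} duplicates a frequent-pattern word")

    def by_subtype(self, subtype: str) -> list[PatternItem]:
        return self._by_subtype.get(subtype, [])

    def by_subtypes(self, subtypes: Iterable[str]) -> list[PatternItem]:
        return [it for st in subtypes for it in self.by_subtype(st)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subtype\tpattern\tratio\n")
            for item in self.items:
                fh.write(f"{item.subtype}\t{item.pattern_str}\t{item.ratio!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "PatternTable":
        items: list[PatternItem] = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            if header != "subtype\tpattern\tratio":
                raise ValueError(f"{path}: unexpected pattern-table header")
            for ln, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    subtype, pattern_s, ratio_s = line.split("\t")
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: expected 3 columns") from exc
                pattern: str | tuple[str, str]
                if subtype == "syntactic":
                    pronoun, verb = pattern_s.split("+", 1)
                    pattern = (pronoun, verb)
                else:
                    pattern = pattern_s
                items.append(PatternItem(subtype, pattern, float(ratio_s)))  # type: ignore[arg-type]
        return cls(items, provenance=provenance or str(path))


def _feature3_words(items: Iterable[PatternItem]) -> set[str]:
    words: set[str] = set()
    for item in items:
        if isinstance(item.pattern, tuple):
            words.update(item.pattern)
        else:
            words.update(w for w in item.pattern.split() if w != "*")
    return words


# ----------------------------------------------------------------------
# Discriminative ratio
# ----------------------------------------------------------------------

def discriminative_ratio(pos_hits: int, n_pos: int,
                         neg_hits: int, n_neg: int) -> float:
    """Relative item frequency in positives over its frequency in negatives."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    if neg_hits == 0:
        warnings.warn("item never occurs in negative sentences; "
                      "ratio is +infinity")
        return math.inf
    return (pos_hits / n_pos) / (neg_hits / n_neg)


# ----------------------------------------------------------------------
# Matching
# ----------------------------------------------------------------------

def _sentence_text(sentence: Sentence | Sequence[str]) -> str:
    tokens = sentence.tokens if isinstance(sentence, Sentence) else sentence
    return " ".join(t.lower() for t in tokens)


def matches_string(pattern: str, sentence: Sentence | Sequence[str]) -> bool:
    """Case-insensitive containment; ``*`` matches any words in between."""
    text = _sentence_text(sentence)
    parts = pattern.lower().split()
    if "*" in parts:
        regex = r"\b" + r"\b.+\b".join(re.escape(p) for p in parts if p != "*") + r"\b"
    else:
        regex = r"\b" + r"\s+".join(re.escape(p) for p in parts) + r"\b"
    return re.search(regex, text) is not None


def first_trigram(sentence: Sentence | Sequence[str]) -> str | None:
    tokens = sentence.tokens if isinstance(sentence, Sentence) else list(sentence)
    if len(tokens) < 3:
        return None
    return " ".join(t.lower() for t in tokens[:3])


def we_verb_pairs(sentence: Sentence | Sequence[str],
                  tagger: Callable[[Sequence[str]], Sequence[str]] | None = None,
                  window: int = 4) -> set[tuple[str, str]]:
    """Detect ``("we", verb)`` pairs in a sentence.

    With a ``tagger`` (tokens -> POS tags), every VB*-tagged token after a
    PRP-tagged "we" pairs with it.  Without one (positional mode), the nearest
    following token found in a reporting-verb lexicon within ``window`` tokens
    is taken as the verb; if none qualifies, the immediately following token
    is used, since reporting cues place the verb right after the pronoun.
    The verb is kept as its surface form (no lemmatization).
    """
    tokens = sentence.tokens if isinstance(sentence, Sentence) else list(sentence)
    low = [t.lower() for t in tokens]
    pairs: set[tuple[str, str]] = set()
    if tagger is not None:
        tags = list(tagger(tokens))
        for i, tok in enumerate(low):
            if tok == "we" and tags[i].startswith("PRP"):
                for j in range(i + 1, len(low)):
                    if tags[j].startswith("VB"):
                        pairs.add(("we", low[j]))
        return pairs
    for i, tok in enumerate(low):
        if tok != "we":
            continue
        verb = None
        for j in range(i + 1, min(i + 1 + window, len(low))):
            if low[j] in _VERB_LEXICON:
                verb = low[j]
                break
        if verb is None and i + 1 < len(low):
            verb = low[i + 1]
        if verb is not None:
            pairs.add(("we", verb))
    return pairs


def item_matches(item: PatternItem, sentence: Sentence | Sequence[str],
                 tagger: Callable[[Sequence[str]], Sequence[str]] | None = None,
                 ) -> bool:
    if item.subtype == "string":
        return matches_string(item.pattern, sentence)  # type: ignore[arg-type]
    if item.subtype == "syntactic":
        return tuple(item.pattern) in we_verb_pairs(sentence, tagger)
    if item.subtype == "first_trigram":
        return first_trigram(sentence) == item.pattern
    if item.subtype in WORD_SUBTYPES:
        tokens = (sentence.tokens if isinstance(sentence, Sentence)
                  else list(sentence))
        return item.pattern in {t.lower() for t in tokens}
    raise ValueError(f"unknown subtype {item.subtype!r}")


# ----------------------------------------------------------------------
# Mining
# ----------------------------------------------------------------------

def _split_sentences(corpus: AnnotatedCorpus
                     ) -> tuple[list[Sentence], list[Sentence]]:
    pos: list[Sentence] = []
    neg: list[Sentence] = []
    for doc, sent, label in corpus.iter_sentences():
        (pos if label != "other" else neg).append(sent)
    if not pos or not neg:
        raise ValueError("corpus must contain both positive and negative "
                         "sentences")
    return pos, neg


def _ratio_filter(counts: dict, pos: list[Sentence], neg: list[Sentence],
                  subtype: Subtype, min_ratio: float) -> list[PatternItem]:
    items = []
    for pattern, (ph, nh) in counts.items():
        ratio = discriminative_ratio(ph, len(pos), nh, len(neg))
        if math.isinf(ratio):
            # a finite discriminative ratio cannot be estimated and the item
            # would make downstream scores unbounded
            warnings.warn(f"{subtype} item {pattern!r} never occurs in "
                          "negative sentences; dropped")
            continue
        if ratio > min_ratio:
            items.append(PatternItem(subtype, pattern, ratio))
    items.sort(key=lambda it: (-it.ratio, str(it.pattern)))
    return items


def mine_string_patterns(corpus: AnnotatedCorpus,
                         min_pos_frac: float = 0.10,
                         min_ratio: float = 2.0) -> list[PatternItem]:
    """Mine single words and ``w1 * w2`` gap patterns.

    Candidates are all single tokens occurring in more than ``min_pos_frac``
    of positive sentences, plus gap patterns over ordered pairs of such
    frequent tokens; survivors must exceed ``min_ratio``.
    """
    pos, neg = _split_sentences(corpus)
    tok_pos = Counter()
    for s in pos:
        tok_pos.update({t.lower() for t in s.tokens})
    floor = min_pos_frac * len(pos)
    frequent = [t for t, c in tok_pos.items() if c > floor]

    candidates: list[str] = sorted(frequent)
    for w1 in frequent:
        for w2 in frequent:
            if w1 == w2:
                continue
            n_ordered = sum(1 for s in pos
                            if _ordered_pair_in(w1, w2, s.tokens))
            if n_ordered > floor:
                candidates.append(f"{w1} * {w2}")

    counts: dict[str, list[int]] = {}
    for pattern in candidates:
        ph = sum(1 for s in pos if matches_string(pattern, s))
        if ph <= floor:
            continue
        nh = sum(1 for s in neg if matches_string(pattern, s))
        counts[pattern] = [ph, nh]
    return _ratio_filter(counts, pos, neg, "string", min_ratio)


def _ordered_pair_in(w1: str, w2: str, tokens: Sequence[str]) -> bool:
    low = [t.lower() for t in tokens]
    try:
        i = low.index(w1)
    except ValueError:
        return False
    return w2 in low[i + 1:]


def mine_syntactic_patterns(corpus: AnnotatedCorpus,
                            tagger: Callable[[Sequence[str]], Sequence[str]] | None = None,
                            min_ratio: float = 2.0,
                            min_pos_count: int = 2) -> list[PatternItem]:
    """Mine ``("we", verb)`` pairs whose discriminative ratio exceeds the floor."""
    pos, neg = _split_sentences(corpus)
    counts: dict[tuple[str, str], list[int]] = {}
    for sentences, slot in ((pos, 0), (neg, 1)):
        for s in sentences:
            try:
                pairs = we_verb_pairs(s, tagger)
            except Exception as exc:  # tagger failure: sentence has no pattern
                warnings.warn(f"tagger failed on sentence {s.index}: {exc}")
                continue
            for pair in pairs:
                counts.setdefault(pair, [0, 0])[slot] += 1
    counts = {p: c for p, c in counts.items() if c[0] >= min_pos_count}
    return _ratio_filter(counts, pos, neg, "syntactic", min_ratio)


def mine_first_trigrams(corpus: AnnotatedCorpus,
                        min_ratio: float = 2.0,
                        min_pos_count: int = 2) -> list[PatternItem]:
    """Mine sentence-initial trigrams over-represented in positives."""
    pos, neg = _split_sentences(corpus)
    counts: dict[str, list[int]] = {}
    for sentences, slot in ((pos, 0), (neg, 1)):
        for s in sentences:
            tri = first_trigram(s)
            if tri is not None:
                counts.setdefault(tri, [0, 0])[slot] += 1
    counts = {p: c for p, c in counts.items() if c[0] >= min_pos_count}
    return _ratio_filter(counts, pos, neg, "first_trigram", min_ratio)


def mine_word_lists(corpus: AnnotatedCorpus,
                    feature3_items: Sequence[PatternItem],
                    min_neg_count: int = 25,
                    pos_ratio: float = 2.0,
                    neg_ratio: float = 0.5) -> list[PatternItem]:
    """Mine the differential positive/negative word lists.

    Words (no stemming, no stop list) contained in at least ``min_neg_count``
    negative sentences and absent from the frequent-pattern items are split
    into a positive list (ratio > 2) and a negative list (ratio < 0.5).
    """
    pos, neg = _split_sentences(corpus)
    excluded = _feature3_words(feature3_items)
    pos_counts: Counter = Counter()
    neg_counts: Counter = Counter()
    for s in pos:
        pos_counts.update({t.lower() for t in s.tokens})
    for s in neg:
        neg_counts.update({t.lower() for t in s.tokens})
    items: list[PatternItem] = []
    for word, nh in neg_counts.items():
        if nh < min_neg_count or word in excluded:
            continue
        ratio = discriminative_ratio(pos_counts.get(word, 0), len(pos),
                                     nh, len(neg))
        if math.isinf(ratio):
            warnings.warn(f"word {word!r} never occurs in negative sentences; "
                          "dropped")
        elif ratio > pos_ratio:
            items.append(PatternItem("word_positive", word, ratio))
        elif ratio < neg_ratio:
            if ratio == 0.0:
                # never seen in positives: the reciprocal penalty is undefined
                warnings.warn(f"word {word!r} never occurs in positive "
                              "sentences; dropped")
                continue
            items.append(PatternItem("word_negative", word, ratio))
    items.sort(key=lambda it: (it.subtype, -it.ratio, str(it.pattern)))
    return items


def mine_pattern_table(corpus: AnnotatedCorpus,
                       tagger: Callable[[Sequence[str]], Sequence[str]] | None = None,
                       provenance: str = "mined") -> PatternTable:
    """Run all four miners and assemble one consistent table."""
    feat3 = (mine_string_patterns(corpus)
             + mine_syntactic_patterns(corpus, tagger)
             + mine_first_trigrams(corpus))
    words = mine_word_lists(corpus, feat3)
    return PatternTable(feat3 + words, provenance=provenance)


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def score_patterns(sentence: Sentence | Sequence[str], table: PatternTable,
                   tagger: Callable[[Sequence[str]], Sequence[str]] | None = None,
                   ) -> float:
    """Sum the ratios of all frequent-pattern items contained in the sentence.

    Each item counts at most once regardless of how often it matches.
    """
    score = 0.0
    for item in table.by_subtypes(FEATURE3_SUBTYPES):
        if item_matches(item, sentence, tagger):
            score += item.ratio
    return score


def score_word_frequency(sentence: Sentence | Sequence[str],
                         table: PatternTable,
                         negative_mode: Literal["reciprocal", "direct"] = "reciprocal",
                         ) -> float:
    """Differential word-list score: + positive ratios, - negative penalties.

    Every listed word is counted at most once per sentence.  A matched
    negative word subtracts 1/ratio (its penalty exceeds 2 since stored
    ratios are < 0.5); ``negative_mode="direct"`` subtracts the stored ratio
    itself instead.
    """
    tokens = (sentence.tokens if isinstance(sentence, Sentence)
              else list(sentence))
    present = {t.lower() for t in tokens}
    score = 0.0
    for item in table.by_subtype("word_positive"):
        if item.pattern in present:
            score += item.ratio
    for item in table.by_subtype("word_negative"):
        if item.pattern in present:
            score -= (1.0 / item.ratio) if negative_mode == "reciprocal" else item.ratio
    return score
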