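# Methods

## Problem and model

`mainfinder` treats main-finding identification as supervised sentence
classification followed by abstract-level decision rules.  The underlying
assumptions are those that hold for clinical case reports: the title states
the main finding concisely in the large majority of articles, the abstract
repeats it in one or two sentences, and those sentences carry distinctive
reporting cues ("we report", "to report a").  Both annotated main-finding
sentences and "alternative" main-finding sentences (a second sentence that
at least one annotator accepted) are positive examples; everything else in
the abstract is negative.  No class rebalancing is applied — the natural
imbalance (roughly one positive per 7–13 sentences) is part of the problem.

## Features

| # | Feature | Range (raw) | Normalization |
|---|---------|-------------|---------------|
| 1 | shared-n-gram title similarity, Σ n² for n = 8…1 | 0 … ~200 | log |
| 2 | embedding cosine of title vs sentence | [−1, 1] | none |
| 3 | Σ discriminative ratios of matched frequent patterns | ≥ 0 | log |
| 4 | Σ positive-word ratios − Σ 1/negative-word ratios | any sign | linear |
| 5 | location category (first/second/middle/second-to-last/last) | one-hot | none |

**Feature 1.** Greedy longest-first matching: for n from 8 down to 2 the
sentence is scanned left to right, each shared n-gram adds n² and is removed
from both sequences (removal splits the sequences into fragments that later
matches may not bridge); at n = 1 a stop-word list is applied first and each
remaining shared word adds 1 with multiset multiplicity.  The leftmost
tie-break makes the scorer deterministic; when equal-length candidate
matches overlap, a different choice order can occasionally score higher, so
the scorer is validated two ways: exact equality against an independent
brute-force implementation of the same deterministic procedure, and an
upper-bound check against a DFS over all longest-first choice sequences.
Shared runs longer than 8 are consumed as an 8-gram plus remainder.  Stop
words are retained for n ≥ 2: the list exists to stop ubiquitous single
words from inflating the score, whereas a shared longer phrase is evidence
even when built from frequent words.

The shipped stop-word list (`mainfinder/data/stopwords.txt`, ~290 terms) is
a reconstruction covering English function words plus high-frequency PubMed
title/abstract terms ("report", "case", "patients", …); any one-term-per-line
file can replace it.

**Feature 2.** The embedding model is a provider interface (token sequence →
fixed-dimension vector).  The default when no word-vector table is supplied
is a hashing provider: each token's unit vector is drawn deterministically
from a hash of the token and a sentence is the mean of its token vectors.
This makes the cosine a smooth function of token overlap — adequate for the
pipeline's mechanics and fully reproducible, but it cannot see synonymy; for
production use, load a biomedical word-embedding table
(`WordTableEmbeddingProvider.from_text_file`, word2vec text format).

**Feature 3.** Three pattern subtypes are mined from the annotated corpus
and filtered by discriminative ratio > 2: string patterns (single tokens
occurring in > 10 % of positive sentences, plus `w1 * w2` gap patterns over
ordered pairs of such tokens), `we + verb` pairs, and sentence-initial
trigrams.  Sentence scoring sums the ratios of matched items, each item
counted once per sentence (symmetric with Feature 4's explicit
once-per-sentence rule).  Verb detection accepts a pluggable POS tagger
(any VB*-tagged token after a PRP-tagged "we" pairs with it); the default
positional mode takes the nearest following token from a reporting-verb
lexicon within four tokens, falling back to the immediately following token.
Verbs are kept as surface forms — no stemming or lemmatization anywhere.

**Feature 4.** Word candidates need ≥ 25 occurrences in the negative
sentence set (sentence-level containment counts, consistent with the
ratio's definition) and must not reuse a word already present in a Feature-3
item.  Ratio > 2 puts a word on the positive list (adds its ratio); ratio
< 0.5 puts it on the negative list (subtracts 1/ratio, so penalties exceed
2).  A config switch (`negative_mode="direct"`) subtracts the stored ratio
instead, preserving the alternative reading of the scoring formula; the
reciprocal mode is the default because it reproduces the canonical worked
example (8.45) from the printed per-word contributions.

**Feature 5.** Unstructured abstracts use the sentence's own position;
structured abstracts (≥ 2 labelled sections in PubMed XML) assign every
sentence its section's position.  Overlapping categories resolve by the
priority first > second > last > second-to-last > middle, applied literally:
a one-sentence abstract is "first", and the trailing sentence of a
two-sentence abstract is "second", not "last".  The model receives one-hot
indicators; per-position discriminative ratios are available descriptively
in the evaluation module but are not model inputs.

## Mining edge cases

Items that never occur in negative sentences have an infinite ratio and are
dropped with a warning (no finite discriminative ratio can be estimated and
downstream scores would be unbounded); negative-list words that never occur
in positive sentences have ratio 0 and an undefined reciprocal penalty and
are likewise dropped.  `discriminative_ratio` itself returns the +inf
sentinel with a warning so callers can decide.  Syntactic and trigram
miners additionally require an item to appear in ≥ 2 positive sentences
(`min_pos_count`), operationalizing "most common" without affecting the
stated floors.

## Normalization

The log rule `k·log(factor·score + 1)`, `k = 1/log(vmax + 1)` maps 0 → 0 and
the maximum training score → 1 while compressing heavy right tails; `factor`
flips an all-negative vector, and mixed-sign vectors are rejected (the
word-frequency feature, which can be negative, is routed to the linear rule
for exactly this reason).  Applying a fitted normalizer to new data supports
two modes: `per_dataset` recomputes `vmax` from the new scores (scores
become dataset-relative), and `frozen` keeps the training `vmax` and clips
to [0, 1].  Frozen is the default everywhere a single abstract is scored —
with per-dataset scaling a one-abstract input would always push its own
maximum to 1.  Cross-validation fits normalizers on each training fold and
applies them frozen to the test fold, avoiding leakage.  Degenerate inputs
(all-equal for linear, all-zero for log) normalize to zeros with a warning
rather than erroring, so a constant feature column cannot abort a fold.

## Classifiers and validation

Six configurations: SVC linear kernel, SVC RBF, nu-SVC, logistic regression
(liblinear, L2, C = 1), MLP with one 150-unit hidden layer (adam, ≤ 200
epochs), and a 100-tree random forest (`max_features=None`).  SVMs use
Platt-calibrated probabilities (`probability=True`).  nu-SVC's nominal
nu = 0.5 is infeasible for imbalanced data (libsvm requires
nu ≤ 2·min(n₊,n₋)/n), so nu is clamped to the minority-class fraction —
half the feasible bound, which reduces to 0.5 on balanced data; fits at the
boundary itself are numerically fragile.  All estimator seeds derive from
the single run seed.

Two CV schemes are provided: stratified 10-fold (the default reported
scheme) and ten repeats of a random half/half split; per-fold sentence
predictions are thresholded at 0.5 for accuracy/precision/recall/F1, and
AUC is computed on the raw probabilities with midrank tie handling.

## Abstract-level rules

Thresholds (0.1, 0.9): probability > 0.9 accepts a sentence outright
(several may be accepted), < 0.1 rejects it; if nothing was accepted and not
everything rejected, the single argmax sentence is predicted, ties breaking
to the earliest index.  An abstract abstains iff every sentence scores below
the lower threshold.  The fallback applies when no sentence reaches
semantic title similarity 0.15: a separately trained 3-feature model
(patterns, word lists, location) — trained on the reduced representation,
not the full model with columns zeroed — scores the abstract instead.

Abstract-level accuracy counts an abstract correct when its predicted set is
non-empty and contained in the gold positive set, or when both are empty
(correct rejection); when a finding spans two adjacent gold sentences,
hitting either counts as correct and the miss is tallied separately as a
partial.  Both denominators (all abstracts; only abstracts with a gold
finding) are reported.

## Synthetic data: what it does and does not show

The generator emulates the signal structure the pipeline exploits, with
defaults fixed once: 200 documents; titles of 8–14 vocabulary words; 4–9
filler sentences per abstract plus exactly one planted main-finding sentence
(as in a training corpus where every abstract has one) at a uniformly random
position, opening with a cue phrase and containing a verbatim 5-token title
span; 10 % of positives get only a 2-token span (titles that barely echo the
finding); 30 % of abstracts get a 3-token distractor span in a filler (so
title similarity alone is fallible); 5 % cue leakage into fillers (so mined
ratios are finite); positive marker words on 80 % of positives and negative
marker words on 50 % of fillers with 5 % cross-class leakage (signal for the
word-list feature).

Passing tests on this corpus demonstrate that mining recovers planted
frequencies exactly, that every classifier can exploit the engineered
features, and that the decision rules and baselines behave as designed.
They do not demonstrate performance on real abstracts: the generator plants
verbatim overlap (no paraphrase), a closed vocabulary, no structured
abstracts, and no annotator noise, which is why the synthetic problem is
nearly separable (CV AUC ≈ 1) where real corpora sit nearer AUC 0.9.  One
consequence, documented deliberately: with almost all probabilities at 0/1,
the threshold pair (0.1, 0.95) can edge out the (0.1, 0.9) default by a few
thousandths of F1 — the default's optimality is a property of noisier,
mid-range-heavy score distributions, and the ordering test over perturbed
thresholds is expected to reflect that only in such regimes.

## Known limitations

- Sentence segmentation is rule-based; known failure modes (bullet
  fragments, embedded keyword lines, missing space after a full stop) are
  flagged for opt-in removal (`remove_flagged`, default on in the CLI)
  rather than silently fixed.
- The positional `we + verb` heuristic approximates a dependency parse; a
  real tagger can be plugged in where available.
- The hashing embedding provider measures lexical, not semantic, proximity.
- Pattern tables are corpus-dependent; tables mined from one domain should
  not be assumed to transfer.
- Multi-sentence findings are not modelled jointly; adjacent-pair gold
  findings are handled only at evaluation time.
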