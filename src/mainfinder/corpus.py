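"""Corpus containers and readers for case-report abstracts.

A :class:`Document` is one clinical case report: its identifier (PMID or a
synthetic id), title tokens, and the ordered sentences of its abstract.
Abstracts from PubMed may be *structured* (divided into labelled sections such
as BACKGROUND / CASE / CONCLUSION); for those, each sentence also carries the
ordinal of the section it belongs to, which the location feature uses.

An :class:`AnnotatedCorpus` adds per-sentence gold labels: ``main_finding``,
``alternative_main_finding`` (a second sentence that at least one annotator
considered the main finding) or ``other``.  Both main-finding label kinds are
treated as positive examples by the classifier.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from lxml import etree

LABEL_MAIN = "main_finding"
LABEL_ALT = "alternative_main_finding"
LABEL_OTHER = "other"
POSITIVE_LABELS = frozenset({LABEL_MAIN, LABEL_ALT})
VALID_LABELS = frozenset({LABEL_MAIN, LABEL_ALT, LABEL_OTHER})

# Words, optionally joined by internal hyphens/apostrophes ("71-year-old",
# "patient's"); punctuation is dropped at tokenization time.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'’][A-Za-z0-9]+)*")

# Abbreviations after which a period does not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "fig", "figs", "e.g", "i.e", "vs",
    "et al", "al", "ref", "no", "approx", "ca", "cf", "st", "jr", "sr",
}

_BOUNDARY_RE = re.compile(r"(?<=[.!?])[\)\]\"”’]*\s+(?=[\"“(\[]?[A-Z0-9•])")


def word_tokenize(text: str) -> list[str]:
    """Split text into word tokens, preserving case and dropping punctuation."""
    return _TOKEN_RE.findall(text)


@dataclass
class Sentence:
    """One abstract sentence: raw text, its word tokens and 0-based position."""

    raw_text: str
    tokens: list[str]
    index: int
    flagged: bool = False

    @classmethod
    def from_text(cls, text: str, index: int) -> "Sentence":
        return cls(raw_text=text, tokens=word_tokenize(text), index=index,
                   flagged=is_problematic(text))


@dataclass
class Document:
    doc_id: str
    title_text: str
    title_tokens: list[str]
    sentences: list[Sentence]
    is_structured: bool = False
    # sentence index -> section ordinal (structured abstracts only)
    section_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.title_tokens:
            raise ValueError(f"document {self.doc_id!r} has an empty title")
        for idx in self.section_of:
            if not 0 <= idx < len(self.sentences):
                raise ValueError(
                    f"document {self.doc_id!r}: section_of index {idx} out of range")

    @property
    def n_units(self) -> int:
        """Number of position units: sections if structured, else sentences."""
        if self.is_structured and self.section_of:
            return max(self.section_of.values()) + 1
        return len(self.sentences)


def is_problematic(text: str) -> bool:
    """Flag sentence fragments produced by known segmentation failure modes.

    Catches bullet fragments, embedded keyword lines, and run-together text
    where a full stop is not followed by a space.
    """
    stripped = text.strip()
    if "•" in stripped:
        return True
    if re.match(r"(?i)^key\s?words?\b", stripped):
        return True
    if re.search(r"[a-z]\.[A-Z]", stripped):
        return True
    return False


def segment_abstract(text: str) -> list[Sentence]:
    """Split abstract text into ordered :class:`Sentence` objects.

    Rule-based segmentation: a sentence ends at ``.``, ``!`` or ``?`` followed
    by whitespace and an upper-case/digit start, except after common
    abbreviations.  Sentences matching known failure modes are flagged
    (``Sentence.flagged``) for optional removal rather than silently dropped.
    """
    if not text or not text.strip():
        return []
    pieces: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        candidate = text[start:match.start() + 1]
        tail = candidate.rstrip(".!?”\"')]").rsplit(None, 1)
        last_word = tail[-1].lower().rstrip(".") if tail else ""
        if last_word in _ABBREVIATIONS:
            continue
        pieces.append(candidate.strip())
        start = match.end()
    rest = text[start:].strip()
    if rest:
        pieces.append(rest)
    return [Sentence.from_text(p, i) for i, p in enumerate(pieces) if p]


@dataclass
class AnnotatedCorpus:
    """Documents plus per-sentence gold labels keyed by (doc_id, sent index)."""

    documents: list[Document]
    labels: dict[tuple[str, int], str]

    def __post_init__(self) -> None:
        by_id = {d.doc_id: d for d in self.documents}
        for (doc_id, idx), label in self.labels.items():
            if label not in VALID_LABELS:
                raise ValueError(f"invalid label {label!r}")
            doc = by_id.get(doc_id)
            if doc is None or not 0 <= idx < len(doc.sentences):
                raise ValueError(f"label key ({doc_id!r}, {idx}) has no sentence")

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def label_of(self, doc_id: str, index: int) -> str:
        return self.labels.get((doc_id, index), LABEL_OTHER)

    def is_positive(self, doc_id: str, index: int) -> bool:
        return self.label_of(doc_id, index) in POSITIVE_LABELS

    def positive_indices(self, doc_id: str) -> set[int]:
        return {
            idx for (d, idx), lab in self.labels.items()
            if d == doc_id and lab in POSITIVE_LABELS
        }

    def iter_sentences(self) -> Iterator[tuple[Document, Sentence, str]]:
        for doc in self.documents:
            for sent in doc.sentences:
                yield doc, sent, self.label_of(doc.doc_id, sent.index)

    def remove_flagged(self) -> "AnnotatedCorpus":
        """Drop flagged sentences, reindexing and remapping labels/sections."""
        docs: list[Document] = []
        labels: dict[tuple[str, int], str] = {}
        for doc in self.documents:
            kept: list[Sentence] = []
            section_of: dict[int, int] = {}
            for sent in doc.sentences:
                if sent.flagged:
                    continue
                new_idx = len(kept)
                kept.append(Sentence(sent.raw_text, list(sent.tokens), new_idx,
                                     flagged=False))
                if sent.index in doc.section_of:
                    section_of[new_idx] = doc.section_of[sent.index]
                lab = self.labels.get((doc.doc_id, sent.index))
                if lab is not None:
                    labels[(doc.doc_id, new_idx)] = lab
            docs.append(Document(doc.doc_id, doc.title_text, list(doc.title_tokens),
                                 kept, doc.is_structured, section_of))
        return AnnotatedCorpus(docs, labels)

    # ------------------------------------------------------------------
    # Tabular round-trip.  Schema: doc_id, sent_index, section_index, label,
    # text (UTF-8, tab-separated).  The title travels as sent_index = -1 with
    # label "title"; section_index is empty for unstructured abstracts.
    # ------------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("doc_id\tsent_index\tsection_index\tlabel\ttext\n")
            for doc in self.documents:
                fh.write(f"{doc.doc_id}\t-1\t\ttitle\t{_escape(doc.title_text)}\n")
                for sent in doc.sentences:
                    sec = doc.section_of.get(sent.index)
                    sec_s = "" if sec is None else str(sec)
                    lab = self.label_of(doc.doc_id, sent.index)
                    fh.write(f"{doc.doc_id}\t{sent.index}\t{sec_s}\t{lab}\t"
                             f"{_escape(sent.raw_text)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotatedCorpus":
        docs: dict[str, dict] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("doc_id\t"):
                raise ValueError(f"{path}: missing corpus TSV header")
            for ln, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{ln}: expected 5 columns")
                doc_id, idx_s, sec_s, label, text = parts
                entry = docs.setdefault(
                    doc_id, {"title": None, "sentences": {}, "sections": {},
                             "labels": {}})
                idx = int(idx_s)
                if idx == -1:
                    entry["title"] = _unescape(text)
                else:
                    entry["sentences"][idx] = _unescape(text)
                    if sec_s:
                        entry["sections"][idx] = int(sec_s)
                    if label != LABEL_OTHER:
                        entry["labels"][idx] = label
        documents: list[Document] = []
        labels: dict[tuple[str, int], str] = {}
        for doc_id, entry in docs.items():
            if entry["title"] is None:
                raise ValueError(f"document {doc_id!r} has no title row")
            sents = [Sentence.from_text(entry["sentences"][i], i)
                     for i in sorted(entry["sentences"])]
            documents.append(Document(
                doc_id, entry["title"], word_tokenize(entry["title"]), sents,
                is_structured=bool(entry["sections"]),
                section_of=dict(entry["sections"])))
            for idx, lab in entry["labels"].items():
                labels[(doc_id, idx)] = lab
        return cls(documents, labels)

    def to_json(self, path: str | Path) -> None:
        payload = []
        for doc in self.documents:
            payload.append({
                "doc_id": doc.doc_id,
                "title": doc.title_text,
                "is_structured": doc.is_structured,
                "sentences": [
                    {"sent_index": s.index,
                     "section_index": doc.section_of.get(s.index),
                     "label": self.label_of(doc.doc_id, s.index),
                     "text": s.raw_text}
                    for s in doc.sentences
                ],
            })
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotatedCorpus":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        documents: list[Document] = []
        labels: dict[tuple[str, int], str] = {}
        for rec in payload:
            section_of = {}
            sents = []
            for s in rec["sentences"]:
                sents.append(Sentence.from_text(s["text"], s["sent_index"]))
                if s.get("section_index") is not None:
                    section_of[s["sent_index"]] = s["section_index"]
                if s.get("label", LABEL_OTHER) != LABEL_OTHER:
                    labels[(rec["doc_id"], s["sent_index"])] = s["label"]
            documents.append(Document(
                rec["doc_id"], rec["title"], word_tokenize(rec["title"]),
                sents, rec.get("is_structured", False), section_of))
        return cls(documents, labels)


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


# ----------------------------------------------------------------------
# PubMed XML
# ----------------------------------------------------------------------

def parse_pubmed_xml(source: str | Path | bytes | IO[bytes]) -> list[Document]:
    """Read a PubMed article-set XML file into :class:`Document` objects.

    Extracts PMID, title and abstract text for every ``PubmedArticle``.
    Records lacking an abstract (or a title) are reported via a warning and
    skipped.  A record counts as structured when its abstract carries at least
    two labelled ``AbstractText`` sections; ``section_of`` then maps each
    sentence to the ordinal of the section whose text contains it.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(str(source) if isinstance(source, (str, Path))
                           else source).getroot()
    documents: list[Document] = []
    for art in root.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        pmid = pmid_el.text.strip() if pmid_el is not None and pmid_el.text else None
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        if not title:
            warnings.warn(f"record PMID={pmid}: no title; skipped")
            continue
        sections = art.findall(".//Abstract/AbstractText")
        texts = ["".join(sec.itertext()).strip() for sec in sections]
        texts = [t for t in texts if t]
        if not texts:
            warnings.warn(f"record PMID={pmid or title[:40]}: no abstract; skipped")
            continue
        labelled = sum(1 for sec in sections if sec.get("Label"))
        is_structured = labelled >= 2 and len(texts) >= 2
        sentences: list[Sentence] = []
        section_of: dict[int, int] = {}
        for sec_ord, text in enumerate(texts):
            for sent in segment_abstract(text):
                idx = len(sentences)
                sentences.append(Sentence(sent.raw_text, sent.tokens, idx,
                                          sent.flagged))
                if is_structured:
                    section_of[idx] = sec_ord
        documents.append(Document(
            doc_id=pmid or f"untitled-{len(documents)}",
            title_text=title, title_tokens=word_tokenize(title),
            sentences=sentences, is_structured=is_structured,
            section_of=section_of))
    return documents
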