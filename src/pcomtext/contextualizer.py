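"""Restrict reports to ovary-relevant sentences and split by laterality.

Pelvic ultrasound reports describe several organs (uterus, endometrium,
kidneys, adnexa). Only the sentences that mention an ovary — plus each
immediately following sentence, which in dictated prose elaborates the
same organ — are kept. Those context sentences are then grouped into at
most two per-ovary documents (left and right); sentences describing both
ovaries, or carrying no side cue, appear in both.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from . import volumetry
from .textprep import (
    OVARY_STEM,
    RawReport,
    default_stopwords,
    preprocess_report,
    tokenize_and_stem,
)

__all__ = [
    "OvaryDocument",
    "extract_ovary_context",
    "assign_laterality",
    "build_ovary_documents",
    "build_ovary_corpus",
]

log = logging.getLogger(__name__)

SIDES = ("left", "right")

_LEFT = re.compile(r"\bleft\b")
_RIGHT = re.compile(r"\bright\b")
_PLURAL = re.compile(r"\bovaries\b|\bboth\b")


@dataclass
class OvaryDocument:
    """All text assigned to one ovary of one report.

    ``sentences`` hold cleaned, unstemmed text (the volumetry input);
    ``token_sentences`` hold the stemmed, stopword-free tokens per
    sentence (the term-counting input, n-grams never cross sentences).
    """

    report_id: str
    side: str
    sentences: list[str] = field(default_factory=list)
    token_sentences: list[list[str]] = field(default_factory=list)
    mention_found: bool = False
    dims: volumetry.Dimensions | None = None
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def tokens(self) -> list[str]:
        return [t for sent in self.token_sentences for t in sent]


def _mentions_ovary(tokens: list[str]) -> bool:
    return OVARY_STEM in tokens


def extract_ovary_context(token_sentences: list[list[str]]) -> list[int]:
    """Indices of sentences mentioning an ovary, plus each successor.

    De-duplicated, in original order. Sentences about other organs that
    neither mention an ovary nor follow an ovary sentence are excluded.
    """
    keep: set[int] = set()
    for i, tokens in enumerate(token_sentences):
        if _mentions_ovary(tokens):
            keep.add(i)
            if i + 1 < len(token_sentences):
                keep.add(i + 1)
    return sorted(keep)


def _side_cues(sentence: str) -> tuple[bool, ...]:
    return (
        bool(_LEFT.search(sentence)),
        bool(_RIGHT.search(sentence)),
        bool(_PLURAL.search(sentence)),
    )


def assign_laterality(
    sentences: list[str],
    token_sentences: list[list[str]],
    context: list[int],
    report_id: str = "",
) -> dict[str, OvaryDocument]:
    """Group context sentences into left and right ovary documents.

    A sentence with exactly one of the cues "left"/"right" joins that
    side; both cues, plural "ovaries"/"both", or no cue at all duplicate
    the sentence into both documents. A successor sentence without its
    own cue inherits the side(s) of the ovary sentence it follows; a
    successor that itself mentions the other ovary starts a new context.
    """
    docs = {side: OvaryDocument(report_id=report_id, side=side) for side in SIDES}
    last_sides: tuple[str, ...] = SIDES
    for i in context:
        sent = sentences[i]
        tokens = token_sentences[i]
        left, right, plural = _side_cues(sent)
        if left and not right:
            sides: tuple[str, ...] = ("left",)
        elif right and not left:
            sides = ("right",)
        elif left or right or plural:
            sides = SIDES
        elif _mentions_ovary(tokens):
            sides = SIDES  # ovary sentence with no cue: could be either
        else:
            sides = last_sides  # successor inherits
        if _mentions_ovary(tokens) or left or right:
            last_sides = sides
        for side in sides:
            doc = docs[side]
            doc.sentences.append(sent)
            doc.token_sentences.append(tokens)
            if _mentions_ovary(tokens):
                doc.mention_found = True
    for doc in docs.values():
        if not doc.mention_found:
            doc.sentences = []
            doc.token_sentences = []
    return docs


def build_ovary_documents(
    report: RawReport, stopwords: frozenset[str] | None = None
) -> dict[str, OvaryDocument]:
    """Full per-report pipeline: clean, contextualize, lateralize, measure."""
    clean = preprocess_report(report, stopwords)
    context = extract_ovary_context(clean.token_sentences)
    docs = assign_laterality(
        clean.sentences, clean.token_sentences, context, report.report_id
    )
    for doc in docs.values():
        result = volumetry.ovary_volume(doc.sentences, doc.token_sentences)
        if result is not None:
            doc.dims, doc.volume_ml = result
    return docs


def build_ovary_corpus(
    reports: list[RawReport], stopwords: frozenset[str] | None = None
) -> list[OvaryDocument]:
    """Two OvaryDocuments (left, right) per report, for the whole corpus.

    Reports that fail to construct (e.g. missing report_id) are rejected
    with a logged diagnostic; processing continues.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    corpus: list[OvaryDocument] = []
    for report in reports:
        try:
            docs = build_ovary_documents(report, stopwords)
        except ValueError as exc:
            log.warning("skipping malformed record: %s", exc)
            continue
        corpus.extend(docs[side] for side in SIDES)
    return corpus
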