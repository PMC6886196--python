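"""Text normalization for ultrasound reports.

Raw dictated radiology prose is lowercased, stripped of irregular
characters and punctuation, segmented into sentences, tokenized, and
stemmed. Measurement syntax (``3x3x5 cm``, ``3.5 ml``) survives cleaning
intact because volume extraction runs downstream on the cleaned,
unstemmed sentence text; stemming applies only on the term-counting path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ._snowball import stem as _snowball_stem

__all__ = [
    "RawReport",
    "CleanReport",
    "clean_text",
    "segment_sentences",
    "tokenize_and_stem",
    "stem_token",
    "load_stopwords",
    "default_stopwords",
    "preprocess_report",
    "OVARY_STEM",
]

# Adjectival "ovarian" carries no removable Snowball suffix, yet ovary
# detection must treat noun and adjective as one term; merged post-stem.
_DOMAIN_MERGES = {"ovarian": "ovari"}

OVARY_STEM = "ovari"

# Laterality and negation words must never be treated as stopwords.
_PROTECTED_WORDS = frozenset({"left", "right", "no", "not", "nor", "both"})

_SENTENCE_END = re.compile(r"[.!?;](?=\s|$)")
# keep letters, digits, '.', '-', '/', 'x' glue and sentence terminators
_STRIP_CHARS = re.compile(r"[^a-z0-9.\-/!?; ]+")
_WS = re.compile(r"\s+")
_TOKEN_TRIM = re.compile(r"^[^a-z0-9]+|[^a-z0-9]+$")


@dataclass(frozen=True)
class RawReport:
    """One ultrasound exam: opaque identifier plus raw report text."""

    report_id: str
    text: str
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")


@dataclass
class CleanReport:
    """Normalized report: cleaned sentences with stemmed token lists.

    ``sentence_spans`` are character offsets into the cleaned text (the
    cleaned string, not the raw one, is the unit every downstream stage
    consumes).
    """

    report_id: str
    sentences: list[str]
    token_sentences: list[list[str]]
    sentence_spans: list[tuple[int, int]] = field(default_factory=list)


def clean_text(text: str) -> str:
    """Normalize raw report text.

    Lowercases, maps unicode spaces and ``×`` to ASCII, strips irregular
    characters and non-measurement punctuation, and collapses whitespace.
    Sentence-final punctuation is retained for :func:`segment_sentences`.
    Total function: any string in, a cleaned string out.
    """
    text = text.lower()
    text = text.replace("×", "x")
    # unicode spaces and control characters become plain spaces
    text = "".join(
        " " if (c.isspace() or ord(c) < 32 or ord(c) == 127) else c for c in text
    )
    text = "".join(c for c in text if ord(c) < 128)
    text = _STRIP_CHARS.sub(" ", text)
    text = _WS.sub(" ", text).strip()
    # drop leftover free-standing punctuation runs like " - " or " . "
    text = _WS.sub(" ", re.sub(r"(?<= )[.\-/]+(?= )", " ", f" {text} ")).strip()
    return text


def segment_sentences(text: str) -> list[str]:
    """Split cleaned text into sentences on ``. ! ? ;`` at word ends.

    A period inside a decimal number never terminates a sentence because
    the terminator must be followed by whitespace or end-of-string.
    """
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        end = m.end()
        sent = text[start:end].strip()
        if sent:
            sentences.append(sent)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def segment_with_spans(text: str) -> tuple[list[str], list[tuple[int, int]]]:
    """Like :func:`segment_sentences` but also return (start, end) offsets."""
    sentences: list[str] = []
    spans: list[tuple[int, int]] = []
    start = 0
    boundaries = [m.end() for m in _SENTENCE_END.finditer(text)] + [len(text)]
    for end in boundaries:
        raw = text[start:end]
        sent = raw.strip()
        if sent:
            lead = len(raw) - len(raw.lstrip())
            spans.append((start + lead, start + lead + len(sent)))
            sentences.append(sent)
        start = end
    return sentences, spans


def stem_token(token: str) -> str:
    """Snowball-stem one token, then apply the domain merge table."""
    stemmed = _snowball_stem(token)
    return _DOMAIN_MERGES.get(token, _DOMAIN_MERGES.get(stemmed, stemmed))


def tokenize_and_stem(sentence: str, stopwords: frozenset[str]) -> list[str]:
    """Whitespace-tokenize a cleaned sentence, drop stopwords, stem the rest.

    Stopwords are matched on the raw lowercase token, before stemming.
    Tokens containing digits (measurements) pass through unstemmed.
    """
    tokens: list[str] = []
    for raw in sentence.split():
        tok = _TOKEN_TRIM.sub("", raw) if not any(c.isdigit() for c in raw) else raw.rstrip(".!?;")
        if not tok or tok in stopwords:
            continue
        tokens.append(stem_token(tok))
    return tokens


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a one-word-per-line stopword file; '#' comments allowed.

    Laterality and negation cues (left/right/no/not/nor/both) are always
    excluded, whatever the file says.
    """
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words - _PROTECTED_WORDS)


def default_stopwords() -> frozenset[str]:
    """The stopword list shipped with the package."""
    ref = resources.files("pcomtext.data") / "stopwords.txt"
    with resources.as_file(ref) as path:
        return load_stopwords(path)


def preprocess_report(
    report: RawReport, stopwords: frozenset[str] | None = None
) -> CleanReport:
    """Run the full clean → segment → tokenize/stem pipeline on one report."""
    if stopwords is None:
        stopwords = default_stopwords()
    cleaned = clean_text(report.text)
    sentences, spans = segment_with_spans(cleaned)
    token_sentences = [tokenize_and_stem(s, stopwords) for s in sentences]
    return CleanReport(
        report_id=report.report_id,
        sentences=sentences,
        token_sentences=token_sentences,
        sentence_spans=spans,
    )
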