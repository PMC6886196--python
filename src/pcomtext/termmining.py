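"""Document-term matrices and n-gram association mining.

The per-ovary documents form a corpus; a document-term matrix (DTM)
over stemmed n-grams is the frequency table of every n-gram that occurs
in at least one document. Mining correlates each 2-/3-gram's binary
occurrence indicator with either the large-volume indicator (> 10 ml) —
candidate volume confounders — or with a seed phrase's occurrence —
candidate polycystic-morphology descriptors. Mined candidates are meant
for human curation; the package ships a small curated default list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DocumentTermMatrix",
    "TermList",
    "build_dtm",
    "ngram_volume_associations",
    "seed_phrase_associations",
    "count_term_hits",
    "load_term_lists",
    "default_term_lists",
    "write_term_candidates",
]

log = logging.getLogger(__name__)

NGRAM_SEP = " "


@dataclass
class DocumentTermMatrix:
    """Documents x n-grams count matrix (sparse; absent = 0)."""

    doc_ids: list[str]
    terms: list[str]
    counts: sp.csr_matrix

    def occurrence(self) -> sp.csr_matrix:
        """Binary doc x term occurrence indicator matrix (sparse)."""
        return (self.counts > 0).astype(float)

    def term_sizes(self) -> np.ndarray:
        return np.array([t.count(NGRAM_SEP) + 1 for t in self.terms])


@dataclass
class TermList:
    """Curated n-grams of one category, in stemmed form."""

    category: str  # confounder | pcom_phrase
    terms: list[str] = field(default_factory=list)
    provenance: str = "curated"  # mined | curated | shipped

    def token_tuples(self) -> list[tuple[str, ...]]:
        return [tuple(t.split(NGRAM_SEP)) for t in self.terms]


def _iter_ngrams(token_sentences: list[list[str]], nmin: int, nmax: int):
    """N-grams within (never across) sentence boundaries."""
    for tokens in token_sentences:
        for n in range(nmin, nmax + 1):
            for i in range(len(tokens) - n + 1):
                yield NGRAM_SEP.join(tokens[i : i + n])


def build_dtm(
    docs: dict[str, list[list[str]]], ngram_range: tuple[int, int] = (1, 3)
) -> DocumentTermMatrix:
    """Count n-grams per document.

    ``docs`` maps doc_id to its token sentences. Every n-gram occurring
    at least once in the corpus becomes a column; cell (d, t) is the
    number of occurrences of t in d.
    """
    nmin, nmax = ngram_range
    if not (1 <= nmin <= nmax):
        raise ValueError(f"invalid ngram_range {ngram_range}")
    if not docs:
        raise ValueError("empty corpus: nothing to mine")
    vocab: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    doc_ids = list(docs)
    for r, doc_id in enumerate(doc_ids):
        local: dict[int, int] = {}
        for gram in _iter_ngrams(docs[doc_id], nmin, nmax):
            idx = vocab.setdefault(gram, len(vocab))
            local[idx] = local.get(idx, 0) + 1
        rows.extend([r] * len(local))
        cols.extend(local)
        vals.extend(local.values())
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(doc_ids), len(vocab)), dtype=np.int64
    )
    return DocumentTermMatrix(doc_ids=doc_ids, terms=list(vocab), counts=counts)


def _pointwise_correlations(occ: sp.csr_matrix, y: np.ndarray) -> np.ndarray:
    """Pearson r of each binary occurrence column with y; 0 where constant.

    For a binary column with occurrence rate p, sd = sqrt(p(1-p)) and
    E[xy] = (x . y)/n, so the whole sweep is one sparse matvec.
    """
    n = len(y)
    p = np.asarray(occ.sum(axis=0)).ravel() / n
    ym = y.mean()
    exy = (occ.T @ y) / n
    cov = exy - p * ym
    sx = np.sqrt(p * (1.0 - p))
    sy = y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    if sy == 0:
        r[:] = 0.0
    return r


def _ranked(
    dtm: DocumentTermMatrix,
    y: np.ndarray,
    keep: np.ndarray,
    threshold: float,
    min_df: int,
) -> list[tuple[str, float]]:
    occ = dtm.occurrence()
    df = np.asarray(occ.sum(axis=0)).ravel()
    keep = keep & (df >= min_df)
    r = _pointwise_correlations(occ, y)
    order = np.argsort(-r, kind="stable")
    return [
        (dtm.terms[i], float(r[i]))
        for i in order
        if keep[i] and r[i] >= threshold
    ]


def ngram_volume_associations(
    dtm: DocumentTermMatrix,
    large_volume: np.ndarray,
    n_sizes: tuple[int, ...] = (2, 3),
    threshold: float = 0.1,
    min_df: int = 5,
) -> list[tuple[str, float]]:
    """2-/3-grams whose occurrence correlates with large ovarian volume.

    ``large_volume`` is a boolean per document (documents without an
    extracted volume must already be excluded). Unigrams are skipped by
    default to reduce variance. Returns (term, score) sorted by
    descending Pearson correlation, score >= threshold.
    """
    y = np.asarray(large_volume, dtype=float)
    if len(y) != len(dtm.doc_ids):
        raise ValueError("large_volume length must match number of documents")
    if len(y) < 3:
        raise ValueError("need at least 3 documents with volumes to mine")
    keep = np.isin(dtm.term_sizes(), n_sizes)
    return _ranked(dtm, y, keep, threshold, min_df)


def seed_phrase_associations(
    dtm: DocumentTermMatrix,
    seed: str,
    n_size: int,
    threshold: float = 0.1,
    min_df: int = 5,
) -> list[tuple[str, float]]:
    """N-grams of size ``n_size`` co-occurring with a stemmed seed phrase.

    The seed must be stemmed with the same pipeline as the corpus. A
    seed absent from the corpus yields an empty list with a warning.
    """
    if seed not in dtm.terms:
        log.warning("seed phrase %r absent from corpus; no candidates", seed)
        return []
    j = dtm.terms.index(seed)
    y = (dtm.counts[:, j] > 0).toarray().ravel().astype(float)
    keep = (dtm.term_sizes() == n_size) & (
        np.array(dtm.terms, dtype=object) != seed
    )
    return _ranked(dtm, y, keep, threshold, min_df)


def count_term_hits(token_sentences: list[list[str]], term_list: TermList) -> int:
    """Total occurrences of any list term in a document's token sentences.

    Terms match as contiguous stemmed token runs within a sentence.
    """
    total = 0
    for target in term_list.token_tuples():
        n = len(target)
        for tokens in token_sentences:
            for i in range(len(tokens) - n + 1):
                if tuple(tokens[i : i + n]) == target:
                    total += 1
    return total


def load_term_lists(path: str | Path) -> dict[str, TermList]:
    """Read category/ngram TSV (optional score column, '#' comments)."""
    lists: dict[str, TermList] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed term list line: {line!r}")
        category, ngram = parts[0].strip(), parts[1].strip()
        lists.setdefault(category, TermList(category=category)).terms.append(ngram)
    return lists


def default_term_lists() -> dict[str, TermList]:
    """The curated term lists shipped with the package."""
    ref = resources.files("pcomtext.data") / "default_terms.tsv"
    with resources.as_file(ref) as path:
        lists = load_term_lists(path)
    for tl in lists.values():
        tl.provenance = "shipped"
    return lists


def write_term_candidates(
    path: str | Path, category: str, ranked: list[tuple[str, float]]
) -> None:
    """Write mined candidates for human review (category, ngram, score)."""
    lines = ["# mined candidates for curation\n# category\tngram\tscore"]
    lines += [f"{category}\t{term}\t{score:.4f}" for term, score in ranked]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
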