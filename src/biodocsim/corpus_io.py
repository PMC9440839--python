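"""Corpus, relevance-label and word-vector I/O plus the dataset-construction protocol.

Documents are MEDLINE-like records: an identifier, an abstract, and a set of
MeSH headings.  Relevance labels assign each document to a topic with one of
three classes — DR (definitely relevant), PR (possibly relevant), NR (not
relevant) — mirroring retrieval-track relevance judgments.  Word vectors are read
from the word2vec keyed-vector text format.

File dialects
-------------
corpus (TSV):     doc_id <TAB> abstract <TAB> heading;heading;...
corpus (jsonl):   {"doc_id": ..., "abstract": ..., "headings": [...]}
relevance (TSV):  doc_id <TAB> topic_id <TAB> DR|PR|NR
word vectors:     header "V D", then one "term f1 ... fD" row per term
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_STOPWORDS",
    "DocumentRecord",
    "RelevanceTable",
    "EmbeddingModel",
    "preprocess_text",
    "read_corpus",
    "write_corpus",
    "read_relevance",
    "write_relevance",
    "load_word_vectors",
    "save_word_vectors",
    "filter_topics",
    "sample_datasets",
]

RELEVANCE_CLASSES = ("DR", "PR", "NR")

# Compact English stopword list (function words only); overridable everywhere
# a stopword set is accepted.
DEFAULT_STOPWORDS = frozenset(
    """a about above after again against all am an and any are as at be because
    been before being below between both but by can could did do does doing down
    during each few for from further had has have having he her here hers herself
    him himself his how i if in into is it its itself just me more most my myself
    no nor not now of off on once only or other our ours ourselves out over own
    same she should so some such than that the their theirs them themselves then
    there these they this those through to too under until up very was we were
    what when where which while who whom why will with you your yours yourself
    yourselves""".split()
)

_TOKEN_SPLIT = re.compile(r"[^0-9a-zA-Z]+")


@dataclass(frozen=True)
class DocumentRecord:
    """One biomedical document: id, abstract, preprocessed tokens, MeSH headings."""

    doc_id: str
    abstract: str
    tokens: tuple[str, ...]
    headings: frozenset[str]

    def with_tokens(self, stopwords: frozenset[str]) -> "DocumentRecord":
        return replace(self, tokens=tuple(preprocess_text(self.abstract, stopwords)))


@dataclass
class RelevanceTable:
    """Rows of (doc_id, topic_id, relevance class).

    Before filtering a document may carry judgments for several topics; after
    :func:`filter_topics` every doc_id maps to exactly one topic.
    """

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for doc_id, topic, rel in self.rows:
            if rel not in RELEVANCE_CLASSES:
                raise ValueError(f"unknown relevance class {rel!r} for {doc_id}/{topic}")

    def topics(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, topic, _ in self.rows:
            seen.setdefault(topic, None)
        return list(seen)

    def doc_topics(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for doc_id, topic, _ in self.rows:
            out.setdefault(doc_id, set()).add(topic)
        return out

    def as_mapping(self) -> dict[str, tuple[str, str]]:
        """doc_id -> (topic, relevance); requires single-topic consistency."""
        out: dict[str, tuple[str, str]] = {}
        for doc_id, topic, rel in self.rows:
            if doc_id in out and out[doc_id][0] != topic:
                raise ValueError(f"document {doc_id} maps to multiple topics")
            out[doc_id] = (topic, rel)
        return out


@dataclass
class EmbeddingModel:
    """Keyed word vectors: term -> vector, all of one dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for term, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {term!r} has length {vec.shape}, expected {self.dimension}"
                )

    @property
    def vocabulary(self) -> set[str]:
        return set(self.vectors)

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def __getitem__(self, term: str) -> np.ndarray:
        return self.vectors[term]


def preprocess_text(
    abstract: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS
) -> list[str]:
    """Tokenize an abstract: split on non-alphanumerics, lowercase, drop
    pure-number tokens and stopwords.  Order is preserved."""
    tokens = []
    for raw in _TOKEN_SPLIT.split(abstract):
        if not raw:
            continue
        tok = raw.lower()
        if tok.isdigit() or tok in stopwords:
            continue
        tokens.append(tok)
    return tokens


def _record_from_fields(
    doc_id: str, abstract: str, headings: Iterable[str], stopwords: frozenset[str]
) -> DocumentRecord:
    heads = frozenset(h for h in headings if h)
    return DocumentRecord(
        doc_id=doc_id,
        abstract=abstract,
        tokens=tuple(preprocess_text(abstract, stopwords)),
        headings=heads,
    )


def read_corpus(
    path: str | Path,
    format: str = "tabular",
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> list[DocumentRecord]:
    """Read a corpus file in the TSV ("tabular") or json-lines dialect.

    Tokens are populated with :func:`preprocess_text`.  Raises ``ValueError``
    (naming the line) on malformed rows and on duplicate doc_ids.
    """
    if format not in ("tabular", "json-lines"):
        raise ValueError(f"unknown corpus format {format!r}")
    stopwords = frozenset(stopwords)
    records: list[DocumentRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if format == "tabular":
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
                    )
                doc_id, abstract, head_str = parts
                headings = head_str.split(";") if head_str else []
            else:
                try:
                    obj = json.loads(line)
                    doc_id = obj["doc_id"]
                    abstract = obj["abstract"]
                    headings = obj["headings"]
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(f"{path}: line {lineno}: malformed record: {exc}") from exc
            if doc_id in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            records.append(_record_from_fields(doc_id, abstract, headings, stopwords))
    return records


def write_corpus(records: Sequence[DocumentRecord], path: str | Path, format: str = "tabular") -> None:
    if format not in ("tabular", "json-lines"):
        raise ValueError(f"unknown corpus format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            headings = sorted(rec.headings)
            if format == "tabular":
                fh.write(f"{rec.doc_id}\t{rec.abstract}\t{';'.join(headings)}\n")
            else:
                fh.write(
                    json.dumps(
                        {"doc_id": rec.doc_id, "abstract": rec.abstract, "headings": headings}
                    )
                    + "\n"
                )


def read_relevance(path: str | Path) -> RelevanceTable:
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
            rows.append((parts[0], parts[1], parts[2]))
    return RelevanceTable(rows)


def write_relevance(table: RelevanceTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, topic, rel in table.rows:
            fh.write(f"{doc_id}\t{topic}\t{rel}\n")


def load_word_vectors(path: str | Path, restrict_vocab: set[str] | None = None) -> EmbeddingModel:
    """Read word2vec keyed-vector text format.

    ``restrict_vocab`` keeps memory proportional to the retained vocabulary:
    rows outside the set are parsed and discarded.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}, expected 'V D'")
        n_vectors, dim = int(header[0]), int(header[1])
        n_rows = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            term = parts[0]
            if len(parts) - 1 != dim:
                raise ValueError(
                    f"{path}: line {lineno}: {len(parts) - 1} values for dimension {dim}"
                )
            n_rows += 1
            if restrict_vocab is not None and term not in restrict_vocab:
                continue
            vectors[term] = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
    if n_rows != n_vectors:
        raise ValueError(f"{path}: header promises {n_vectors} rows, found {n_rows}")
    return EmbeddingModel(dimension=dim, vectors=vectors)


def save_word_vectors(model: EmbeddingModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vectors)} {model.dimension}\n")
        for term, vec in model.vectors.items():
            fh.write(term + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def filter_topics(
    corpus: Sequence[DocumentRecord],
    relevance: RelevanceTable,
    min_docs: int = 9,
) -> tuple[list[DocumentRecord], RelevanceTable]:
    """Dataset-construction filter: drop documents judged under two or more
    topics, then drop topics left with ``min_docs`` or fewer documents.

    The result is consistent (every remaining document has exactly one topic)
    and the operation is idempotent.
    """
    if min_docs < 0:
        raise ValueError("min_docs must be >= 0")
    multi = {doc for doc, topics in relevance.doc_topics().items() if len(topics) > 1}
    rows = [r for r in relevance.rows if r[0] not in multi]
    topic_sizes: dict[str, int] = {}
    for _, topic, _ in rows:
        topic_sizes[topic] = topic_sizes.get(topic, 0) + 1
    keep_topics = {t for t, n in topic_sizes.items() if n > min_docs}
    rows = [r for r in rows if r[1] in keep_topics]
    kept_docs = {doc_id for doc_id, _, _ in rows}
    corpus_out = [d for d in corpus if d.doc_id in kept_docs]
    return corpus_out, RelevanceTable(rows)


def sample_datasets(
    topics: Sequence[str],
    n_datasets: int = 100,
    k_min: int = 3,
    k_max: int = 12,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Draw ``n_datasets`` random topic subsets, each of a size drawn uniformly
    from [k_min, k_max], sampled without replacement within a subset."""
    topics = list(topics)
    if k_max > len(topics):
        raise ValueError(f"k_max={k_max} exceeds the {len(topics)} available topics")
    if not (0 < k_min <= k_max):
        raise ValueError("need 0 < k_min <= k_max")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, ...]] = []
    for _ in range(n_datasets):
        k = int(rng.integers(k_min, k_max + 1))
        chosen = rng.choice(len(topics), size=k, replace=False)
        out.append(tuple(topics[i] for i in chosen))
    return out
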