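"""TF-IDF content vectors and cosine content similarity.

tf(t, d) is the raw count of t in d's token list.  Two idf variants:

* ``smooth`` (default): idf(t) = ln((1 + N) / (1 + df(t))) + 1 — never zero,
  no division hazard for unseen terms;
* ``classic``:          idf(t) = ln(N / df(t)).

Document vectors are tf·idf; similarity is the cosine of the two nonnegative
vectors (hence in [0, 1]); a zero vector paired with anything scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .corpus_io import DocumentRecord
from .similarity_matrix import SimilarityMatrix

__all__ = [
    "TfidfModel",
    "fit_tfidf",
    "content_document_similarity",
    "content_similarity_matrix",
]


@dataclass
class TfidfModel:
    """Vocabulary, aligned idf weights, per-document sparse tf·idf vectors."""

    vocabulary: list[str]
    idf: np.ndarray
    doc_vectors: dict[str, sp.csr_matrix]
    df: np.ndarray

    def vector(self, doc_id: str) -> sp.csr_matrix:
        return self.doc_vectors[doc_id]

    def dump_vocabulary(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tdf\tidf\n")
            for term, df, idf in zip(self.vocabulary, self.df, self.idf):
                fh.write(f"{term}\t{int(df)}\t{idf!r}\n")


def fit_tfidf(corpus: Sequence[DocumentRecord], variant: str = "smooth") -> TfidfModel:
    if not corpus:
        raise ValueError("empty corpus")
    if variant not in ("smooth", "classic"):
        raise ValueError(f"unknown idf variant {variant!r}")
    vocab = sorted({tok for doc in corpus for tok in doc.tokens})
    pos = {t: i for i, t in enumerate(vocab)}
    n_docs = len(corpus)

    rows, cols, data = [], [], []
    df = np.zeros(len(vocab))
    for i, doc in enumerate(corpus):
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            counts[pos[tok]] = counts.get(pos[tok], 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            data.append(float(c))
            df[j] += 1
    tf = sp.csr_matrix((data, (rows, cols)), shape=(n_docs, len(vocab)))

    if variant == "smooth":
        idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    else:
        # classic ln(N/df); terms in every doc get idf 0, df is never 0 for
        # vocabulary terms by construction
        idf = np.log(n_docs / df)
    tfidf = tf.multiply(idf).tocsr()
    doc_vectors = {doc.doc_id: tfidf.getrow(i) for i, doc in enumerate(corpus)}
    return TfidfModel(vocabulary=vocab, idf=idf, doc_vectors=doc_vectors, df=df)


def content_document_similarity(c1, c2) -> float:
    """Cosine of two aligned nonnegative tf·idf vectors (sparse rows or dense
    1-D arrays); 0 whenever either vector is zero."""
    if sp.issparse(c1):
        dot = float((c1 @ c2.T).toarray().ravel()[0])
        n1 = math.sqrt(float((c1 @ c1.T).toarray().ravel()[0]))
        n2 = math.sqrt(float((c2 @ c2.T).toarray().ravel()[0]))
    else:
        x = np.asarray(c1, dtype=np.float64).ravel()
        y = np.asarray(c2, dtype=np.float64).ravel()
        if x.shape != y.shape:
            raise ValueError("vectors are not aligned to one vocabulary")
        dot = float(np.dot(x, y))
        n1, n2 = float(np.linalg.norm(x)), float(np.linalg.norm(y))
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return dot / (n1 * n2)


def content_similarity_matrix(
    corpus: Sequence[DocumentRecord], variant: str = "smooth"
) -> SimilarityMatrix:
    """Pairwise Sim_Con; zero-token documents get 0 off-diagonal, 1 on the
    diagonal."""
    model = fit_tfidf(corpus, variant=variant)
    vecs = [model.doc_vectors[d.doc_id] for d in corpus]
    # precomputed norms use the same expression as content_document_similarity,
    # so the matrix path equals the pairwise path exactly
    norms = [math.sqrt(float((v @ v.T).toarray().ravel()[0])) for v in vecs]
    n = len(corpus)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0.0 or norms[j] == 0.0:
                s = 0.0
            else:
                dot = float((vecs[i] @ vecs[j].T).toarray().ravel()[0])
                s = dot / (norms[i] * norms[j])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix([d.doc_id for d in corpus], values)
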