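"""Word-embedding document similarity.

A document's average semantic vector (ASV) is the mean of its in-vocabulary
token vectors (token multiplicity counts; out-of-vocabulary tokens are
skipped), Z-score normalized across its own components:

    x'_i = (x_i - mean(x)) / sd(x)        (population sd)

Document similarity is the cosine of two normalized ASVs.  Cosine can be
negative; the matrix builder maps evidences into [0, 1] under a selectable
policy (clip negatives to 0 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import DocumentRecord, EmbeddingModel
from .similarity_matrix import (
    DegenerateVectorError,
    SimilarityMatrix,
    UndefinedEvidenceError,
)

__all__ = [
    "AverageSemanticVector",
    "average_semantic_vector",
    "embedding_document_similarity",
    "embedding_similarity_matrix",
]

NEGATIVE_POLICIES = ("clip", "shift", "raw")


@dataclass
class AverageSemanticVector:
    """Z-scored mean word vector of a document; ``in_vocab_count`` is the
    number of token occurrences found in the embedding vocabulary."""

    values: np.ndarray
    in_vocab_count: int


def average_semantic_vector(
    tokens: Sequence[str], model: EmbeddingModel
) -> AverageSemanticVector:
    if model.dimension < 2:
        raise ValueError("embedding dimension must be >= 2 for Z-score normalization")
    acc = np.zeros(model.dimension)
    count = 0
    for tok in tokens:
        vec = model.vectors.get(tok)
        if vec is not None:
            acc += vec
            count += 1
    if count == 0:
        raise UndefinedEvidenceError("no token of the document is in the embedding vocabulary")
    mean_vec = acc / count
    mu = float(mean_vec.mean())
    sigma = float(mean_vec.std())  # population sd (ddof=0)
    if sigma == 0.0:
        raise DegenerateVectorError("averaged vector is constant; Z-score undefined")
    return AverageSemanticVector(values=(mean_vec - mu) / sigma, in_vocab_count=count)


def embedding_document_similarity(
    a: AverageSemanticVector, a2: AverageSemanticVector
) -> float:
    """Cosine similarity of two ASVs, in [-1, 1]."""
    x, y = a.values, a2.values
    if x.shape != y.shape:
        raise ValueError("dimension mismatch")
    nx, ny = float(np.linalg.norm(x)), float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise DegenerateVectorError("zero-norm vector in cosine")
    return float(np.dot(x, y) / (nx * ny))


def embedding_similarity_matrix(
    corpus: Sequence[DocumentRecord],
    model: EmbeddingModel,
    negatives: str = "clip",
    on_missing: str = "error",
) -> SimilarityMatrix:
    """Pairwise Sim_WE.  ``negatives`` maps raw cosines to the shared [0, 1]
    scale: "clip" sends negatives to 0, "shift" applies (x+1)/2, "raw" keeps
    cosines (matrix may then contain negative entries).

    ``on_missing``: "error" raises on documents with no in-vocabulary tokens
    or degenerate vectors; "zero" scores all their pairs 0.
    """
    if negatives not in NEGATIVE_POLICIES:
        raise ValueError(f"unknown negatives policy {negatives!r}")
    if on_missing not in ("error", "zero"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    if not corpus:
        raise ValueError("empty corpus")

    asvs: list[AverageSemanticVector | None] = []
    for doc in corpus:
        try:
            asvs.append(average_semantic_vector(doc.tokens, model))
        except (UndefinedEvidenceError, DegenerateVectorError) as exc:
            if on_missing == "error":
                raise type(exc)(f"document {doc.doc_id}: {exc}") from exc
            asvs.append(None)

    n = len(corpus)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if asvs[i] is None or asvs[j] is None:
                s = 0.0
            else:
                s = embedding_document_similarity(asvs[i], asvs[j])
                if negatives == "clip":
                    s = max(s, 0.0)
                elif negatives == "shift":
                    s = (s + 1.0) / 2.0
            values[i, j] = values[j, i] = s
    return SimilarityMatrix([d.doc_id for d in corpus], values)
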