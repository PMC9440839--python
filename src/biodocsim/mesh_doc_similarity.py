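"""Document-level MeSH similarity: AMM over heading sets, and the Sim_MeSH
matrix builder.

A document's MeSH evidence is the set of its headings that resolve in the
forest; headings absent from the forest are dropped with a warning (absence is
vocabulary mismatch, not dissimilarity).  A document with zero resolvable
headings has undefined MeSH evidence: hard error by default, with an opt-in
fallback scoring all its pairs 0.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .corpus_io import DocumentRecord
from .mesh_ontology import MeshForest, MeshHeading
from .similarity_matrix import SimilarityMatrix, UndefinedEvidenceError
from .term_similarity import NodeSimilarityMeasure, amm, heading_similarity

__all__ = ["mesh_document_similarity", "mesh_similarity_matrix"]

logger = logging.getLogger(__name__)


def _resolve(doc: DocumentRecord, forest: MeshForest) -> list[MeshHeading]:
    resolved = []
    for name in sorted(doc.headings):
        heading = forest.headings.get(name)
        if heading is None:
            logger.warning("heading %r of document %s not in forest; dropped", name, doc.doc_id)
        else:
            resolved.append(heading)
    return resolved


def mesh_document_similarity(
    d1: DocumentRecord,
    d2: DocumentRecord,
    forest: MeshForest,
    measure: NodeSimilarityMeasure,
) -> float:
    """AMM over the two documents' resolvable heading sets, with heading-pair
    similarity itself the AMM over node sets."""
    h1, h2 = _resolve(d1, forest), _resolve(d2, forest)
    for doc, hs in ((d1, h1), (d2, h2)):
        if not hs:
            raise UndefinedEvidenceError(
                f"document {doc.doc_id} has no headings resolvable in the forest"
            )
    sims = np.asarray([[heading_similarity(a, b, measure) for b in h2] for a in h1])
    return amm(sims)


def mesh_similarity_matrix(
    corpus: Sequence[DocumentRecord],
    forest: MeshForest,
    measure: NodeSimilarityMeasure,
    on_missing: str = "error",
) -> SimilarityMatrix:
    """Pairwise Sim_MeSH over a corpus.

    Heading-pair similarities are computed once and cached; the per-pair AMM is
    evaluated by the same reduction as :func:`mesh_document_similarity`, so the
    matrix path equals the pairwise path exactly.

    ``on_missing``: "error" raises on a document with no resolvable headings;
    "zero" assigns 0 to all its off-diagonal pairs.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if on_missing not in ("error", "zero"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")

    resolved = [_resolve(doc, forest) for doc in corpus]
    missing = [doc.doc_id for doc, hs in zip(corpus, resolved) if not hs]
    if missing and on_missing == "error":
        raise UndefinedEvidenceError(
            f"documents with no resolvable headings: {', '.join(missing)}"
        )

    names = sorted({h.name for hs in resolved for h in hs})
    name_pos = {name: i for i, name in enumerate(names)}
    hsim = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i, len(names)):
            s = heading_similarity(forest.headings[a], forest.headings[names[j]], measure)
            hsim[i, j] = hsim[j, i] = s

    idx_sets = [np.asarray([name_pos[h.name] for h in hs], dtype=int) for hs in resolved]
    n = len(corpus)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if len(idx_sets[i]) == 0 or len(idx_sets[j]) == 0:
                values[i, j] = values[j, i] = 0.0
                continue
            sub = hsim[np.ix_(idx_sets[i], idx_sets[j])]
            values[i, j] = values[j, i] = amm(sub)
    return SimilarityMatrix([d.doc_id for d in corpus], values)
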