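"""Offline synthetic fixtures with the statistical structure the method assumes.

The generator emulates a topic-structured MEDLINE-like corpus: a toy MeSH
forest in which each topic's headings sit as near-siblings of one deep branch
(with a configurable fraction of headings shared between topics), word
embeddings clustered around per-topic centers, and bag-of-words documents
drawn from a mixture of topic-specific and shared vocabulary.  Each topic's
documents are split into DR and PR relevance classes.  Everything is
deterministic under the spec seed, so fixtures never need to ship with the
package.

Forest layout (subtree letters A/B plus V for shared and Z for secondary
nodes): topic t's specific headings are leaves ``{A|B}01.<topic>.500.<i>``
(depth 4), so within-topic pairs meet at depth 3 while topics sharing a
subtree meet only at depth 1 and topics in different subtrees score 0.  Every
third topic-specific heading carries a second node in the Z subtree, exercising
multi-node headings without inflating cross-topic similarity (Z branches of
different topics have no common ancestor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import DocumentRecord, EmbeddingModel, RelevanceTable
from .mesh_ontology import MeshForest, MeshHeading

__all__ = [
    "SyntheticSpec",
    "generate_mesh_forest",
    "generate_embeddings",
    "generate_corpus",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study corpus.

    Defaults give a desk-scale, well-separated but non-trivial corpus:
    5 topics x 40 documents, 6 headings per topic with 20% shared between
    topics, 60 tokens per document from an 80-word topic vocabulary mixed with
    a 40-word shared vocabulary, 50-dimensional embeddings with topic centers
    of norm 3 and per-word noise sd 0.5, and half of each topic's documents
    labeled DR (the rest PR).
    """

    n_topics: int = 5
    docs_per_topic: int = 40
    headings_per_topic: int = 6
    heading_overlap: float = 0.2
    vocab_per_topic: int = 80
    shared_vocab: int = 40
    tokens_per_doc: int = 60
    embedding_dim: int = 50
    topic_vector_separation: float = 3.0
    noise_sd: float = 0.5
    dr_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_topics",
            "docs_per_topic",
            "headings_per_topic",
            "vocab_per_topic",
            "shared_vocab",
            "tokens_per_doc",
            "embedding_dim",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("heading_overlap", "dr_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.topic_vector_separation <= 0 or self.noise_sd <= 0:
            raise ValueError("separation and noise_sd must be positive")


def _n_shared_headings(spec: SyntheticSpec) -> int:
    return round(spec.heading_overlap * spec.headings_per_topic)


def _shared_heading_names(spec: SyntheticSpec) -> list[str]:
    return [f"SH{i}" for i in range(_n_shared_headings(spec))]


def _specific_heading_names(spec: SyntheticSpec, topic: int) -> list[str]:
    n_specific = spec.headings_per_topic - _n_shared_headings(spec)
    return [f"T{topic}H{i}" for i in range(n_specific)]


def topic_heading_pool(spec: SyntheticSpec, topic: int) -> list[str]:
    """The heading names topic ``topic`` draws from (shared ones first)."""
    return _shared_heading_names(spec) + _specific_heading_names(spec, topic)


def _topic_words(spec: SyntheticSpec, topic: int) -> list[str]:
    return [f"wt{topic}x{i}" for i in range(spec.vocab_per_topic)]


def _shared_words(spec: SyntheticSpec) -> list[str]:
    return [f"wshx{i}" for i in range(spec.shared_vocab)]


def generate_mesh_forest(spec: SyntheticSpec) -> MeshForest:
    """Toy MeSH forest with per-topic heading clusters; annotation counts are
    populated (deterministically from the seed) so IC is computable."""
    headings: list[MeshHeading] = []
    letters = "AB"
    for t in range(spec.n_topics):
        base = f"{letters[t % 2]}01.{100 + t}.500"
        for i, name in enumerate(_specific_heading_names(spec, t)):
            nodes = {f"{base}.{550 + i}"}
            if i % 3 == 2:
                nodes.add(f"Z{t + 1:02d}.{400 + i}")
            headings.append(MeshHeading(name=name, nodes=frozenset(nodes)))
    for i, name in enumerate(_shared_heading_names(spec)):
        headings.append(MeshHeading(name=name, nodes=frozenset({f"V01.900.300.{i + 10}"})))
    forest = MeshForest.from_headings(headings)
    rng = np.random.default_rng([spec.seed, 17])
    for name in sorted(forest.headings):
        for node in sorted(forest.headings[name].nodes):
            forest.counts[node] = float(rng.integers(1, 20))
    return forest


def generate_embeddings(spec: SyntheticSpec) -> EmbeddingModel:
    """Topic-clustered word vectors: topic t's words are its center (a random
    direction scaled to ``topic_vector_separation``) plus gaussian noise;
    shared words are pure noise near the origin."""
    rng = np.random.default_rng([spec.seed, 29])
    vectors: dict[str, np.ndarray] = {}
    for t in range(spec.n_topics):
        direction = rng.normal(size=spec.embedding_dim)
        center = spec.topic_vector_separation * direction / np.linalg.norm(direction)
        for word in _topic_words(spec, t):
            vectors[word] = center + rng.normal(0.0, spec.noise_sd, spec.embedding_dim)
    for word in _shared_words(spec):
        vectors[word] = rng.normal(0.0, spec.noise_sd, spec.embedding_dim)
    return EmbeddingModel(dimension=spec.embedding_dim, vectors=vectors)


def generate_corpus(
    spec: SyntheticSpec,
    forest: MeshForest | None = None,
    embeddings: EmbeddingModel | None = None,
) -> tuple[list[DocumentRecord], RelevanceTable]:
    """Topic-structured documents plus DR/PR relevance labels.

    Each document samples headings without replacement from its topic's pool
    and draws tokens from a 70/30 mixture of topic-specific and shared
    vocabulary.  ``forest``/``embeddings`` are accepted for interface symmetry
    (heading and word names are derived from the spec deterministically).
    """
    rng = np.random.default_rng([spec.seed, 43])
    records: list[DocumentRecord] = []
    rows: list[tuple[str, str, str]] = []
    n_dr = round(spec.dr_fraction * spec.docs_per_topic)
    for t in range(spec.n_topics):
        pool = topic_heading_pool(spec, t)
        topic_words = _topic_words(spec, t)
        shared_words = _shared_words(spec)
        for j in range(spec.docs_per_topic):
            doc_id = str(10_000_000 + t * spec.docs_per_topic + j)
            n_head = min(4, len(pool))
            chosen = rng.choice(len(pool), size=n_head, replace=False)
            headings = frozenset(pool[c] for c in chosen)
            from_topic = rng.random(spec.tokens_per_doc) < 0.7
            tokens = [
                topic_words[rng.integers(len(topic_words))]
                if pick
                else shared_words[rng.integers(len(shared_words))]
                for pick in from_topic
            ]
            records.append(
                DocumentRecord(
                    doc_id=doc_id,
                    abstract=" ".join(tokens),
                    tokens=tuple(tokens),
                    headings=headings,
                )
            )
            rows.append((doc_id, f"T{t}", "DR" if j < n_dr else "PR"))
    return records, RelevanceTable(rows)
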