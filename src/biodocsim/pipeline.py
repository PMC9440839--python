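"""End-to-end composition: evidences -> trained fusion net -> fused similarity
-> multi-dataset clustering evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .content_similarity import content_similarity_matrix
from .corpus_io import DocumentRecord, EmbeddingModel, RelevanceTable
from .embedding_similarity import embedding_similarity_matrix
from .evaluation import (
    ClusteringOutcome,
    all_metrics,
    spectral_cluster,
)
from .fusion import (
    FusionNetwork,
    build_training_pairs,
    fuse_linear,
    normalize_similarity,
    semantic_similarity_matrix,
    train_fnn,
)
from .mesh_doc_similarity import mesh_similarity_matrix
from .mesh_ontology import MeshForest, compute_ic, counts_from_corpus
from .similarity_matrix import SimilarityMatrix
from .term_similarity import NodeSimilarityMeasure

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_datasets"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full similarity pipeline.

    Defaults follow the best-performing configuration: Jiang–Conrath node
    similarity with damping 1, content weight w = 0.7, min-max normalization,
    100 training epochs.
    """

    measure: str = "jc"
    lam: float = 1.0
    w: float = 0.7
    norm: str = "minmax"
    epochs: int = 100
    learning_rate: float = 1e-3
    negatives: str = "clip"
    idf_variant: str = "smooth"
    ic_smoothing: float = 1.0
    ic_from_corpus: bool = True
    on_missing: str = "error"
    train_seed: int = 0
    cluster_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class PipelineResult:
    """All intermediate and final similarity matrices plus the trained net."""

    sim_mesh: SimilarityMatrix
    sim_we: SimilarityMatrix
    sim_con: SimilarityMatrix
    sim_sem: SimilarityMatrix
    sim_fused: SimilarityMatrix
    net: FusionNetwork
    config: PipelineConfig = field(default=PipelineConfig())


def run_pipeline(
    corpus: Sequence[DocumentRecord],
    relevance: RelevanceTable,
    forest: MeshForest,
    embeddings: EmbeddingModel,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Compute the three evidences, train the fusion net on relevance-derived
    targets, and produce the fused similarity matrix."""
    if config.ic_from_corpus:
        counts_from_corpus(forest, corpus)
    compute_ic(forest, smoothing=config.ic_smoothing)
    measure = NodeSimilarityMeasure(config.measure, forest, lam=config.lam)

    sim_mesh = mesh_similarity_matrix(corpus, forest, measure, on_missing=config.on_missing)
    sim_we = embedding_similarity_matrix(
        corpus, embeddings, negatives=config.negatives, on_missing=config.on_missing
    )
    sim_con = content_similarity_matrix(corpus, variant=config.idf_variant)

    pairs = build_training_pairs(sim_mesh, sim_we, relevance)
    net = train_fnn(
        pairs,
        epochs=config.epochs,
        seed=config.train_seed,
        learning_rate=config.learning_rate,
    )
    sim_sem = semantic_similarity_matrix(net, sim_mesh, sim_we)
    fused = fuse_linear(
        normalize_similarity(sim_con, config.norm),
        normalize_similarity(sim_sem, config.norm),
        config.w,
    )
    return PipelineResult(
        sim_mesh=sim_mesh,
        sim_we=sim_we,
        sim_con=sim_con,
        sim_sem=sim_sem,
        sim_fused=fused,
        net=net,
        config=config,
    )


def evaluate_datasets(
    corpus: Sequence[DocumentRecord],
    relevance: RelevanceTable,
    datasets: Sequence[Sequence[str]],
    config: PipelineConfig = PipelineConfig(),
    forest: MeshForest | None = None,
    embeddings: EmbeddingModel | None = None,
    result: PipelineResult | None = None,
) -> pd.DataFrame:
    """Run the clustering protocol over sampled topic subsets.

    The evidences and the fusion net are computed once on the full corpus
    (pass ``result`` to reuse a finished :func:`run_pipeline`); for each
    dataset the semantic and content matrices are subset to the dataset's
    documents, re-normalized within the dataset, fused with weight w, and
    spectrally clustered with k = the number of topics.  Datasets with fewer
    than 2 topics are skipped with a warning.  Returns one row per dataset
    with purity, ARI, NMI and FMI.
    """
    if result is None:
        if forest is None or embeddings is None:
            raise ValueError("either a PipelineResult or (forest, embeddings) is required")
        result = run_pipeline(corpus, relevance, forest, embeddings, config)
    labels = relevance.as_mapping()
    by_topic: dict[str, list[str]] = {}
    for doc in result.sim_fused.doc_ids:
        by_topic.setdefault(labels[doc][0], []).append(doc)

    rows = []
    for ds_id, topics in enumerate(datasets):
        present = [t for t in topics if t in by_topic]
        if len(present) < 2:
            logger.warning("dataset %d has fewer than 2 topics present; skipped", ds_id)
            continue
        docs = [d for t in present for d in by_topic[t]]
        k = len(present)
        sem = normalize_similarity(result.sim_sem.subset(docs), config.norm)
        con = normalize_similarity(result.sim_con.subset(docs), config.norm)
        fused = fuse_linear(con, sem, config.w)
        pred = spectral_cluster(fused, k=k, seed=config.cluster_seed + ds_id)
        outcome = ClusteringOutcome(
            doc_ids=docs, predicted=list(pred), truth=[labels[d][0] for d in docs]
        )
        metrics = all_metrics(outcome)
        rows.append(
            {
                "dataset_id": ds_id,
                "n_docs": len(docs),
                "k": k,
                "purity": metrics["purity"],
                "ari": metrics["ari"],
                "nmi": metrics["nmi"],
                "fmi": metrics["fmi"],
            }
        )
    return pd.DataFrame(rows)
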