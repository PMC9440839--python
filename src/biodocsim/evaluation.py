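"""Clustering evaluation: spectral clustering over a similarity matrix and the
four external metrics — purity, Rand index / adjusted Rand index, normalized
mutual information, and the Fowlkes–Mallows index.

Pair counting over all unordered document pairs uses the conventional
semantics: TP = same truth class and same predicted cluster; FP = same truth,
different clusters; FN = different truth, same cluster; TN = different truth,
different clusters.  ARI uses the Hubert–Arabie contingency-table closed form
of the permutation-model expectation.  Entropies use natural logs (NMI is
base-invariant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from .similarity_matrix import SimilarityMatrix

__all__ = [
    "ClusteringOutcome",
    "PairConfusion",
    "spectral_cluster",
    "pair_confusion",
    "purity",
    "rand_index",
    "adjusted_rand_index",
    "nmi",
    "fmi",
    "all_metrics",
    "summarize_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusteringOutcome:
    """Predicted cluster labels alongside true topic labels; labels are opaque."""

    doc_ids: list[str]
    predicted: list
    truth: list

    def __post_init__(self) -> None:
        if not (len(self.doc_ids) == len(self.predicted) == len(self.truth)):
            raise ValueError("doc_ids, predicted and truth must have equal lengths")

    def contingency(self) -> np.ndarray:
        """Truth-class x predicted-cluster count table."""
        t_codes = pd.Categorical(self.truth).codes
        p_codes = pd.Categorical(self.predicted).codes
        table = np.zeros((t_codes.max() + 1, p_codes.max() + 1), dtype=np.int64)
        np.add.at(table, (t_codes, p_codes), 1)
        return table


@dataclass(frozen=True)
class PairConfusion:
    """Counts over all N(N-1)/2 unordered pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) // 2


def spectral_cluster(
    s: SimilarityMatrix | np.ndarray, k: int, seed: int = 0
) -> np.ndarray:
    """Normalized spectral clustering of a symmetric nonnegative similarity
    matrix: symmetric-normalized Laplacian, the k smallest-eigenvalue
    eigenvectors, row normalization, then seeded k-means.
    """
    w = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=np.float64)
    n = w.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if (w < 0).any():
        raise ValueError("similarity matrix must be nonnegative")
    deg = w.sum(axis=1)
    if (deg == 0).any():
        logger.warning("isolated vertices in similarity graph; adding epsilon to adjacency")
        w = w + 1e-10
        deg = w.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - (d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :])
    lap = (lap + lap.T) / 2.0
    _, vecs = scipy.linalg.eigh(lap, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vecs / norms
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(embedding)


def pair_confusion(outcome: ClusteringOutcome) -> PairConfusion:
    table = outcome.contingency()
    n = table.sum()
    if n < 2:
        raise ValueError("pair counting needs at least 2 documents")
    tp = int(_comb2(table).sum())
    same_truth = int(_comb2(table.sum(axis=1)).sum())
    same_pred = int(_comb2(table.sum(axis=0)).sum())
    total = int(_comb2(np.asarray([n])).sum())
    fp = same_truth - tp
    fn = same_pred - tp
    tn = total - tp - fp - fn
    return PairConfusion(tp=tp, fp=fp, tn=tn, fn=fn)


def purity(outcome: ClusteringOutcome) -> float:
    """Fraction of documents assigned to their predicted cluster's majority
    truth class."""
    table = outcome.contingency()
    return float(table.max(axis=0).sum() / table.sum())


def rand_index(pc: PairConfusion) -> float:
    return (pc.tp + pc.tn) / pc.total


def adjusted_rand_index(outcome: ClusteringOutcome) -> float:
    """Hubert–Arabie ARI via the contingency-table closed form; the degenerate
    all-agreeing single-partition case is defined as 1."""
    table = outcome.contingency()
    n = table.sum()
    sum_ij = float(_comb2(table).sum())
    sum_a = float(_comb2(table.sum(axis=1)).sum())
    sum_b = float(_comb2(table.sum(axis=0)).sum())
    total = float(n * (n - 1) // 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def nmi(outcome: ClusteringOutcome, average: str = "geometric") -> float:
    """I(truth; predicted) normalized by the geometric (default) or arithmetic
    mean of the two entropies.  A single-cluster side has zero entropy: NMI is
    0 unless both sides are single (then 1)."""
    if average not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown average {average!r}")
    table = outcome.contingency().astype(np.float64)
    n = table.sum()
    pi = table.sum(axis=1) / n
    pj = table.sum(axis=0) / n
    h_t = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    h_p = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if h_t == 0.0 or h_p == 0.0:
        return 1.0 if (h_t == 0.0 and h_p == 0.0) else 0.0
    pij = table / n
    mask = pij > 0
    outer = np.outer(pi, pj)
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    denom = math.sqrt(h_t * h_p) if average == "geometric" else (h_t + h_p) / 2.0
    return mi / denom


def fmi(pc: PairConfusion) -> float:
    """Geometric mean of pairwise precision and recall: TP / sqrt((TP+FP)(TP+FN))."""
    if pc.tp + pc.fp == 0 or pc.tp + pc.fn == 0:
        return 0.0
    return pc.tp / math.sqrt((pc.tp + pc.fp) * (pc.tp + pc.fn))


def all_metrics(outcome: ClusteringOutcome) -> dict[str, float]:
    pc = pair_confusion(outcome)
    return {
        "purity": purity(outcome),
        "ri": rand_index(pc),
        "ari": adjusted_rand_index(outcome),
        "nmi": nmi(outcome),
        "fmi": fmi(pc),
    }


def summarize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation per metric column."""
    cols = ["purity", "ari", "nmi", "fmi"]
    return pd.DataFrame(
        {"metric": cols, "mean": [table[c].mean() for c in cols], "sd": [table[c].std(ddof=1) for c in cols]}
    )
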