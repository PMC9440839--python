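"""Evidence fusion.

Stage one: a small feedforward network (2 inputs, 300 ReLU hidden units, one
sigmoid output) maps the pair (Sim_MeSH, Sim_WE) to a single semantic
similarity Sim_Sem.  Training pairs come from topic-relevance labels: a pair
of documents both DR for the same topic targets 0.9, both PR for the same
topic targets 0.5, anything else targets 0.1.  The net is trained full-batch
with Adam on mean squared error; the stated ReLU on the input layer is the
identity on [0, 1] similarities and is a documented no-op.

Stage two: Sim_Sem and the TF-IDF content similarity Sim_Con are normalized
to [0, 1] and combined linearly,

    Sim_F = w·Sim_Con + (1 − w)·Sim_Sem,      w in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import RelevanceTable
from .similarity_matrix import SimilarityMatrix

__all__ = [
    "FusionNetwork",
    "PairTrainingSet",
    "FusionWeights",
    "build_training_pairs",
    "train_fnn",
    "fnn_predict",
    "semantic_similarity_matrix",
    "normalize_similarity",
    "fuse_linear",
]

HIDDEN_UNITS = 300
TARGET_DR, TARGET_PR, TARGET_NR = 0.9, 0.5, 0.1


@dataclass
class PairTrainingSet:
    """Unordered document pairs with their two evidence similarities and the
    relevance-derived target in {0.9, 0.5, 0.1}."""

    inputs: np.ndarray  # (n_pairs, 2): columns Sim_MeSH, Sim_WE
    targets: np.ndarray  # (n_pairs,)
    doc_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.inputs.shape != (len(self.targets), 2):
            raise ValueError("inputs must be (n_pairs, 2) aligned with targets")
        allowed = {TARGET_DR, TARGET_PR, TARGET_NR}
        if not set(np.unique(self.targets)) <= allowed:
            raise ValueError(f"targets must be drawn from {allowed}")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class FusionNetwork:
    """Weights of the 2-300-1 fusion net plus training metadata."""

    w1: np.ndarray  # (hidden, 2)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (1, hidden)
    b2: float
    training_meta: dict = field(default_factory=dict)

    def forward(self, inputs: np.ndarray) -> np.ndarray:
        """Batched forward pass; ``inputs`` is (n, 2), output is (n,) in (0, 1)."""
        x = np.asarray(inputs, dtype=np.float64)
        h = np.maximum(x @ self.w1.T + self.b1, 0.0)
        z = h @ self.w2.ravel() + self.b2
        return 1.0 / (1.0 + np.exp(-z))

    # --- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FusionNetwork":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            w1=np.asarray(payload["w1"]),
            b1=np.asarray(payload["b1"]),
            w2=np.asarray(payload["w2"]),
            b2=float(payload["b2"]),
            training_meta=payload.get("training_meta", {}),
        )


@dataclass(frozen=True)
class FusionWeights:
    """Content weight w of the linear fusion; 1 - w goes to Sim_Sem."""

    w: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"fusion weight must be in [0, 1], got {self.w}")


def build_training_pairs(
    sim_mesh: SimilarityMatrix,
    sim_we: SimilarityMatrix,
    relevance: RelevanceTable,
) -> PairTrainingSet:
    """One row per unordered document pair: target 0.9 iff both docs are DR for
    the same topic, 0.5 iff both PR for the same topic, else 0.1."""
    if sim_mesh.doc_ids != sim_we.doc_ids:
        raise ValueError("similarity matrices are not aligned on doc_ids")
    labels = relevance.as_mapping()
    missing = [d for d in sim_mesh.doc_ids if d not in labels]
    if missing:
        raise ValueError(f"documents missing from relevance table: {', '.join(missing)}")
    ids = sim_mesh.doc_ids
    n = len(ids)
    inputs, targets, pairs = [], [], []
    for i in range(n):
        ti, ri = labels[ids[i]]
        for j in range(i + 1, n):
            tj, rj = labels[ids[j]]
            if ti == tj and ri == rj == "DR":
                t = TARGET_DR
            elif ti == tj and ri == rj == "PR":
                t = TARGET_PR
            else:
                t = TARGET_NR
            inputs.append((sim_mesh.values[i, j], sim_we.values[i, j]))
            targets.append(t)
            pairs.append((ids[i], ids[j]))
    return PairTrainingSet(np.asarray(inputs), np.asarray(targets), pairs)


def train_fnn(
    pairs: PairTrainingSet,
    epochs: int = 100,
    seed: int = 0,
    learning_rate: float = 1e-3,
    hidden: int = HIDDEN_UNITS,
) -> FusionNetwork:
    """Train the fusion net full-batch with Adam on mean squared error.

    Weights are initialized uniformly in [-1/sqrt(fan_in), 1/sqrt(fan_in)] from
    ``seed``; the loss curve (initial MSE followed by the MSE after each
    epoch) is stored in ``training_meta``.  Deterministic under seed.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    lim1, lim2 = 1.0 / np.sqrt(2.0), 1.0 / np.sqrt(hidden)
    params = {
        "w1": rng.uniform(-lim1, lim1, size=(hidden, 2)),
        "b1": rng.uniform(-lim1, lim1, size=hidden),
        "w2": rng.uniform(-lim2, lim2, size=(1, hidden)),
        "b2": rng.uniform(-lim2, lim2, size=1),
    }
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    x, y = pairs.inputs, pairs.targets
    n = len(pairs)

    def forward_full():
        pre = x @ params["w1"].T + params["b1"]
        h = np.maximum(pre, 0.0)
        z = h @ params["w2"].ravel() + params["b2"][0]
        p = 1.0 / (1.0 + np.exp(-z))
        return pre, h, p

    loss_curve: list[float] = []
    for step in range(1, epochs + 1):
        pre, h, p = forward_full()
        loss_curve.append(float(np.mean((p - y) ** 2)))  # loss before this update
        # d(MSE)/dz through the sigmoid
        dz = 2.0 * (p - y) * p * (1.0 - p) / n  # (n,)
        grads = {
            "w2": (dz @ h)[None, :],
            "b2": np.asarray([dz.sum()]),
        }
        dh = np.outer(dz, params["w2"].ravel())  # (n, hidden)
        dpre = dh * (pre > 0.0)
        grads["w1"] = dpre.T @ x
        grads["b1"] = dpre.sum(axis=0)
        for k in params:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - beta1**step)
            v_hat = v[k] / (1 - beta2**step)
            params[k] -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
    _, _, p = forward_full()
    loss_curve.append(float(np.mean((p - y) ** 2)))

    return FusionNetwork(
        w1=params["w1"],
        b1=params["b1"],
        w2=params["w2"],
        b2=float(params["b2"][0]),
        training_meta={
            "epochs": epochs,
            "seed": seed,
            "learning_rate": learning_rate,
            "loss_curve": loss_curve,
        },
    )


def fnn_predict(net: FusionNetwork, sim_mesh: float, sim_we: float) -> float:
    """Fused semantic similarity of one document pair, strictly in (0, 1)."""
    return float(net.forward(np.asarray([[sim_mesh, sim_we]]))[0])


def semantic_similarity_matrix(
    net: FusionNetwork,
    sim_mesh: SimilarityMatrix,
    sim_we: SimilarityMatrix,
) -> SimilarityMatrix:
    """Apply the trained net to every off-diagonal pair; the diagonal is
    forced to 1."""
    if sim_mesh.doc_ids != sim_we.doc_ids:
        raise ValueError("similarity matrices are not aligned on doc_ids")
    n = sim_mesh.n
    iu = np.triu_indices(n, k=1)
    inputs = np.column_stack([sim_mesh.values[iu], sim_we.values[iu]])
    preds = net.forward(inputs)
    values = np.eye(n)
    values[iu] = preds
    values[(iu[1], iu[0])] = preds
    return SimilarityMatrix(list(sim_mesh.doc_ids), values)


def normalize_similarity(matrix: SimilarityMatrix, method: str = "minmax") -> SimilarityMatrix:
    """Rescale off-diagonal entries to [0, 1]; the diagonal stays 1.

    ``minmax`` maps the off-diagonal min to 0 and max to 1 (a constant
    off-diagonal becomes all zeros).  ``sumnorm`` first divides each
    off-diagonal entry by the off-diagonal sum, then applies the same [0, 1]
    rescale.
    """
    if matrix.n < 2:
        raise ValueError("normalization needs at least 2 documents")
    if method not in ("minmax", "sumnorm"):
        raise ValueError(f"unknown normalization {method!r}")
    values = matrix.values.copy()
    off = ~np.eye(matrix.n, dtype=bool)
    entries = values[off]
    if method == "sumnorm":
        total = entries.sum()
        entries = entries / total if total != 0.0 else np.zeros_like(entries)
    lo, hi = entries.min(), entries.max()
    if hi > lo:
        entries = (entries - lo) / (hi - lo)
    else:
        entries = np.zeros_like(entries)
    values[off] = entries
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(matrix.doc_ids), values)


def fuse_linear(
    sim_con: SimilarityMatrix,
    sim_sem: SimilarityMatrix,
    w: float | FusionWeights,
) -> SimilarityMatrix:
    """Sim_F = w·Sim_Con + (1 − w)·Sim_Sem, element-wise; w = 0 reproduces
    Sim_Sem exactly and w = 1 reproduces Sim_Con exactly."""
    weight = w.w if isinstance(w, FusionWeights) else float(w)
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"fusion weight must be in [0, 1], got {weight}")
    if sim_con.doc_ids != sim_sem.doc_ids:
        raise ValueError("similarity matrices are not aligned on doc_ids")
    if weight == 0.0:
        values = sim_sem.values.copy()
    elif weight == 1.0:
        values = sim_con.values.copy()
    else:
        values = weight * sim_con.values + (1.0 - weight) * sim_sem.values
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(sim_con.doc_ids), values)
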