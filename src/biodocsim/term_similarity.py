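"""Node- and heading-level MeSH similarity.

Four node measures are supported, all mapped into [0, 1], all scoring 1 on
identical nodes and 0 across subtrees:

* ``wp``  — Wu–Palmer: 2·depth(LCA) / (depth(v) + depth(v')).
* ``lc``  — Leacock–Chodorow on node-count paths, -log(nodepath / 2·Dmax),
  rescaled by its maximum -log(1 / 2·Dmax) so identity scores 1; Dmax is the
  maximum node depth of the shared subtree.
* ``lin`` — Lin: 2·IC(LCA) / (IC(v) + IC(v')).
* ``jc``  — Jiang–Conrath distance d = IC(v) + IC(v') − 2·IC(LCA) turned into
  a similarity 1 / (1 + λ·d); λ > 0 damps the distance.

Heading similarity aggregates node similarities by average maximum match
(AMM): each node's best match in the other set, averaged over both
directions.  Natural logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh_ontology import MeshForest, MeshHeading, depth, lca, path_length

__all__ = ["NodeSimilarityMeasure", "heading_similarity", "amm"]

_KINDS = ("wp", "lc", "lin", "jc")


@dataclass
class NodeSimilarityMeasure:
    """A named node-similarity measure bound to a MeSH forest.

    ``lin`` and ``jc`` require the forest's information content (``compute_ic``)
    to be populated; ``lc`` uses the forest's per-subtree maximum depth.
    """

    kind: str
    forest: MeshForest
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in _KINDS:
            raise ValueError(f"unknown measure {self.kind!r}; choose from {_KINDS}")
        if self.kind == "jc" and self.lam <= 0:
            raise ValueError("jc requires lambda > 0")
        if self.kind in ("lin", "jc") and not self.forest.ic:
            raise ValueError(f"measure {self.kind!r} requires information content; run compute_ic")
        self._max_depth = self.forest.subtree_max_depth() if self.kind == "lc" else {}

    def __call__(self, v: str, v2: str) -> float:
        anc = lca(v, v2)
        if anc is None:
            return 0.0
        if self.kind == "wp":
            return 2.0 * depth(anc) / (depth(v) + depth(v2))
        if self.kind == "lc":
            dmax = self._max_depth.get(v[0], max(depth(v), depth(v2)))
            nodepath = path_length(v, v2) + 1.0
            return math.log(nodepath / (2.0 * dmax)) / math.log(1.0 / (2.0 * dmax))
        ic = self.forest.ic
        if self.kind == "lin":
            denom = ic[v] + ic[v2]
            if denom == 0.0:
                return 1.0 if v == v2 else 0.0
            return 2.0 * ic[anc] / denom
        # jc
        d = max(ic[v] + ic[v2] - 2.0 * ic[anc], 0.0)
        return 1.0 / (1.0 + self.lam * d)


def amm(sims: np.ndarray) -> float:
    """Average maximum match of a |M| x |M'| pairwise similarity array: the sum
    of row maxima plus the sum of column maxima over |M| + |M'|."""
    sims = np.asarray(sims, dtype=np.float64)
    if sims.size == 0:
        raise ValueError("AMM over an empty set")
    n, m = sims.shape
    return float((sims.max(axis=1).sum() + sims.max(axis=0).sum()) / (n + m))


def heading_similarity(
    m1: MeshHeading, m2: MeshHeading, measure: NodeSimilarityMeasure
) -> float:
    """AMM over the two headings' node sets under the given node measure."""
    nodes1, nodes2 = sorted(m1.nodes), sorted(m2.nodes)
    if not nodes1 or not nodes2:
        raise ValueError("heading with empty node set")
    sims = np.asarray([[measure(a, b) for b in nodes2] for a in nodes1])
    return amm(sims)
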