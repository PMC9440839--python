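"""The MeSH forest: tree numbers, depth/LCA/path computations, information content.

MeSH organizes headings into 16 subtrees (categories A, B, C, ...).  A heading
occupies one or more *nodes*, each addressed by a dotted tree number such as
``A11.284.430.214.190.500.560``; the tree number encodes the full ancestor
chain, so depth, lowest common ancestor and path length are all prefix
computations on the segment list.  Nodes in different subtrees (different
first segments) have no common ancestor.

Information content (IC) is corpus-based: each node accumulates its own
annotation count plus the counts of all descendants (IS-A propagation), is
normalized within its subtree, and IC(v) = -log p(v).  Each subtree is its own
probability space because cross-subtree similarity is defined as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TreeNumber",
    "MeshHeading",
    "MeshForest",
    "depth",
    "lca",
    "path_length",
    "compute_ic",
    "load_mesh_forest",
    "save_mesh_forest",
    "counts_from_corpus",
]


def _segments(tree_number: str) -> list[str]:
    segs = tree_number.split(".")
    if not segs or any(s == "" for s in segs):
        raise ValueError(f"malformed tree number {tree_number!r}")
    return segs


@dataclass(frozen=True)
class TreeNumber:
    """A dotted MeSH tree number; ``subtree`` is the category letter."""

    segments: tuple[str, ...]

    @classmethod
    def parse(cls, s: str) -> "TreeNumber":
        return cls(tuple(_segments(s)))

    @property
    def subtree(self) -> str:
        return self.segments[0][0]

    def __str__(self) -> str:
        return ".".join(self.segments)


@dataclass(frozen=True)
class MeshHeading:
    """A MeSH heading with its (nonempty) set of tree-number nodes."""

    name: str
    nodes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError(f"heading {self.name!r} has no tree numbers")


def depth(v: str | TreeNumber) -> int:
    """Number of segments; a top-level segment such as ``A11`` has depth 1."""
    if isinstance(v, TreeNumber):
        return len(v.segments)
    return len(_segments(v))


def lca(v: str | TreeNumber, v2: str | TreeNumber) -> str | None:
    """Longest common segment prefix, or None when the first segments differ
    (no common ancestor across subtree roots)."""
    a, b = str(v).split("."), str(v2).split(".")
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    if n == 0:
        return None
    return ".".join(a[:n])


def path_length(v: str | TreeNumber, v2: str | TreeNumber) -> float:
    """Edge count of the path through the LCA; infinity across subtrees."""
    anc = lca(v, v2)
    if anc is None:
        return math.inf
    return depth(v) + depth(v2) - 2 * depth(anc)


@dataclass
class MeshForest:
    """Headings, node index, per-node annotation counts and derived IC.

    ``nodes`` (derived) is the closure of every listed tree number under
    prefixes, so ancestors implied by tree numbers always exist for IC and
    LCA lookups even when no heading sits on them.
    """

    headings: dict[str, MeshHeading] = field(default_factory=dict)
    node_index: dict[str, str] = field(default_factory=dict)
    counts: dict[str, float] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._closure: set[str] | None = None

    @classmethod
    def from_headings(cls, headings: Iterable[MeshHeading]) -> "MeshForest":
        forest = cls()
        for h in headings:
            if h.name in forest.headings:
                raise ValueError(f"duplicate heading {h.name!r}")
            forest.headings[h.name] = h
            for node in h.nodes:
                _segments(node)  # validate
                forest.node_index[node] = h.name
        return forest

    # --- structure ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        """All nodes: every tree number plus every proper prefix (implicit ancestors)."""
        if self._closure is None:
            closure: set[str] = set()
            for node in self.node_index:
                segs = node.split(".")
                for i in range(1, len(segs) + 1):
                    closure.add(".".join(segs[:i]))
            self._closure = closure
        return self._closure

    def invalidate(self) -> None:
        self._closure = None

    def subtree_max_depth(self) -> dict[str, int]:
        """Maximum node depth per subtree category letter."""
        out: dict[str, int] = {}
        for node in self.nodes:
            cat = node[0]
            d = node.count(".") + 1
            out[cat] = max(out.get(cat, 0), d)
        return out

    def children(self) -> dict[str, list[str]]:
        kids: dict[str, list[str]] = {n: [] for n in self.nodes}
        for node in self.nodes:
            if "." in node:
                parent = node.rsplit(".", 1)[0]
                kids[parent].append(node)
        return kids


def compute_ic(forest: MeshForest, smoothing: float = 1.0) -> MeshForest:
    """Populate ``forest.ic`` from annotation counts with descendant propagation.

    cumulative(v) = count(v) + smoothing + sum of children's cumulatives;
    p(v) = cumulative(v) / cumulative(subtree top-level ancestor of v);
    ic(v) = -log p(v).  IC is 0 at each top-level node and non-decreasing down
    any root-to-leaf path.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    forest.invalidate()
    nodes = forest.nodes
    kids = forest.children()
    cumulative: dict[str, float] = {}
    for node in sorted(nodes, key=lambda n: -n.count(".")):  # deepest first
        own = forest.counts.get(node, 0.0) + smoothing
        cumulative[node] = own + sum(cumulative[c] for c in kids[node])
    ic: dict[str, float] = {}
    for node in nodes:
        top = node.split(".", 1)[0]
        denom = cumulative[top]
        if denom <= 0:
            raise ValueError(
                f"subtree root {top!r} has cumulative count 0 with smoothing 0; cannot normalize"
            )
        ic[node] = -math.log(cumulative[node] / denom)
    forest.ic = ic
    return forest


def counts_from_corpus(forest: MeshForest, corpus: Sequence) -> MeshForest:
    """Annotation counts from a document corpus: each document increments the
    count of every tree number of every heading it carries."""
    counts: dict[str, float] = {}
    for doc in corpus:
        for name in doc.headings:
            heading = forest.headings.get(name)
            if heading is None:
                continue
            for node in heading.nodes:
                counts[node] = counts.get(node, 0.0) + 1.0
    forest.counts = counts
    return forest


def load_mesh_forest(path: str | Path, format: str = "fixture") -> MeshForest:
    """Read a MeSH forest.

    ``fixture``: one heading per line, ``name<TAB>tree;numbers``.
    ``descriptor``: NLM descriptor ASCII export (``*NEWRECORD`` blocks with
    ``MH =`` and ``MN =`` lines).
    """
    headings: list[MeshHeading] = []
    if format == "fixture":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}: line {lineno}: expected 'name<TAB>numbers'")
                name, numbers = parts
                nodes = frozenset(n for n in numbers.split(";") if n)
                if not nodes:
                    raise ValueError(f"{path}: line {lineno}: heading {name!r} has no tree numbers")
                for n in nodes:
                    _segments(n)
                headings.append(MeshHeading(name=name, nodes=nodes))
    elif format == "descriptor":
        name: str | None = None
        nodes_acc: list[str] = []

        def flush() -> None:
            if name is not None and nodes_acc:
                headings.append(MeshHeading(name=name, nodes=frozenset(nodes_acc)))

        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("*NEWRECORD"):
                    flush()
                    name, nodes_acc = None, []
                elif line.startswith("MH = "):
                    name = line[5:].strip()
                elif line.startswith("MN = "):
                    _segments(line[5:].strip())
                    nodes_acc.append(line[5:].strip())
        flush()
    else:
        raise ValueError(f"unknown forest format {format!r}")
    return MeshForest.from_headings(headings)


def save_mesh_forest(forest: MeshForest, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(forest.headings):
            nodes = ";".join(sorted(forest.headings[name].nodes))
            fh.write(f"{name}\t{nodes}\n")
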