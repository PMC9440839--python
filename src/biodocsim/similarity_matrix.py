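"""Symmetric document-by-document similarity matrices — the interchange format
between every stage of the pipeline — plus the shared error types for
documents whose evidence is undefined."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "UndefinedEvidenceError",
    "DegenerateVectorError",
]


class UndefinedEvidenceError(ValueError):
    """A document has no usable evidence for a similarity (no resolvable MeSH
    headings, or no in-vocabulary tokens)."""


class DegenerateVectorError(ValueError):
    """A document vector is constant/zero and cannot be normalized."""


@dataclass
class SimilarityMatrix:
    """Ordered doc_ids plus a symmetric values matrix with unit diagonal.

    Entries live in [0, 1] under the default policies; ``validate`` checks the
    contract (``check_range=False`` admits raw cosine matrices in [-1, 1]).
    """

    doc_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.doc_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} doc_ids")
        if len(set(self.doc_ids)) != n:
            raise ValueError("duplicate doc_ids")

    @property
    def n(self) -> int:
        return len(self.doc_ids)

    def validate(self, check_range: bool = True, atol: float = 1e-9) -> None:
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=atol):
            raise ValueError("diagonal is not all ones")
        if check_range and ((self.values < -atol).any() or (self.values > 1 + atol).any()):
            raise ValueError("entries outside [0, 1]")

    def entry(self, doc_a: str, doc_b: str) -> float:
        idx = {d: i for i, d in enumerate(self.doc_ids)}
        return float(self.values[idx[doc_a], idx[doc_b]])

    def subset(self, doc_ids: list[str]) -> "SimilarityMatrix":
        idx = {d: i for i, d in enumerate(self.doc_ids)}
        rows = [idx[d] for d in doc_ids]
        return SimilarityMatrix(list(doc_ids), self.values[np.ix_(rows, rows)])

    # --- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("doc_id\t" + "\t".join(self.doc_ids) + "\n")
            for i, doc in enumerate(self.doc_ids):
                row = "\t".join(repr(float(x)) for x in self.values[i])
                fh.write(f"{doc}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            doc_ids = header[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(doc_ids, np.asarray(rows))

    def to_npy(self, path: str | Path) -> None:
        """Compact binary matrix with a sidecar id list (path + '.ids.txt')."""
        path = Path(path)
        np.save(path, self.values)
        with open(str(path) + ".ids.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.doc_ids) + "\n")
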