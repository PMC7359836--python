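"""Labelled square distance matrices and their PHYLIP-dialect serialization."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["DistanceMatrix", "read_phylip_square", "write_phylip_square"]


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal square matrix with one label per row."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        pos = {lab: i for i, lab in enumerate(self.labels)}
        idx = np.array([pos[lab] for lab in labels], dtype=int)
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        n = len(self)
        return self.values[np.tril_indices(n, k=-1)]


def write_phylip_square(dm: DistanceMatrix, path: str | Path, fmt: str = "%.10g") -> None:
    """Square PHYLIP dialect: first line n, then one label + full row per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for lab, row in zip(dm.labels, dm.values):
            fh.write(lab + "\t" + "\t".join(fmt % v for v in row) + "\n")


def read_phylip_square(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"{path}: empty matrix file")
    n = int(tokens[0])
    if len(tokens) != 1 + n * (n + 1):
        raise ValueError(f"{path}: expected {n} rows of {n} values")
    labels: list[str] = []
    values = np.zeros((n, n))
    pos = 1
    for i in range(n):
        labels.append(tokens[pos])
        values[i] = [float(t) for t in tokens[pos + 1 : pos + 1 + n]]
        pos += 1 + n
    return DistanceMatrix(labels=labels, values=values)
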