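"""Point metrics between natural vectors and the Hausdorff set distance.

H(X, Y) = max( max_x min_y d(x, y), max_y min_x d(x, y) ) over finite vector
sets, with a Euclidean or Manhattan base norm.  Vectors are compared raw —
no standardization or rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from alfphylo.natvec import NaturalVector, profile_vectors
from alfphylo.seqio import TaxonProfile

BASE_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def _as_array(v) -> np.ndarray:
    if isinstance(v, NaturalVector):
        return v.values
    return np.asarray(v, dtype=float)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        arr = np.atleast_2d(np.asarray(X, dtype=float))
    else:
        arr = np.atleast_2d(np.vstack([_as_array(x) for x in X]))
    if arr.size == 0:
        raise ValueError("empty vector set")
    return arr


def point_distance(u, v, base_metric: str = "euclidean") -> float:
    """Euclidean or Manhattan distance between two equal-dimension vectors."""
    if base_metric not in BASE_METRICS:
        raise ValueError(f"unknown base metric {base_metric!r}")
    a, b = _as_array(u), _as_array(v)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if base_metric == "euclidean":
        return float(np.linalg.norm(a - b))
    return float(np.abs(a - b).sum())


def hausdorff(X, Y, base_metric: str = "euclidean") -> float:
    """Hausdorff distance between two non-empty finite vector sets."""
    if base_metric not in BASE_METRICS:
        raise ValueError(f"unknown base metric {base_metric!r}")
    A, B = _as_matrix(X), _as_matrix(Y)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    d = cdist(A, B, metric=BASE_METRICS[base_metric])
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


@dataclass
class DistanceMatrix:
    """Labeled symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    base_metric: str = "euclidean"
    set_metric: str = "hausdorff"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path=None) -> str:
        lines = ["\t".join(["label"] + self.labels)]
        for label, row in zip(self.labels, self.values):
            lines.append("\t".join([label] + [repr(float(v)) for v in row]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, path, base_metric: str = "euclidean", set_metric: str = "direct") -> "DistanceMatrix":
        lines = Path(path).read_text().strip().splitlines()
        labels = lines[0].split("\t")[1:]
        values = np.array([[float(x) for x in line.split("\t")[1:]] for line in lines[1:]])
        return cls(labels=labels, values=values, base_metric=base_metric, set_metric=set_metric)

    def to_phylip(self, path=None) -> str:
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append("  ".join([f"{label:<10s}"] + [f"{v:.6f}" for v in row]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def pairwise_matrix(
    profiles: Sequence[TaxonProfile],
    base_metric: str = "euclidean",
    set_metric: str = "hausdorff",
    extended: bool = True,
    vectors: Sequence[np.ndarray] | None = None,
) -> DistanceMatrix:
    """Pairwise taxon distances from natural-vector sets.

    ``set_metric="hausdorff"`` compares per-taxon vector sets;
    ``set_metric="direct"`` requires exactly one sequence per taxon and uses
    the base point metric (single-sequence rRNA-style mode).  Precomputed
    per-taxon vector arrays can be passed via ``vectors`` (bootstrap reuse).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if set_metric not in ("hausdorff", "direct"):
        raise ValueError(f"unknown set metric {set_metric!r}")
    alphabets = {p.alphabet.name for p in profiles}
    if len(alphabets) > 1:
        raise ValueError(f"profiles mix alphabets {sorted(alphabets)}")
    labels = [p.label for p in profiles]
    if vectors is None:
        vectors = [profile_vectors(p, extended=extended) for p in profiles]
    if set_metric == "direct":
        bad = [p.label for p, v in zip(profiles, vectors) if v.shape[0] != 1]
        if bad:
            raise ValueError(f"direct mode requires single-sequence taxa; offending: {bad}")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if set_metric == "direct":
                dij = point_distance(vectors[i][0], vectors[j][0], base_metric)
            else:
                dij = hausdorff(vectors[i], vectors[j], base_metric)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=labels, values=d, base_metric=base_metric, set_metric=set_metric)
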