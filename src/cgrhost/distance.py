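"""Cosine distances between CGR signatures, for distance-based phylogenetics.

Each feature tensor is flattened to a vector of length 3*4^k — all F1
(count) cells first, then all F2 (mean-x) cells, then all F3 (mean-y) cells,
each channel in row-major cell order — and pairs of sequences are compared
by cosine distance, 1 - (a.b)/(|a||b|).  The pairwise matrix can be written
in PHYLIP square format for external tree building (e.g. Neighbor-Joining
in MEGA); tree construction itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureTensor

__all__ = [
    "DistanceMatrix",
    "flatten",
    "cosine_similarity",
    "cosine_distance",
    "pairwise_distances",
    "write_phylip",
    "write_long_tsv",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise cosine-distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")


def flatten(tensor: FeatureTensor) -> np.ndarray:
    """Tensor -> vector of length 3*4^k: F1 cells, then F2, then F3, each
    channel row-major.  The value of word w sits at offset
    channel*4^k + row*2^k + col with (row, col) from ``kmer_cell_index``."""
    return np.ascontiguousarray(tensor.data).reshape(-1).copy()


def _checked(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector lengths differ: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return a / na, b / nb

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a.b / (|a| |b|); in [-1, 1], and [0, 1] for non-negative vectors."""
    ua, ub = _checked(a, b)
    if np.array_equal(ua, ub):  # identical direction: exactly 1
        return 1.0
    return float(np.clip(ua @ ub, -1.0, 1.0))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cosine similarity; 0 for identical directions, at most 2."""
    return 1.0 - cosine_similarity(a, b)


def pairwise_distances(
    tensors: Sequence[FeatureTensor], ids: Sequence[str]
) -> DistanceMatrix:
    """All-vs-all cosine distances over flattened tensors (common k)."""
    if len(tensors) < 2:
        raise ValueError("need at least 2 sequences")
    if len(tensors) != len(ids):
        raise ValueError("ids and tensors differ in length")
    k = tensors[0].k
    for t in tensors:
        if t.k != k:
            raise ValueError(f"mixed k values: {t.k} vs {k}")
    vecs = np.stack([flatten(t) for t in tensors])
    norms = np.linalg.norm(vecs, axis=1)
    if (norms == 0).any():
        bad = [ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"all-zero feature vectors for: {bad}")
    d = cdist(vecs, vecs, metric="cosine")
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=tuple(ids), matrix=d)


def write_phylip(dm: DistanceMatrix, handle: TextIO) -> None:
    """Relaxed PHYLIP square distance matrix (names of any length)."""
    handle.write(f"{len(dm.ids)}\n")
    width = max(10, max(len(i) for i in dm.ids) + 2)
    for name, row in zip(dm.ids, dm.matrix):
        vals = " ".join(f"{v:.10f}" for v in row)
        handle.write(f"{name:<{width}}{vals}\n")


def write_long_tsv(dm: DistanceMatrix, handle: TextIO) -> None:
    """Long-format TSV: id_a, id_b, distance for every unordered pair."""
    handle.write("id_a\tid_b\tdistance\n")
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            handle.write(f"{dm.ids[i]}\t{dm.ids[j]}\t{dm.matrix[i, j]:.10f}\n")
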