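"""Chaos-game-representation (CGR) featurization of DNA sequences.

A DNA sequence is embedded in the unit square by the iterated midpoint map:
starting from the centre (0.5, 0.5), each nucleotide pulls the current point
halfway toward its assigned corner.  All trajectory points whose last ``k``
nucleotides spell the same k-mer fall inside one 2^-k x 2^-k sub-square, so a
2^k x 2^k grid indexed by k-mer identity tiles the square (the classical
frequency-CGR, or FCGR).

This module builds a three-channel FCGR signature per sequence:

* channel F1 - k-mer occurrence counts,
* channel F2 - per k-mer, the mean x-coordinate of the trajectory points at
  which that k-mer ends (0 for absent k-mers),
* channel F3 - the corresponding mean y-coordinate.

The positional channels F2/F3 retain where along the sequence a k-mer tends
to occur (through its prefix context), which plain FCGR discards.  Channels
may be min-max normalized to [0, 1] independently so counts and coordinates
share a scale before classification.

Residues outside {A, C, G, T} (IUPAC ambiguity codes) emit no trajectory
point and invalidate every k-window that contains them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "GenomeSequence",
    "CornerAssignment",
    "DEFAULT_CORNERS",
    "CgrTrajectory",
    "KmerCountTable",
    "KmerPositionTable",
    "FeatureTensor",
    "count_kmers",
    "cgr_trajectory",
    "kmer_average_positions",
    "kmer_cell_index",
    "build_feature_tensor",
    "minmax_normalize",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_UNIT_CORNERS = {(0, 0), (0, 1), (1, 0), (1, 1)}


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence.

    Residues are uppercased on construction; the alphabet is {A, C, G, T}
    plus IUPAC ambiguity codes (any other letter is tolerated on input and
    treated as ambiguous downstream).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CornerAssignment:
    """Bijective mapping of {A, C, G, T} onto the unit-square corners.

    The default places A=(0,0), C=(0,1), G=(1,1), T=(1,0) — the convention
    under which every number of the reference worked computation is
    reproduced.  Any bijection is accepted; the choice only relabels grid
    cells and reflects coordinates, it does not change the information
    content of the signature.
    """

    A: tuple[int, int] = (0, 0)
    C: tuple[int, int] = (0, 1)
    G: tuple[int, int] = (1, 1)
    T: tuple[int, int] = (1, 0)

    def __post_init__(self) -> None:
        corners = {self.A, self.C, self.G, self.T}
        if corners != _UNIT_CORNERS:
            raise ValueError(
                "corner assignment must map A,C,G,T onto the four distinct "
                f"unit-square corners, got {self.A, self.C, self.G, self.T}"
            )

    def corner(self, base: str) -> tuple[int, int]:
        return getattr(self, base)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Corner x and y coordinates indexed by base index (A,C,G,T)."""
        xs = np.array([self.corner(b)[0] for b in _BASES], dtype=np.float64)
        ys = np.array([self.corner(b)[1] for b in _BASES], dtype=np.float64)
        return xs, ys

    def to_dict(self) -> dict[str, list[int]]:
        return {b: list(self.corner(b)) for b in _BASES}

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "CornerAssignment":
        return cls(**{b: tuple(d[b]) for b in _BASES})  # type: ignore[arg-type]


DEFAULT_CORNERS = CornerAssignment()


@dataclass(frozen=True)
class CgrTrajectory:
    """Ordered CGR points, one per accepted (A/C/G/T) residue."""

    points: tuple[tuple[float, float], ...]
    start: tuple[float, float] = (0.5, 0.5)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.points)


@dataclass(frozen=True)
class KmerCountTable:
    """Occurrence counts of every length-k word over {A,C,G,T}."""

    k: int
    counts: Mapping[str, int]

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class KmerPositionTable:
    """Mean CGR endpoint per k-mer; (0, 0) for absent k-mers."""

    k: int
    mean_x: Mapping[str, float]
    mean_y: Mapping[str, float]


@dataclass(frozen=True)
class FeatureTensor:
    """The 3 x 2^k x 2^k signature (counts, mean-x, mean-y channels)."""

    k: int
    data: np.ndarray  # shape (3, 2**k, 2**k), float64
    normalized: bool
    corners: CornerAssignment = field(default=DEFAULT_CORNERS)

    def __post_init__(self) -> None:
        side = 2**self.k
        if self.data.shape != (3, side, side):
            raise ValueError(
                f"feature tensor for k={self.k} must have shape "
                f"(3, {side}, {side}), got {self.data.shape}"
            )

    @property
    def side(self) -> int:
        return 2**self.k

    @property
    def f1(self) -> np.ndarray:
        return self.data[0]

    @property
    def f2(self) -> np.ndarray:
        return self.data[1]

    @property
    def f3(self) -> np.ndarray:
        return self.data[2]


def all_kmers(k: int) -> list[str]:
    """All 4^k words over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


def _check_k(seq: GenomeSequence, k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq)} < k={k}"
        )


def _scan(
    residues: str, k: int, corners: CornerAssignment
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single streaming pass: per-word counts and coordinate sums.

    Words are indexed lexicographically (first letter most significant,
    A=0..T=3).  A non-ACGT residue leaves the CGR point where it is and
    resets the run of valid residues, so no window spanning it is counted.
    """
    n_words = 4**k
    counts = np.zeros(n_words, dtype=np.int64)
    sum_x = np.zeros(n_words, dtype=np.float64)
    sum_y = np.zeros(n_words, dtype=np.float64)
    cx, cy = corners.as_arrays()
    x = y = 0.5
    wid = 0
    run = 0
    for ch in residues:
        b = _BASE_INDEX.get(ch)
        if b is None:
            run = 0
            continue
        x = 0.5 * (x + cx[b])
        y = 0.5 * (y + cy[b])
        wid = (wid * 4 + b) % n_words
        run += 1
        if run >= k:
            counts[wid] += 1
            sum_x[wid] += x
            sum_y[wid] += y
    return counts, sum_x, sum_y


def count_kmers(seq: GenomeSequence, k: int) -> KmerCountTable:
    """Count every length-k word of ``seq`` over {A,C,G,T}.

    Windows containing an ambiguity code contribute nothing, so for an
    ambiguity-free sequence the counts sum to L - k + 1.
    """
    _check_k(seq, k)
    counts, _, _ = _scan(seq.residues, k, DEFAULT_CORNERS)
    words = all_kmers(k)
    return KmerCountTable(k=k, counts=dict(zip(words, counts.tolist())))


def cgr_trajectory(
    seq: GenomeSequence, corners: CornerAssignment = DEFAULT_CORNERS
) -> CgrTrajectory:
    """CGR points of ``seq``: from (0.5, 0.5), each A/C/G/T residue moves the
    point halfway toward its corner.  Ambiguity codes emit no point."""
    cx, cy = corners.as_arrays()
    x = y = 0.5
    points: list[tuple[float, float]] = []
    for ch in seq.residues:
        b = _BASE_INDEX.get(ch)
        if b is None:
            continue
        x = 0.5 * (x + cx[b])
        y = 0.5 * (y + cy[b])
        points.append((x, y))
    return CgrTrajectory(points=tuple(points))


def kmer_average_positions(
    seq: GenomeSequence, k: int, corners: CornerAssignment = DEFAULT_CORNERS
) -> KmerPositionTable:
    """Mean CGR endpoint of every k-mer of ``seq``.

    For a k-mer occurring N_w times, the mean of the N_w trajectory points at
    which a window equal to w ends; (0, 0) for absent k-mers.  Because all
    endpoints of w lie in w's 2^-k sub-square, so does the mean.
    """
    _check_k(seq, k)
    counts, sum_x, sum_y = _scan(seq.residues, k, corners)
    present = counts > 0
    mx = np.zeros_like(sum_x)
    my = np.zeros_like(sum_y)
    mx[present] = sum_x[present] / counts[present]
    my[present] = sum_y[present] / counts[present]
    words = all_kmers(k)
    return KmerPositionTable(
        k=k,
        mean_x=dict(zip(words, mx.tolist())),
        mean_y=dict(zip(words, my.tolist())),
    )


@lru_cache(maxsize=32)
def _cell_index_arrays(
    k: int, corners: CornerAssignment
) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) of every word id (lexicographic order) at resolution 2^-k.

    The j-th letter of a word (1-based, j=1 first) contributes its corner
    bits at binary weight 2^(j-1): the *last* letter selects the coarsest
    half of the square.  Row 0 is the top of the grid (largest y).
    """
    cx, cy = corners.as_arrays()
    cx = cx.astype(np.int64)
    cy = cy.astype(np.int64)
    ids = np.arange(4**k, dtype=np.int64)
    col = np.zeros_like(ids)
    yidx = np.zeros_like(ids)
    for j in range(1, k + 1):
        digit = (ids >> (2 * (k - j))) & 3  # j-th letter, A=0..T=3
        col += cx[digit] << (j - 1)
        yidx += cy[digit] << (j - 1)
    row = (2**k - 1) - yidx
    return row, col


def kmer_cell_index(
    word: str, k: int | None = None, corners: CornerAssignment = DEFAULT_CORNERS
) -> tuple[int, int]:
    """Grid cell (row, col) of the 2^-k sub-square holding all trajectory
    points whose suffix is ``word``; row 0 = top, col 0 = left."""
    word = word.upper()
    if k is None:
        k = len(word)
    if len(word) != k or any(ch not in _BASE_INDEX for ch in word):
        raise ValueError(f"{word!r} is not a length-{k} word over ACGT")
    wid = 0
    for ch in word:
        wid = wid * 4 + _BASE_INDEX[ch]
    rows, cols = _cell_index_arrays(k, corners)
    return int(rows[wid]), int(cols[wid])


def build_feature_tensor(
    seq: GenomeSequence,
    k: int,
    corners: CornerAssignment = DEFAULT_CORNERS,
    normalize: bool = True,
) -> FeatureTensor:
    """Assemble the 3 x 2^k x 2^k signature of ``seq``.

    Channel 1 holds k-mer counts, channels 2/3 the per-k-mer mean CGR x and
    y, each k-mer placed in its geometric grid cell.  With ``normalize``,
    each channel is independently min-max scaled to [0, 1].
    """
    _check_k(seq, k)
    counts, sum_x, sum_y = _scan(seq.residues, k, corners)
    present = counts > 0
    mx = np.zeros_like(sum_x)
    my = np.zeros_like(sum_y)
    mx[present] = sum_x[present] / counts[present]
    my[present] = sum_y[present] / counts[present]

    side = 2**k
    rows, cols = _cell_index_arrays(k, corners)
    data = np.zeros((3, side, side), dtype=np.float64)
    data[0, rows, cols] = counts
    data[1, rows, cols] = mx
    data[2, rows, cols] = my
    tensor = FeatureTensor(k=k, data=data, normalized=False, corners=corners)
    return minmax_normalize(tensor) if normalize else tensor


def minmax_normalize(tensor: FeatureTensor) -> FeatureTensor:
    """Min-max scale each channel independently to [0, 1].

    A constant channel (x_max == x_min) maps to all zeros; this only arises
    for degenerate inputs and avoids division by zero.
    """
    if tensor.normalized:
        raise ValueError("tensor is already normalized")
    data = tensor.data.copy()
    for c in range(3):
        lo = data[c].min()
        hi = data[c].max()
        if hi > lo:
            data[c] = (data[c] - lo) / (hi - lo)
        else:
            data[c] = 0.0
    return FeatureTensor(
        k=tensor.k, data=data, normalized=True, corners=tensor.corners
    )
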