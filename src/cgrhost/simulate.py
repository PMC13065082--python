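"""Class-conditioned synthetic phage-like sequences.

Host-specific phage genomes share k-mer composition biases — the signal the
CGR signature classifier exploits.  This module emulates exactly that
compositional signal (and nothing else: no genes, codon structure or
prophages) with per-class Markov chains over {A,C,G,T}:

* each host class gets an order-m chain (default m=2, the smallest order
  giving rich 3-mer-and-above structure with an analytically computable
  stationary distribution for tests);
* a ``separation`` knob in [0, 1] interpolates every transition row between
  a table shared by all classes (separation 0: classes identical, the
  classifier can only reach chance) and a class-private sparse table
  (separation 1: near-disjoint preferred k-mers, classes are separable);
* sequence lengths default to 2-10 kb, a desk-scale stand-in for phage
  genomes.

Everything is seeded and reproducible; datasets export to FASTA plus a
tab-separated label file, the exact input contract of the main pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

from .features import GenomeSequence

__all__ = [
    "HostClassSpec",
    "SyntheticDataset",
    "make_class_specs",
    "sample_sequences",
    "stationary_distribution",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class HostClassSpec:
    """An order-m Markov chain standing in for one host class.

    transitions has shape (4^m, 4): row ``s`` is the next-base distribution
    given the length-m context with lexicographic index ``s``.
    """

    name: str
    transitions: np.ndarray
    order: int = 2
    length_mean: float = 5000.0
    length_sd: float = 1500.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=np.float64)
        if t.shape != (4**self.order, 4):
            raise ValueError(
                f"transitions must be ({4**self.order}, 4) for order "
                f"{self.order}, got {t.shape}"
            )
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("each transition row must be a distribution")
        object.__setattr__(self, "transitions", t)

    @property
    def gc_content(self) -> float:
        """Stationary G+C fraction of the chain."""
        pi = stationary_distribution(self)
        ends_gc = [
            s for s in range(4**self.order) if (s % 4) in (1, 2)  # ...C or ...G
        ]
        return float(pi[ends_gc].sum())


def stationary_distribution(spec: HostClassSpec) -> np.ndarray:
    """Stationary distribution over length-m contexts (4^m states).

    For order 2 these are exactly the stationary dinucleotide probabilities,
    which long simulated sequences must converge to.
    """
    m, t = spec.order, spec.transitions
    n = 4**m
    P = np.zeros((n, n))
    for s in range(n):
        for b in range(4):
            P[s, (s * 4 + b) % n] += t[s, b]
    # principal left eigenvector by power iteration (P is a stochastic matrix)
    pi = np.full(n, 1.0 / n)
    for _ in range(10_000):
        nxt = pi @ P
        if np.abs(nxt - pi).max() < 1e-14:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


def make_class_specs(
    n_classes: int,
    separation: float,
    seed: int = 0,
    order: int = 2,
    length_mean: float = 5000.0,
    length_sd: float = 1500.0,
) -> list[HostClassSpec]:
    """Build per-class chains whose pairwise difference grows with
    ``separation``: 0 gives identical tables, 1 gives each class its own
    sparse (Dirichlet 0.15) preference table."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_ctx = 4**order
    shared = rng.dirichlet(np.full(4, 5.0), size=n_ctx)
    specs = []
    for c in range(n_classes):
        private = rng.dirichlet(np.full(4, 0.15), size=n_ctx)
        table = (1.0 - separation) * shared + separation * private
        specs.append(
            HostClassSpec(
                name=f"host_{c}",
                transitions=table,
                order=order,
                length_mean=length_mean,
                length_sd=length_sd,
            )
        )
    return specs


@dataclass(frozen=True)
class SyntheticDataset:
    """Labelled sequences plus the specs and seed that produced them."""

    records: tuple[tuple[GenomeSequence, str], ...]
    seed: int
    specs: tuple[HostClassSpec, ...] = field(repr=False)

    @property
    def sequences(self) -> list[GenomeSequence]:
        return [s for s, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [l for _, l in self.records]

    def write_fasta(self, handle: TextIO, width: int = 70) -> None:
        for seq, _ in self.records:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")

    def write_labels(self, handle: TextIO) -> None:
        for seq, label in self.records:
            handle.write(f"{seq.id}\t{label}\n")


def _sample_one(
    spec: HostClassSpec, length: int, rng: np.random.Generator
) -> str:
    m = spec.order
    cum = spec.transitions.cumsum(axis=1)
    bases = list(rng.integers(0, 4, size=m))
    ctx = 0
    for b in bases:
        ctx = (ctx * 4 + int(b)) % (4**m)
    us = rng.random(max(length - m, 0))
    for u in us:
        b = int(np.searchsorted(cum[ctx], u, side="right"))
        b = min(b, 3)
        bases.append(b)
        ctx = (ctx * 4 + b) % (4**m)
    return "".join(_BASES[b] for b in bases[:length])


def sample_sequences(
    specs: Sequence[HostClassSpec],
    n_per_class: int,
    length: int | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw ``n_per_class`` sequences from each class chain.

    With ``length`` None, lengths are drawn per sequence from the spec's
    normal(length_mean, length_sd), truncated below at 200 bases.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[GenomeSequence, str]] = []
    for spec in specs:
        for i in range(n_per_class):
            if length is None:
                ln = max(200, int(round(rng.normal(spec.length_mean, spec.length_sd))))
            else:
                ln = length
            residues = _sample_one(spec, ln, rng)
            records.append(
                (GenomeSequence(id=f"{spec.name}_seq{i}", residues=residues), spec.name)
            )
    return SyntheticDataset(records=tuple(records), seed=seed, specs=tuple(specs))
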