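"""Shared fixtures: the hand-checkable reference computation and
independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from cgrhost.features import DEFAULT_CORNERS, CornerAssignment, GenomeSequence

# Fully hand-verifiable reference computation: S = AGTCGTTACA, k = 2,
# corners A=(0,0), C=(0,1), G=(1,1), T=(1,0).  Every value below is an exact
# binary fraction obtained by iterating the midpoint map by hand.
WORKED_SEQ = "AGTCGTTACA"
WORKED_K = 2

WORKED_TRAJECTORY = [
    (0.25, 0.25),
    (0.625, 0.625),
    (0.8125, 0.3125),
    (0.40625, 0.65625),
    (0.703125, 0.828125),
    (0.8515625, 0.4140625),
    (0.92578125, 0.20703125),
    (0.462890625, 0.103515625),
    (0.2314453125, 0.5517578125),
    (0.11572265625, 0.27587890625),
]

WORKED_COUNTS = {
    "AA": 0, "AC": 1, "AG": 1, "AT": 0,
    "CA": 1, "CC": 0, "CG": 1, "CT": 0,
    "GA": 0, "GC": 0, "GG": 0, "GT": 2,
    "TA": 1, "TC": 1, "TG": 0, "TT": 1,
}

WORKED_MEAN_POSITIONS = {
    "AA": (0.0, 0.0),
    "AC": (0.2314453125, 0.5517578125),
    "AG": (0.625, 0.625),
    "AT": (0.0, 0.0),
    "CA": (0.11572265625, 0.27587890625),
    "CC": (0.0, 0.0),
    "CG": (0.703125, 0.828125),
    "CT": (0.0, 0.0),
    "GA": (0.0, 0.0),
    "GC": (0.0, 0.0),
    "GG": (0.0, 0.0),
    "GT": (0.83203125, 0.36328125),
    "TA": (0.462890625, 0.103515625),
    "TC": (0.40625, 0.65625),
    "TG": (0.0, 0.0),
    "TT": (0.92578125, 0.20703125),
}


@pytest.fixture
def worked_seq() -> GenomeSequence:
    return GenomeSequence(id="worked", residues=WORKED_SEQ)


def oracle_positions(
    residues: str, k: int, corners: CornerAssignment = DEFAULT_CORNERS
) -> tuple[dict[str, int], dict[str, float], dict[str, float]]:
    """Brute-force oracle: materialize every prefix, recompute its CGR
    endpoint from scratch, and group endpoints by the k-suffix window.

    Independent of the streaming implementation: no rolling state, no cell
    arithmetic.  Windows containing a non-ACGT residue are skipped; non-ACGT
    residues contribute no midpoint step.
    """
    residues = residues.upper()
    counts: dict[str, int] = {}
    sums: dict[str, list[float]] = {}
    for i in range(k, len(residues) + 1):
        window = residues[i - k : i]
        if any(ch not in "ACGT" for ch in window):
            continue
        x, y = 0.5, 0.5
        for ch in residues[:i]:
            if ch in "ACGT":
                cx, cy = corners.corner(ch)
                x = 0.5 * (x + cx)
                y = 0.5 * (y + cy)
        counts[window] = counts.get(window, 0) + 1
        sx, sy = sums.get(window, [0.0, 0.0])
        sums[window] = [sx + x, sy + y]
    mean_x = {w: sums[w][0] / counts[w] for w in counts}
    mean_y = {w: sums[w][1] / counts[w] for w in counts}
    return counts, mean_x, mean_y


def random_dna(rng: np.random.Generator, length: int, ambiguity: float = 0.0) -> str:
    """Random sequence over ACGT, optionally salted with N's."""
    bases = rng.choice(list("ACGT"), size=length)
    if ambiguity > 0:
        mask = rng.random(length) < ambiguity
        bases[mask] = "N"
    return "".join(bases)
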