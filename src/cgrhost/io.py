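"""Readers and writers: FASTA, label tables, and the tensor store."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .features import CornerAssignment, FeatureTensor, GenomeSequence

__all__ = [
    "LabelTable",
    "read_fasta",
    "read_labels",
    "save_tensors",
    "load_tensors",
]

logger = logging.getLogger("cgrhost")


@dataclass(frozen=True)
class LabelTable:
    """Sequence id -> host taxon at one taxonomy level."""

    mapping: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, seq_id: str) -> str:
        return self.mapping[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.mapping

    def taxa(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def check_against(self, sequence_ids: Sequence[str]) -> None:
        """Warn (not fail) on ids missing on either side."""
        ids = set(sequence_ids)
        unlabeled = ids - set(self.mapping)
        orphaned = set(self.mapping) - ids
        if unlabeled:
            warnings.warn(
                f"{len(unlabeled)} sequence(s) have no label, e.g. "
                f"{sorted(unlabeled)[:3]}",
                stacklevel=2,
            )
        if orphaned:
            warnings.warn(
                f"{len(orphaned)} label(s) have no sequence, e.g. "
                f"{sorted(orphaned)[:3]}",
                stacklevel=2,
            )


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Residues are uppercased; record order is preserved; IUPAC ambiguity
    codes pass through (featurization skips windows containing them).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        if not str(rec.seq):
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        out.append(GenomeSequence(id=rec.id, residues=str(rec.seq)))
    return out


def read_labels(path) -> LabelTable:
    """Read a two-column tab-separated id -> taxon table.

    Duplicate ids are an error (listed); empty taxon names are an error.
    """
    mapping: dict[str, str] = {}
    dups: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            seq_id, taxon = parts[0].strip(), parts[1].strip()
            if not seq_id or not taxon:
                raise ValueError(f"{path}:{lineno}: empty id or taxon name")
            if seq_id in mapping:
                dups.append(seq_id)
            mapping[seq_id] = taxon
    if dups:
        raise ValueError(f"duplicate sequence ids in {path}: {sorted(set(dups))}")
    if not mapping:
        raise ValueError(f"no label rows found in {path}")
    return LabelTable(mapping=mapping)


def save_tensors(path, tensors: Mapping[str, FeatureTensor]) -> None:
    """Write an id-keyed tensor container (.npz) plus a JSON sidecar
    recording k, corner assignment and normalization flag."""
    if not tensors:
        raise ValueError("no tensors to save")
    first = next(iter(tensors.values()))
    for tid, t in tensors.items():
        if t.k != first.k or t.normalized != first.normalized:
            raise ValueError(f"tensor {tid!r} disagrees on k/normalization")
        if t.corners != first.corners:
            raise ValueError(f"tensor {tid!r} has a different corner assignment")
    path = Path(path)
    ids = list(tensors)
    np.savez_compressed(
        path, **{f"t{i}": tensors[tid].data for i, tid in enumerate(ids)}
    )
    sidecar = {
        "k": first.k,
        "corners": first.corners.to_dict(),
        "normalized": first.normalized,
        "ids": ids,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    logger.info("wrote %d tensors (k=%d) to %s", len(ids), first.k, path)


def load_tensors(path) -> dict[str, FeatureTensor]:
    """Reload a tensor container written by :func:`save_tensors`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    corners = CornerAssignment.from_dict(sidecar["corners"])
    out: dict[str, FeatureTensor] = {}
    with np.load(path) as npz:
        for i, tid in enumerate(sidecar["ids"]):
            out[tid] = FeatureTensor(
                k=sidecar["k"],
                data=npz[f"t{i}"],
                normalized=sidecar["normalized"],
                corners=corners,
            )
    return out
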