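"""FASTA / pair-list input and prediction output.

Protein sequences are read with Biopython, upper-cased, and validated
against the 20 canonical one-letter codes. Non-canonical residues
(X, B, Z, U, O, gaps, stops) are handled by a configurable policy:

``drop``
    remove the residue and recompute the length (default);
``error``
    raise ``ValueError``;
``zero``
    keep the residue in the sequence — downstream it contributes an
    all-zero adjacency column and is skipped by dipeptide counting.

Pair lists are delimited text with at least three columns
(id_a, id_b, label in {0, 1}); tab or comma delimiters are auto-detected
and an optional header row is recognised by a non-numeric label column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import CANONICAL_AA

logger = logging.getLogger(__name__)

RESIDUE_POLICIES = ("drop", "error", "zero")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus a validated amino-acid sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class Pair:
    """One labelled protein pair: interaction (1) or non-interaction (0)."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1")


@dataclass
class PairDataset:
    """Aligned proteins and labelled pairs, the unit the pipeline consumes."""

    proteins: dict[str, ProteinRecord]
    pairs: list[Pair]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def protein_ids(self, pairs: Iterable[Pair] | None = None) -> list[str]:
        """Unique protein ids used by *pairs* (default: all), in first-seen order."""
        seen: dict[str, None] = {}
        for p in self.pairs if pairs is None else pairs:
            seen.setdefault(p.id_a)
            seen.setdefault(p.id_b)
        return list(seen)


def clean_sequence(raw: str, protein_id: str, policy: str = "drop") -> str:
    """Upper-case *raw* and apply the non-canonical residue *policy*."""
    if policy not in RESIDUE_POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; choose from {RESIDUE_POLICIES}")
    seq = raw.upper().replace(" ", "")
    bad = [c for c in seq if c not in CANONICAL_AA]
    if bad:
        if policy == "error":
            raise ValueError(
                f"protein {protein_id!r}: non-canonical residues {sorted(set(bad))}"
            )
        if policy == "drop":
            logger.warning(
                "protein %s: dropping %d non-canonical residue(s) %s",
                protein_id, len(bad), sorted(set(bad)),
            )
            seq = "".join(c for c in seq if c in CANONICAL_AA)
        # policy == "zero": keep as-is, features handle it
    return seq


def read_fasta(path: str | Path, residue_policy: str = "drop") -> dict[str, ProteinRecord]:
    """Read a FASTA file into an id -> :class:`ProteinRecord` mapping.

    Duplicate ids and sequences that are empty after cleaning are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, ProteinRecord] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in records:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seq = clean_sequence(str(entry.seq), entry.id, residue_policy)
        if not seq:
            raise ValueError(f"protein {entry.id!r}: empty sequence after cleaning")
        records[entry.id] = ProteinRecord(id=entry.id, seq=seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, ProteinRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records.values():
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_pairs(path: str | Path, proteins: Mapping[str, ProteinRecord]) -> list[Pair]:
    """Read a delimited (id_a, id_b, label) pair list, resolving ids.

    Raises on ids absent from *proteins* and on non-binary labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[Pair] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return pairs
    delim = _sniff_delimiter(lines[0])
    start = 0
    first = lines[0].split(delim)
    if len(first) >= 3:
        try:
            float(first[2].strip())
        except ValueError:
            start = 1  # non-numeric label column -> header row
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cols = [c.strip() for c in line.split(delim)]
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(cols)}")
        id_a, id_b, raw_label = cols[0], cols[1], cols[2]
        for pid in (id_a, id_b):
            if pid not in proteins:
                raise KeyError(f"{path}:{lineno}: unknown protein id {pid!r}")
        if raw_label not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {raw_label!r}")
        pairs.append(Pair(id_a, id_b, int(raw_label)))
    return pairs


def write_pairs(pairs: Sequence[Pair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def write_predictions(
    pairs: Sequence[Pair],
    predicted: Sequence[int],
    scores: Sequence[float],
    path: str | Path,
    true_labels: Sequence[int] | None = None,
) -> None:
    """Write one TSV row per pair: id_a, id_b, label, predicted, score."""
    if not (len(pairs) == len(predicted) == len(scores)):
        raise ValueError("pairs, predicted and scores must be aligned")
    if true_labels is None:
        true_labels = [p.label for p in pairs]
    with Path(path).open("w") as fh:
        fh.write("id_a\tid_b\tlabel\tpredicted\tscore\n")
        for pair, t, pred, s in zip(pairs, true_labels, predicted, scores):
            fh.write(f"{pair.id_a}\t{pair.id_b}\t{t}\t{pred}\t{s:.10g}\n")
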