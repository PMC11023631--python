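"""Validated nucleotide sequences and FASTA / group-label input.

Sequences are plain A/C/G/T strings with an identifier and an optional group
label (e.g. ``"SCI"`` / ``"MI"`` for sedentary chromosomal vs mobile integron
integrases).  Validation is strict by default: ambiguity codes would silently
break homopolymer runs and bias run-length spectra, so they are rejected
rather than skipped over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class SequenceValidationError(ValueError):
    """Raised when a sequence contains residues outside {A, C, G, T}."""


@dataclass(frozen=True)
class NucSequence:
    """A validated nucleotide sequence.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within a loaded set.
    residues:
        Upper-case A/C/G/T string, length >= 1.
    group:
        Optional group label (e.g. ``"SCI"``, ``"MI"``).
    source:
        Optional provenance note (file name, generator call, ...).
    """

    id: str
    residues: str
    group: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        residues = self.residues.upper().replace("U", "T")
        if "U" in self.residues.upper():
            logger.warning("sequence %s: RNA input, U mapped to T", self.id)
        if not residues:
            raise SequenceValidationError(f"sequence {self.id!r} is empty")
        for pos, base in enumerate(residues):
            if base not in VALID_BASES:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: invalid residue {base!r} at "
                    f"position {pos + 1} (1-based); only A/C/G/T accepted"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def with_group(self, group: str) -> "NucSequence":
        return NucSequence(self.id, self.residues, group=group, source=self.source)


def read_fasta(
    path: str | Path,
    group: str | None = None,
    groups: Mapping[str, str] | None = None,
    on_invalid: str = "error",
) -> list[NucSequence]:
    """Load sequences from a (multi-)FASTA file.

    ``group`` applies one label to every record; ``groups`` maps record ids to
    labels (e.g. loaded with :func:`read_group_table`).  ``on_invalid`` is
    ``"error"`` (default) or ``"drop"``: dropping logs a warning per discarded
    sequence instead of raising.
    """
    if on_invalid not in ("error", "drop"):
        raise ValueError("on_invalid must be 'error' or 'drop'")
    seqs: list[NucSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        seen.add(record.id)
        label = groups.get(record.id) if groups else group
        try:
            seqs.append(
                NucSequence(record.id, str(record.seq), group=label, source=str(path))
            )
        except SequenceValidationError as exc:
            if on_invalid == "error":
                raise
            logger.warning("dropping sequence %s: %s", record.id, exc)
    return seqs


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sequence id, group label)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected two tab-separated columns")
            table[fields[0]] = fields[1]
    return table


def require_groups(seqs: Sequence[NucSequence]) -> None:
    """Raise if any sequence lacks a group label, listing offending ids."""
    missing = [s.id for s in seqs if s.group is None]
    if missing:
        raise ValueError(f"sequences without group label: {', '.join(missing)}")
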