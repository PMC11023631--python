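"""Maximal homopolymer runs, run-length spectra, and barcode tracks.

A homopolymer run is a maximal stretch of identical consecutive nucleotides;
``ATTTAACC`` decomposes into A, TTT, AA, CC.  The run list of a sequence is
sorted, non-overlapping and tiles the sequence exactly, so run lengths sum to
the sequence length and joining the runs reproduces the input.

Spectra count runs by length with a top-code bin: all runs of length >= Lmax
are collected in the Lmax bin (the analyses report lengths 1..10).  Raw
(un-top-coded) lengths are retained for conservation checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import NucSequence

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = np.array(list("ACGT"))


def encode(residues: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        pos = int(np.flatnonzero(codes == 255)[0])
        raise ValueError(f"invalid residue {residues[pos]!r} at position {pos + 1}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_BASE[codes])


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical bases, 0-based half-open coordinates."""

    base: str
    start: int
    length: int

    @property
    def end_exclusive(self) -> int:
        return self.start + self.length

    def positions_1based(self) -> tuple[int, int]:
        """(first, last) position of the run, 1-based inclusive."""
        return self.start + 1, self.end_exclusive


def split_runs(seq: NucSequence | str) -> list[HomopolymerRun]:
    """Decompose a sequence into its maximal homopolymer runs, left to right.

    >>> [(r.base, r.length) for r in split_runs("ATTTAACC")]
    [('A', 1), ('T', 3), ('A', 2), ('C', 2)]
    """
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    codes = encode(residues)
    starts = np.flatnonzero(np.concatenate(([True], codes[1:] != codes[:-1])))
    ends = np.append(starts[1:], codes.size)
    return [
        HomopolymerRun(residues[s], int(s), int(e - s))
        for s, e in zip(starts, ends)
    ]


def join_runs(runs: Sequence[HomopolymerRun]) -> str:
    """Inverse of :func:`split_runs` (round-trip identity)."""
    return "".join(r.base * r.length for r in runs)


@dataclass(frozen=True)
class RunSpectrum:
    """Run counts by length bin, with all lengths >= ``Lmax`` top-coded at Lmax.

    ``raw_counts`` keeps the un-top-coded length histogram so the mass
    conservation law (sum of length x count = total sequence length) can be
    verified after binning.
    """

    counts: dict[int, int]
    Lmax: int
    total_runs: int
    raw_counts: dict[int, int] = field(default_factory=dict)

    @property
    def has_proportions(self) -> bool:
        return self.total_runs > 0

    @property
    def proportions(self) -> dict[int, float]:
        """Fraction of runs per length bin; empty mapping when no runs."""
        if not self.has_proportions:
            return {}
        return {L: c / self.total_runs for L, c in self.counts.items()}

    @property
    def total_bases(self) -> int:
        return sum(L * c for L, c in self.raw_counts.items())

    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(L, 0) for L in range(1, self.Lmax + 1)])

    def proportion_vector(self) -> np.ndarray:
        """Proportions over bins 1..Lmax (zeros included); NaN when no runs."""
        if not self.has_proportions:
            return np.full(self.Lmax, np.nan)
        return self.count_vector() / self.total_runs


def spectrum(runs: Iterable[HomopolymerRun], Lmax: int = 10) -> RunSpectrum:
    """Histogram run lengths into bins 1..Lmax (>= Lmax top-coded).

    An empty run list yields ``total_runs == 0`` with undefined proportions
    (flagged via ``has_proportions``), not an exception.
    """
    if Lmax < 1:
        raise ValueError("Lmax must be >= 1")
    raw = Counter(r.length for r in runs)
    counts: Counter[int] = Counter()
    for L, c in raw.items():
        counts[min(L, Lmax)] += c
    return RunSpectrum(
        counts=dict(sorted(counts.items())),
        Lmax=Lmax,
        total_runs=sum(raw.values()),
        raw_counts=dict(sorted(raw.items())),
    )


def pooled_spectrum(seqs: Sequence[NucSequence], Lmax: int = 10) -> RunSpectrum:
    """Spectrum over the concatenated run lists of several sequences.

    Runs never span sequence boundaries; pooling is additive over the
    per-sequence spectra.
    """
    if not seqs:
        raise ValueError("pooled_spectrum requires at least one sequence")
    all_runs: list[HomopolymerRun] = []
    for seq in seqs:
        all_runs.extend(split_runs(seq))
    return spectrum(all_runs, Lmax=Lmax)


@dataclass(frozen=True)
class BarcodeTrack:
    """Per-position run-length track for barcode-style rendering.

    ``values[i]`` is the length of the maximal run covering position ``i`` if
    that length >= ``min_len``, else 0.  ``max_len`` is a display saturation
    only (runs of 8+ all render at the darkest shade); stored values are the
    true run lengths.
    """

    gene_id: str
    values: tuple[int, ...]
    min_len: int = 3
    max_len: int = 8

    def saturated(self) -> np.ndarray:
        """Values capped at ``max_len`` for rendering."""
        return np.minimum(np.array(self.values), self.max_len)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "position_1based": np.arange(1, len(self.values) + 1),
                "run_length": self.values,
            }
        )


def barcode_track(
    seq: NucSequence, min_len: int = 3, max_len: int = 8
) -> BarcodeTrack:
    """Per-position homopolymer barcode (runs shorter than ``min_len`` -> 0)."""
    values = np.zeros(len(seq.residues), dtype=int)
    for run in split_runs(seq):
        if run.length >= min_len:
            values[run.start : run.end_exclusive] = run.length
    return BarcodeTrack(seq.id, tuple(int(v) for v in values), min_len, max_len)


def spectra_frame(spectra: Mapping[str, RunSpectrum]) -> pd.DataFrame:
    """Long-format table (group, length_bin, count, proportion) for TSV export."""
    rows = []
    for group, spec in spectra.items():
        props = spec.proportion_vector()
        for L in range(1, spec.Lmax + 1):
            rows.append(
                {
                    "group": group,
                    "length_bin": L,
                    "count": spec.counts.get(L, 0),
                    "proportion": props[L - 1],
                }
            )
    return pd.DataFrame(rows)
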