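"""Composition-preserving shuffle null model for homopolymer spectra.

The theoretical ("theo") spectrum of a sequence is the mean run-length
spectrum over uniformly random permutations of its nucleotides: each shuffle
preserves the base multiset exactly, so the null keeps composition fixed and
destroys only the ordering.  The Monte Carlo estimator (default 10,000
replicates) is backed by two independent oracles used in the test suite:

* exact enumeration of all distinct permutations for short sequences, and
* a closed form for the expected number of maximal runs of each length in an
  i.i.d. sequence, itself validated against exhaustive enumeration of all
  ``4**n`` sequences for small ``n``.

Replicate permutations are drawn by argsorting i.i.d. uniform keys, which is
uniform over permutations (ties have probability zero); run counting is
vectorized across replicates.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .runs import encode
from .sequences import NucSequence

BASES = "ACGT"


@dataclass(frozen=True)
class NullSpectrum:
    """Expected run-length spectrum under the shuffle (or enumeration) null.

    ``mean_counts[L]`` is the mean number of runs in bin ``L`` (lengths
    >= Lmax top-coded at Lmax); ``mc_sd[L]`` the per-bin standard deviation
    across replicates (population SD).  ``proportions`` normalizes the mean
    counts by the mean total number of runs.
    """

    mean_counts: dict[int, float]
    mc_sd: dict[int, float]
    n_reps: int
    Lmax: int
    seed: int | None
    mean_total_runs: float

    @property
    def proportions(self) -> dict[int, float]:
        if self.mean_total_runs == 0:
            return {}
        return {L: c / self.mean_total_runs for L, c in self.mean_counts.items()}

    def mean_vector(self) -> np.ndarray:
        return np.array([self.mean_counts.get(L, 0.0) for L in range(1, self.Lmax + 1)])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.mc_sd.get(L, 0.0) for L in range(1, self.Lmax + 1)])


def sequence_rng(root_seed: int, seq_id: str) -> np.random.Generator:
    """Deterministic per-sequence stream derived from (root seed, sequence id).

    The id is hashed with SHA-256 so the stream does not depend on load order
    or on Python's randomized string hashing.
    """
    digest = hashlib.sha256(seq_id.encode()).digest()
    id_words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([root_seed, *id_words]))


def shuffle_sequence(
    seq: NucSequence, rng: np.random.Generator
) -> NucSequence:
    """Uniformly random permutation of the residues (base multiset preserved)."""
    codes = encode(seq.residues)
    permuted = rng.permutation(codes)
    residues = "".join("ACGT"[c] for c in permuted)
    return NucSequence(seq.id, residues, group=seq.group, source="shuffle")


def _run_bin_counts(mat: np.ndarray, Lmax: int) -> np.ndarray:
    """Per-row top-coded run-length histograms of a (reps x n) code matrix.

    Rows are independent replicate sequences; runs never span row boundaries.
    Returns an int64 array of shape (reps, Lmax), column j = bin length j+1.
    """
    n_reps, n = mat.shape
    flat = mat.ravel()
    change = np.empty(flat.size, dtype=bool)
    change[0] = True
    np.not_equal(flat[1:], flat[:-1], out=change[1:])
    change[::n] = True
    starts = np.flatnonzero(change)
    lengths = np.diff(starts, append=flat.size)
    rows = starts // n
    bins = np.minimum(lengths, Lmax)
    idx = rows * Lmax + (bins - 1)
    return np.bincount(idx, minlength=n_reps * Lmax).reshape(n_reps, Lmax)


def null_spectrum(
    seq: NucSequence,
    n_reps: int = 10_000,
    Lmax: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    chunk_size: int | None = None,
) -> NullSpectrum:
    """Monte Carlo shuffle null: mean and SD of per-bin run counts.

    The same split/enumerate logic is applied to each shuffled replicate as to
    the observed sequence.  Reproducible bit-exactly for fixed ``seed``,
    ``n_reps`` and input.  ``rng`` overrides ``seed`` when supplied (used for
    per-sequence streams derived from a root seed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if Lmax < 1:
        raise ValueError("Lmax must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = encode(seq.residues)
    n = codes.size
    if chunk_size is None:
        chunk_size = max(1, min(n_reps, 4_000_000 // max(n, 1)))
    sums = np.zeros(Lmax)
    sumsq = np.zeros(Lmax)
    total_runs = 0.0
    done = 0
    while done < n_reps:
        reps = min(chunk_size, n_reps - done)
        keys = rng.random((reps, n))
        order = np.argsort(keys, axis=1, kind="stable")
        shuffled = codes[order]
        counts = _run_bin_counts(shuffled, Lmax)
        sums += counts.sum(axis=0)
        sumsq += (counts.astype(np.float64) ** 2).sum(axis=0)
        total_runs += counts.sum()
        done += reps
    mean = sums / n_reps
    var = np.maximum(sumsq / n_reps - mean**2, 0.0)
    return NullSpectrum(
        mean_counts={L: float(mean[L - 1]) for L in range(1, Lmax + 1)},
        mc_sd={L: float(math.sqrt(var[L - 1])) for L in range(1, Lmax + 1)},
        n_reps=n_reps,
        Lmax=Lmax,
        seed=seed,
        mean_total_runs=float(total_runs / n_reps),
    )


def count_distinct_permutations(residues: str) -> int:
    n = len(residues)
    total = math.factorial(n)
    for base in BASES:
        total //= math.factorial(residues.count(base))
    return total


def exact_null_by_enumeration(
    seq: NucSequence | str, Lmax: int = 10, cap: int = 100_000
) -> NullSpectrum:
    """Exact null spectrum by averaging over all distinct permutations.

    Distinct arrangements of a fixed multiset all carry equal weight (each
    corresponds to the same number of orderings of the n! labelled shuffles),
    so the uniform average over distinct permutations equals the expectation
    under uniformly random shuffling.  Refuses inputs with more than ``cap``
    distinct permutations; use :func:`null_spectrum` for those.
    """
    from sympy.utilities.iterables import multiset_permutations

    residues = seq.residues if isinstance(seq, NucSequence) else seq
    n_distinct = count_distinct_permutations(residues)
    if n_distinct > cap:
        raise ValueError(
            f"{n_distinct} distinct permutations exceed cap {cap}; "
            "use the Monte Carlo null_spectrum instead"
        )
    codes = encode(residues)
    counts = np.empty((n_distinct, Lmax), dtype=np.int64)
    for i, perm in enumerate(multiset_permutations(list(codes))):
        counts[i] = _run_bin_counts(np.array([perm], dtype=np.uint8), Lmax)[0]
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0)
    return NullSpectrum(
        mean_counts={L: float(mean[L - 1]) for L in range(1, Lmax + 1)},
        mc_sd={L: float(sd[L - 1]) for L in range(1, Lmax + 1)},
        n_reps=n_distinct,
        Lmax=Lmax,
        seed=None,
        mean_total_runs=float(counts.sum(axis=1).mean()),
    )


def _check_composition(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size != 4:
        raise ValueError("composition must be a length-4 probability vector (A,C,G,T)")
    if (p < 0).any() or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("composition probabilities must be >= 0 and sum to 1")
    return p


def iid_expected_runs(composition: Sequence[float], n: int, L: int) -> float:
    """Expected number of maximal runs of length exactly L in an i.i.d. sequence.

    For ``L < n`` the count decomposes into interior runs (flanked on both
    sides by a different base) and the two edge positions (flanked on one
    side only)::

        sum_b [ (n - L - 1) * p_b**L * (1 - p_b)**2  +  2 * p_b**L * (1 - p_b) ]

    with the interior term taken as 0 when ``n - L - 1 < 0``; for ``L == n``
    the whole sequence must be one base: ``sum_b p_b**n``.  Validated against
    exhaustive enumeration of all 4**n sequences for n <= 8 (see
    :func:`iid_expected_runs_by_enumeration` and the test suite).
    """
    p = _check_composition(composition)
    if not 1 <= L <= n:
        raise ValueError(f"L must satisfy 1 <= L <= n (got L={L}, n={n})")
    if L == n:
        return float(np.sum(p**n))
    interior = max(n - L - 1, 0)
    return float(np.sum(interior * p**L * (1 - p) ** 2 + 2 * p**L * (1 - p)))


def iid_expected_spectrum(
    composition: Sequence[float], n: int, Lmax: int = 10
) -> dict[int, float]:
    """Closed-form expected top-coded spectrum for an i.i.d. sequence.

    Bin ``Lmax`` collects the expected counts of all lengths >= Lmax.
    """
    expected = {L: iid_expected_runs(composition, n, L) for L in range(1, min(Lmax, n) + 1)}
    if Lmax <= n:
        expected[Lmax] = sum(
            iid_expected_runs(composition, n, L) for L in range(Lmax, n + 1)
        )
    for L in range(n + 1, Lmax + 1):
        expected.setdefault(L, 0.0)
    return expected


def iid_expected_runs_by_enumeration(
    composition: Sequence[float], n: int, Lmax: int | None = None
) -> dict[int, float]:
    """Brute-force oracle: exact expectation by enumerating all 4**n sequences.

    Each sequence is weighted by its i.i.d. probability under ``composition``.
    Returns un-top-coded expected counts for lengths 1..n (or binned at
    ``Lmax`` when given).  Exponential in ``n``; intended for n <= 8.
    """
    p = _check_composition(composition)
    if n > 10:
        raise ValueError("enumeration oracle limited to n <= 10")
    n_seqs = 4**n
    idx = np.arange(n_seqs)
    mat = ((idx[:, None] // (4 ** np.arange(n)[::-1])) % 4).astype(np.uint8)
    weights = np.prod(p[mat], axis=1)
    bin_max = Lmax if Lmax is not None else n
    counts = _run_bin_counts(mat, bin_max)
    expected = weights @ counts
    return {L: float(expected[L - 1]) for L in range(1, bin_max + 1)}
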