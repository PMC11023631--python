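"""Shuffle null model: Monte Carlo, exact enumeration, and closed form."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyslip import (
    NucSequence,
    exact_null_by_enumeration,
    iid_expected_runs,
    iid_expected_runs_by_enumeration,
    iid_expected_spectrum,
    null_spectrum,
    sequence_rng,
    shuffle_sequence,
    spectrum,
    split_runs,
)

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def test_shuffle_preserves_base_multiset(rng):
    seq = NucSequence("s", "ATTTAACCGGGGTTAC")
    for _ in range(20):
        shuffled = shuffle_sequence(seq, rng)
        assert Counter(shuffled.residues) == Counter(seq.residues)


def test_shuffle_of_homogeneous_sequence_is_identity(rng):
    seq = NucSequence("s", "AAAA")
    assert shuffle_sequence(seq, rng).residues == "AAAA"


def test_shuffle_is_uniform_over_two_permutations():
    rng = np.random.default_rng(7)
    seq = NucSequence("s", "AC")
    draws = Counter(shuffle_sequence(seq, rng).residues for _ in range(10_000))
    # exact binomial: p=0.5, SE=sqrt(0.25/10000)=0.005
    assert abs(draws["AC"] / 10_000 - 0.5) <= 3 * 0.005


def test_null_spectrum_degenerate_composition():
    null = null_spectrum(NucSequence("s", "AAAA"), n_reps=50, Lmax=10, seed=0)
    assert null.mean_counts[4] == 1.0
    assert all(v == 0 for L, v in null.mean_counts.items() if L != 4)
    assert all(v == 0 for v in null.mc_sd.values())


def test_null_spectrum_matches_exact_enumeration_within_3se():
    seq = NucSequence("s", "AAAATTTT")
    null = null_spectrum(seq, n_reps=10_000, Lmax=8, seed=11)
    exact = exact_null_by_enumeration(seq, Lmax=8)
    assert exact.n_reps == 70  # 8! / (4! 4!)
    for L in range(1, 9):
        se = null.mc_sd[L] / math.sqrt(null.n_reps)
        assert abs(null.mean_counts[L] - exact.mean_counts[L]) <= max(3 * se, 1e-12)


def test_null_spectrum_seed_determinism():
    seq = NucSequence("s", "ATTTAACCGGGGTTACAGCT")
    a = null_spectrum(seq, n_reps=200, seed=42)
    b = null_spectrum(seq, n_reps=200, seed=42)
    assert a == b
    c = null_spectrum(seq, n_reps=200, seed=43)
    assert c.mean_counts != a.mean_counts


def test_per_sequence_streams_do_not_depend_on_order():
    a1 = sequence_rng(5, "geneA").random(4)
    _ = sequence_rng(5, "geneB").random(4)
    a2 = sequence_rng(5, "geneA").random(4)
    assert np.array_equal(a1, a2)


def test_null_spectrum_conserves_sequence_length():
    seq = NucSequence("s", "ACGTACGGGTTTACCAGT")
    n = len(seq.residues)
    null = null_spectrum(seq, n_reps=300, Lmax=n, seed=3)  # no top-coding
    assert sum(L * c for L, c in null.mean_counts.items()) == pytest.approx(n)


def test_null_spectrum_rejects_bad_n_reps():
    with pytest.raises(ValueError):
        null_spectrum(NucSequence("s", "ACGT"), n_reps=0)


def test_exact_enumeration_worked_examples():
    ac = exact_null_by_enumeration("AC", Lmax=4)
    assert ac.mean_counts[1] == 2.0
    assert ac.mc_sd[1] == 0.0
    aac = exact_null_by_enumeration("AAC", Lmax=4)
    assert aac.mean_counts[1] == pytest.approx(5 / 3)
    assert aac.mean_counts[2] == pytest.approx(2 / 3)


def test_exact_enumeration_refuses_above_cap():
    with pytest.raises(ValueError, match="Monte Carlo"):
        exact_null_by_enumeration("ACGT" * 6, cap=1000)


def test_monte_carlo_agrees_with_enumeration_on_random_short_panel(rng, make_random_sequence):
    for i in range(20):
        residues = make_random_sequence(rng, int(rng.integers(2, 9)))
        seq = NucSequence(f"s{i}", residues)
        null = null_spectrum(seq, n_reps=10_000, Lmax=8, seed=100 + i)
        exact = exact_null_by_enumeration(seq, Lmax=8)
        for L in range(1, 9):
            se = null.mc_sd[L] / math.sqrt(null.n_reps)
            assert abs(null.mean_counts[L] - exact.mean_counts[L]) <= max(3 * se, 1e-12)


@pytest.mark.parametrize(
    "n,L,expected",
    [
        (1, 1, 1.0),
        (2, 2, 0.25),  # 4 of 16 dinucleotides are doubles
        (2, 1, 1.5),   # 12/16 sequences have two length-1 runs
    ],
)
def test_iid_expected_runs_small_cases(n, L, expected):
    assert iid_expected_runs(UNIFORM, n, L) == pytest.approx(expected, abs=1e-12)


def test_iid_expected_runs_parameter_errors():
    with pytest.raises(ValueError):
        iid_expected_runs((0.5, 0.5, 0.5, 0.5), 10, 2)
    with pytest.raises(ValueError):
        iid_expected_runs(UNIFORM, 5, 6)
    with pytest.raises(ValueError):
        iid_expected_runs(UNIFORM, 5, 0)


@pytest.mark.parametrize("composition", [UNIFORM, (0.4, 0.1, 0.2, 0.3)])
@pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
def test_iid_formula_matches_exhaustive_enumeration(composition, n):
    """Closed form vs brute-force enumeration of all 4**n sequences (n<=6 here;
    the full n<=8 sweep runs in the acceptance suite)."""
    enum = iid_expected_runs_by_enumeration(composition, n)
    for L in range(1, n + 1):
        assert iid_expected_runs(composition, n, L) == pytest.approx(enum[L], abs=1e-9)


def test_iid_expected_spectrum_top_code_collects_tail():
    full = {L: iid_expected_runs(UNIFORM, 30, L) for L in range(1, 31)}
    spec = iid_expected_spectrum(UNIFORM, 30, Lmax=5)
    assert spec[5] == pytest.approx(sum(full[L] for L in range(5, 31)))
    assert spec[3] == pytest.approx(full[3])
    # total mass: sum L*E(L) = n over the un-top-coded spectrum
    assert sum(L * full[L] for L in full) == pytest.approx(30)


def test_mc_null_tracks_iid_closed_form_on_long_sequence():
    """Permutation null of one i.i.d. draw approximates the i.i.d. closed form
    (first-order composition fluctuations cancel at uniform base usage)."""
    rng = np.random.default_rng(5150)
    n = 5000
    seq = NucSequence("long", "".join(rng.choice(list("ACGT"), size=n)))
    null = null_spectrum(seq, n_reps=2000, Lmax=20, seed=77)
    for L in range(1, 21):
        expected = iid_expected_runs(UNIFORM, n, L)
        if expected >= 1:
            assert null.mean_counts[L] == pytest.approx(expected, rel=0.05)


@given(st.text(alphabet="ACGT", min_size=1, max_size=30))
def test_every_shuffle_replicate_conserves_tiling(seq_str):
    seq = NucSequence("s", seq_str)
    rng = np.random.default_rng(1)
    shuffled = shuffle_sequence(seq, rng)
    sp = spectrum(split_runs(shuffled), Lmax=len(seq_str))
    assert sp.total_bases == len(seq_str)
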