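"""Observed vs theoretical homopolymer frequencies between two sequence groups.

For each group the observed spectrum pools the maximal-run counts of all
member sequences; the theoretical spectrum pools each member's shuffle-null
mean counts (each sequence shuffled independently, preserving its own
composition) and normalizes to proportions.  Per-length enrichment ratios
(group A over group B) are then reported for both, with explicit status flags
where a ratio is undefined — no pseudo-counts are added by default, matching
the raw differential the analysis reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nullmodel import null_spectrum, sequence_rng
from .runs import pooled_spectrum
from .sequences import NucSequence, require_groups

STATUS_FINITE = "finite"
STATUS_ZERO_DEN = "undefined_zero_denominator"
STATUS_ZERO_NUM = "zero_numerator"


@dataclass(frozen=True)
class GroupFrequencies:
    """Per-group observed and theoretical proportions over bins 1..Lmax."""

    group: str
    Lmax: int
    obs_counts: np.ndarray
    obs_freq: np.ndarray
    theo_mean_counts: np.ndarray
    theo_freq: np.ndarray
    theo_sd: np.ndarray
    n_reps: int
    n_sequences: int


@dataclass(frozen=True)
class GroupComparison:
    """Per-length observed/theoretical frequencies and A/B enrichment ratios."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: length_bin, obs_freq_a, ..., status


def group_frequencies(
    seqs: Sequence[NucSequence],
    n_reps: int = 10_000,
    Lmax: int = 10,
    seed: int = 0,
    mode: str = "pooled",
) -> dict[str, GroupFrequencies]:
    """Observed and theoretical proportion tables, one per group label.

    ``mode="pooled"`` (default) pools run counts across the sequences of a
    group before normalizing; ``mode="mean"`` averages per-sequence
    proportions instead.  Pooling is the assumed convention of the published
    figures; the flag exists because the alternative cannot be ruled out.
    Theoretical means use a per-sequence RNG stream derived from
    ``(seed, sequence id)`` so results do not depend on iteration order.
    """
    if mode not in ("pooled", "mean"):
        raise ValueError("mode must be 'pooled' or 'mean'")
    require_groups(seqs)
    groups: dict[str, list[NucSequence]] = {}
    for s in seqs:
        groups.setdefault(s.group, []).append(s)

    out: dict[str, GroupFrequencies] = {}
    for label, members in groups.items():
        obs = pooled_spectrum(members, Lmax=Lmax)
        obs_counts = obs.count_vector().astype(float)
        theo_mean = np.zeros(Lmax)
        theo_var = np.zeros(Lmax)
        obs_prop_sum = np.zeros(Lmax)
        theo_prop_sum = np.zeros(Lmax)
        for seq in members:
            null = null_spectrum(
                seq, n_reps=n_reps, Lmax=Lmax, rng=sequence_rng(seed, seq.id)
            )
            theo_mean += null.mean_vector()
            theo_var += null.sd_vector() ** 2
            if mode == "mean":
                obs_sp = pooled_spectrum([seq], Lmax=Lmax)
                obs_prop_sum += obs_sp.proportion_vector()
                theo_prop_sum += null.mean_vector() / null.mean_total_runs
        if mode == "pooled":
            obs_freq = obs_counts / obs_counts.sum()
            theo_freq = theo_mean / theo_mean.sum()
        else:
            obs_freq = obs_prop_sum / len(members)
            theo_freq = theo_prop_sum / len(members)
        out[label] = GroupFrequencies(
            group=label,
            Lmax=Lmax,
            obs_counts=obs_counts,
            obs_freq=obs_freq,
            theo_mean_counts=theo_mean,
            theo_freq=theo_freq,
            theo_sd=np.sqrt(theo_var),
            n_reps=n_reps,
            n_sequences=len(members),
        )
    return out


def _ratio_with_status(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, list[str]]:
    ratios = np.full(num.shape, np.nan)
    status: list[str] = []
    for i, (a, b) in enumerate(zip(num, den)):
        if b > 0:
            ratios[i] = a / b
            status.append(STATUS_ZERO_NUM if a == 0 else STATUS_FINITE)
        else:
            status.append(STATUS_ZERO_DEN)
    return ratios, status


def enrichment_ratio(
    freq_a: Mapping[int, float] | np.ndarray,
    freq_b: Mapping[int, float] | np.ndarray,
    group_a: str = "A",
    group_b: str = "B",
    pseudocount: float = 0.0,
) -> GroupComparison:
    """Per-bin frequency ratio A/B with explicit undefined-ratio flags.

    ``pseudocount`` (non-canonical, off by default) is added to both
    frequencies before dividing, for exploratory use only.
    """
    if isinstance(freq_a, Mapping) or isinstance(freq_b, Mapping):
        if not isinstance(freq_a, Mapping) or not isinstance(freq_b, Mapping):
            raise ValueError("freq_a and freq_b must both be mappings or both arrays")
        if set(freq_a) != set(freq_b):
            raise ValueError("mismatched length-bin sets between the two tables")
        bins = sorted(freq_a)
        a = np.array([freq_a[L] for L in bins], dtype=float)
        b = np.array([freq_b[L] for L in bins], dtype=float)
    else:
        a = np.asarray(freq_a, dtype=float)
        b = np.asarray(freq_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("mismatched length-bin sets between the two tables")
        bins = list(range(1, a.size + 1))
    if pseudocount:
        a = a + pseudocount
        b = b + pseudocount
    ratios, status = _ratio_with_status(a, b)
    table = pd.DataFrame(
        {
            "length_bin": bins,
            "freq_a": a,
            "freq_b": b,
            "ratio": ratios,
            "status": status,
        }
    )
    return GroupComparison(group_a=group_a, group_b=group_b, table=table)


def compare_groups(
    seqs: Sequence[NucSequence],
    group_a: str,
    group_b: str,
    n_reps: int = 10_000,
    Lmax: int = 10,
    seed: int = 0,
    mode: str = "pooled",
    pseudocount: float = 0.0,
) -> GroupComparison:
    """Full two-group comparison table (observed and theoretical ratios).

    Columns: length_bin, obs_freq_a, obs_freq_b, theo_freq_a, theo_freq_b,
    obs_ratio, theo_ratio, status (observed-ratio status) and theo_status.
    """
    freqs = group_frequencies(seqs, n_reps=n_reps, Lmax=Lmax, seed=seed, mode=mode)
    for label in (group_a, group_b):
        if label not in freqs:
            raise ValueError(f"no sequences labeled {label!r}")
    fa, fb = freqs[group_a], freqs[group_b]
    obs = enrichment_ratio(fa.obs_freq, fb.obs_freq, group_a, group_b, pseudocount)
    theo = enrichment_ratio(fa.theo_freq, fb.theo_freq, group_a, group_b, pseudocount)
    table = pd.DataFrame(
        {
            "length_bin": obs.table["length_bin"],
            "obs_freq_a": fa.obs_freq,
            "obs_freq_b": fb.obs_freq,
            "theo_freq_a": fa.theo_freq,
            "theo_freq_b": fb.theo_freq,
            "obs_ratio": obs.table["ratio"],
            "theo_ratio": theo.table["ratio"],
            "status": obs.table["status"],
            "theo_status": theo.table["status"],
        }
    )
    return GroupComparison(group_a=group_a, group_b=group_b, table=table)
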