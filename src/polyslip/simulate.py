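"""Synthetic integrase-like genes and slippage-driven variant tables.

Everything here exists so that the whole pipeline — run spectra, shuffle
nulls, group comparison, variant filtering and hotspot attribution — can be
exercised end to end with known ground truth and no external data.

Genes are drawn i.i.d. from a base composition, with optional *planted*
homopolymer runs (e.g. the canonical fixture: an 8xA run starting 57 bp after
the ATG, emulating the mutational hotspot observed at the 5' end of an
integron integrase gene).  Planted runs are flank-guarded — the bases
immediately 5' and 3' are forced to differ from the run base — so the planted
length is exact.

Variants are emitted from a slipped-strand mispairing (SSM) caricature: each
run of length L >= 3 yields a +-1-unit indel of its own base at rate
``r1 * g**(L - 1)`` (capped), reflecting the empirical tendency of slippage
rates to grow steeply with repeat length.  This geometric form is an
implementation choice for testability, not a measured mutational model.
Read counts are binomial at the stated coverage and split binomially by
strand; a configurable fraction of variants is planted as strand-biased
artifacts (all alt reads on one strand) to exercise the strand-balance
filter.  Indels are emitted in left-aligned parsimonious VCF form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .runs import split_runs
from .sequences import NucSequence
from .variants import VariantRecord

BASES = "ACGT"
UNIFORM = (0.25, 0.25, 0.25, 0.25)
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Recipe for one synthetic coding sequence.

    planted_runs:
        (base, length, start) triples, start 1-based.  Runs are planted after
        the i.i.d. draw and flank-guarded so their maximal length is exact.
    orf_mode:
        Enforce ATG start, terminal TAA stop, and no internal stop codons
        (length must then be divisible by 3).
    """

    length: int
    composition: tuple[float, float, float, float] = UNIFORM
    planted_runs: tuple[tuple[str, int, int], ...] = ()
    orf_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        p = np.asarray(self.composition, dtype=float)
        if p.size != 4 or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("composition must be 4 probabilities summing to 1")
        if self.orf_mode and self.length % 3:
            raise ValueError("orf_mode requires length divisible by 3")
        spans = []
        for base, L, start in self.planted_runs:
            if base not in BASES:
                raise ValueError(f"planted run base {base!r} not in ACGT")
            if L < 1 or start < 1 or start + L - 1 > self.length:
                raise ValueError(f"planted run ({base},{L},{start}) out of bounds")
            spans.append((start - 1, start - 1 + L))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1 + 1:  # +1: guard base between adjacent runs
                raise ValueError("planted runs overlap or touch")


def _sample_not(rng: np.random.Generator, p: np.ndarray, forbidden: str) -> str:
    """Draw a base from composition ``p`` conditioned on != forbidden."""
    keep = [i for i in range(4) if BASES[i] != forbidden]
    q = p[keep]
    if q.sum() == 0:
        raise ValueError(f"composition gives zero mass to bases other than {forbidden}")
    return BASES[keep[rng.choice(len(keep), p=q / q.sum())]]


def generate_cds(spec: SyntheticGeneSpec, seq_id: str = "synthetic_gene") -> NucSequence:
    """Draw a synthetic gene: i.i.d. bases, planted runs, optional ORF constraints.

    Deterministic for a fixed spec (same seed twice gives the identical
    sequence).  Raises if a planted run conflicts with the ORF scaffold (ATG,
    terminal stop) or if an all-fixed internal codon is a stop.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.composition, dtype=float)
    n = spec.length

    fixed: dict[int, str] = {}
    if spec.orf_mode:
        if n < 6:
            raise ValueError("orf_mode needs length >= 6 (start + stop codon)")
        for i, b in enumerate("ATG"):
            fixed[i] = b
        for i, b in enumerate("TAA"):
            fixed[n - 3 + i] = b

    guard: dict[int, str] = {}  # position -> base it must differ from
    for base, L, start in spec.planted_runs:
        for pos in range(start - 1, start - 1 + L):
            if pos in fixed and fixed[pos] != base:
                raise ValueError(
                    f"planted run ({base},{L},{start}) conflicts with ORF "
                    f"scaffold at position {pos + 1}"
                )
            fixed[pos] = base
        for flank in (start - 2, start - 1 + L):
            if 0 <= flank < n:
                if flank in fixed:
                    if fixed[flank] == base:
                        raise ValueError(
                            f"planted run ({base},{L},{start}): fixed flank at "
                            f"position {flank + 1} equals the run base"
                        )
                else:
                    guard[flank] = base

    seq = list(rng.choice(list(BASES), size=n, p=p))
    for pos, b in fixed.items():
        seq[pos] = b
    for pos, forbidden in guard.items():
        if seq[pos] == forbidden:
            seq[pos] = _sample_not(rng, p, forbidden)

    if spec.orf_mode:
        for c in range(1, n // 3 - 1):
            for _ in range(1000):
                codon = slice(3 * c, 3 * c + 3)
                if "".join(seq[codon]) not in STOP_CODONS:
                    break
                free = [
                    i for i in range(3 * c, 3 * c + 3)
                    if i not in fixed
                ]
                if not free:
                    raise ValueError(
                        f"codon {c + 1} is a stop and fully fixed by planted runs"
                    )
                for i in free:
                    forbidden = guard.get(i)
                    seq[i] = (
                        _sample_not(rng, p, forbidden)
                        if forbidden is not None
                        else rng.choice(list(BASES), p=p)
                    )
            else:
                raise ValueError(f"could not resample stop codon {c + 1}")

    return NucSequence(seq_id, "".join(seq), source="generate_cds")


def generate_group_panel(
    n_seqs: int,
    length: int = 1000,
    composition: tuple[float, float, float, float] = UNIFORM,
    policy: str = "iid",
    seed: int = 0,
    group: str | None = None,
    max_tries: int = 1000,
) -> list[NucSequence]:
    """Generate a labeled sequence panel under a run-content policy.

    Policies:

    * ``"sci_like"`` — one long planted run (length 7-9, random base and
      position) per sequence: spectra carry a long-run tail their own shuffle
      null also predicts only weakly at the planted length.
    * ``"mi_like"`` — rejection-sample sequences until none contains a run of
      length >= 6, emulating integrase genes depleted of long homopolymers.
    * ``"iid"`` — plain i.i.d. draws (null-calibration panels).
    """
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    if policy not in ("sci_like", "mi_like", "iid"):
        raise ValueError("policy must be 'sci_like', 'mi_like' or 'iid'")
    label = group or {"sci_like": "SCI", "mi_like": "MI", "iid": "IID"}[policy]
    root = np.random.SeedSequence([seed, {"sci_like": 1, "mi_like": 2, "iid": 3}[policy]])
    rng = np.random.default_rng(root)
    panel: list[NucSequence] = []
    for i in range(n_seqs):
        seq_id = f"{label}_{i:04d}"
        if policy == "sci_like":
            L = int(rng.integers(7, 10))
            base = BASES[rng.integers(0, 4)]
            start = int(rng.integers(2, length - L + 1))  # guards stay in-bounds
            spec = SyntheticGeneSpec(
                length=length,
                composition=composition,
                planted_runs=((base, L, start),),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            seq = generate_cds(spec, seq_id)
        elif policy == "mi_like":
            for attempt in range(max_tries):
                spec = SyntheticGeneSpec(
                    length=length,
                    composition=composition,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                seq = generate_cds(spec, seq_id)
                if max(r.length for r in split_runs(seq)) <= 5:
                    break
            else:
                raise RuntimeError(
                    f"mi_like rejection sampling exceeded {max_tries} tries; "
                    "shorten the sequences or relax the run cap"
                )
        else:
            spec = SyntheticGeneSpec(
                length=length,
                composition=composition,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            seq = generate_cds(spec, seq_id)
        panel.append(seq.with_group(label))
    return panel


@dataclass(frozen=True)
class SlippageModel:
    """Caricature slippage/error model for synthetic variant tables.

    rate(L) = min(r1 * g**(L-1), rate_max) is the allele frequency of the
    +-1-unit indel emitted at a run of length L (geometric growth with repeat
    number — an implementation choice for testability, not a measured law).
    Background SNVs appear at ``snv_rate`` per site with allele frequency
    ``snv_freq``.  ``strand_bias_fraction`` of all variants are planted as
    strand artifacts (all alt reads on one strand).
    """

    r1: float = 1e-5
    g: float = 4.0
    rate_max: float = 0.5
    min_run_len: int = 3
    snv_rate: float = 0.001
    snv_freq: float = 0.002
    coverage: int = 10_000
    strand_bias_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r1", "rate_max", "snv_rate", "snv_freq", "strand_bias_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.g < 0:
            raise ValueError("g must be >= 0")

    def rate(self, run_length: int) -> float:
        return min(self.r1 * self.g ** (run_length - 1), self.rate_max)


def simulate_variants(
    gene: NucSequence, model: SlippageModel = SlippageModel(), seed: int = 0
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Emit slippage indels and background SNVs with binomial read counts.

    Returns ``(records, truth)``.  ``truth`` has one row per emitted variant:
    pos, ref, alt, mechanism ("slippage" or "snv"), the generating run
    (start/base/length, 1-based start of the run itself) or NA, the model
    rate, and whether the variant was planted as a strand artifact.
    Runs starting at the first base of the gene have no 5' anchor base and
    are skipped (a warning-free structural constraint of the VCF encoding).
    """
    rng = np.random.default_rng(seed)
    residues = gene.residues
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []

    def emit(
        pos: int, ref: str, alt: str, rate: float
    ) -> tuple[VariantRecord, bool] | None:
        alt_n = int(rng.binomial(model.coverage, rate))
        if alt_n == 0:
            return None
        artifact = bool(rng.random() < model.strand_bias_fraction)
        if artifact:
            saf = alt_n if rng.random() < 0.5 else 0
        else:
            saf = int(rng.binomial(alt_n, 0.5))
        ro = model.coverage - alt_n
        srf = int(rng.binomial(ro, 0.5))
        rec = VariantRecord(
            contig=gene.id,
            pos=pos,
            ref=ref,
            alt=alt,
            alt_fwd=saf,
            alt_rev=alt_n - saf,
            ref_fwd=srf,
            ref_rev=ro - srf,
            depth=model.coverage,
            alt_count=alt_n,
            ref_count=ro,
            freq=alt_n / model.coverage,
        )
        records.append(rec)
        return rec, artifact

    for run in split_runs(gene):
        if run.length < model.min_run_len or run.start < 1:
            continue
        rate = model.rate(run.length)
        anchor_pos = run.start  # 1-based position of the base 5' of the run
        anchor = residues[run.start - 1]
        if rng.random() < 0.5:  # deletion of one repeat unit
            ref, alt = anchor + run.base, anchor
        else:  # insertion of one repeat unit
            ref, alt = anchor, anchor + run.base
        emitted = emit(anchor_pos, ref, alt, rate)
        if emitted is not None:
            rec, artifact = emitted
            truth_rows.append(
                {
                    "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                    "mechanism": "slippage",
                    "run_start": run.start + 1, "run_base": run.base,
                    "run_length": run.length, "rate": rate,
                    "strand_artifact": artifact,
                }
            )

    snv_sites = np.flatnonzero(rng.random(len(residues)) < model.snv_rate)
    for pos0 in snv_sites:
        ref = residues[pos0]
        alt = _sample_not(rng, np.full(4, 0.25), ref)
        emitted = emit(int(pos0) + 1, ref, alt, model.snv_freq)
        if emitted is not None:
            rec, artifact = emitted
            truth_rows.append(
                {
                    "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                    "mechanism": "snv", "run_start": pd.NA, "run_base": pd.NA,
                    "run_length": pd.NA, "rate": model.snv_freq,
                    "strand_artifact": artifact,
                }
            )

    records.sort(key=lambda r: r.pos)
    truth = pd.DataFrame(
        truth_rows,
        columns=["pos", "ref", "alt", "mechanism", "run_start", "run_base",
                 "run_length", "rate", "strand_artifact"],
    ).sort_values("pos", kind="stable").reset_index(drop=True)
    return records, truth


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contig: str,
    contig_length: int,
) -> None:
    """Write records as a Freebayes-style VCF (AO/RO/SAF/SAR/SRF/SRR/DP INFO)."""
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=contig_length)
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.info.add("AO", "A", "Integer", "Alternate allele observation count")
    header.info.add("RO", 1, "Integer", "Reference allele observation count")
    header.info.add("SAF", "A", "Integer", "Alt observations on the forward strand")
    header.info.add("SAR", "A", "Integer", "Alt observations on the reverse strand")
    header.info.add("SRF", 1, "Integer", "Ref observations on the forward strand")
    header.info.add("SRR", 1, "Integer", "Ref observations on the reverse strand")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in records:
            out = vcf.new_record(
                contig=contig,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            out.info["DP"] = rec.depth
            out.info["AO"] = (rec.alt_count,)
            out.info["RO"] = rec.ref_count
            out.info["SAF"] = (rec.alt_fwd,)
            out.info["SAR"] = (rec.alt_rev,)
            out.info["SRF"] = rec.ref_fwd
            out.info["SRR"] = rec.ref_rev
            vcf.write(out)
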