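"""Variant filtering and indel-to-homopolymer hotspot attribution.

Consumes Freebayes-style VCF calls (per-allele observation counts AO/RO and
per-strand counts SAF/SAR/SRF/SRR) from deep amplicon or plasmid sequencing,
applies the post-calling filters used for such data — a minimum allele
frequency (default 0.1%, suited to ~10,000x coverage) and a two-sided Fisher
exact test on strand balance of alt vs ref reads — classifies variants as
SNV / MNV / indel, and attributes each surviving indel to the maximal
homopolymer run that generated it (slipped-strand mispairing produces
+-1-unit indels anchored at a run).

Indels are parsimony-trimmed and left-aligned against the reference before
attribution, so equivalent VCF encodings of the same event map to the same
run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .runs import HomopolymerRun, split_runs
from .sequences import NucSequence

logger = logging.getLogger(__name__)

SNV = "SNV"
MNV = "MNV"
INDEL = "indel"


@dataclass
class VariantRecord:
    """One called variant (one ALT allele) with strand-split read counts."""

    contig: str
    pos: int  # 1-based reference position of the REF allele (VCF convention)
    ref: str
    alt: str
    alt_fwd: int | None = None
    alt_rev: int | None = None
    ref_fwd: int | None = None
    ref_rev: int | None = None
    depth: int | None = None
    alt_count: int | None = None
    ref_count: int | None = None
    freq: float = float("nan")
    filter_reason: str | None = None

    @property
    def vtype(self) -> str:
        return classify_variant(self.ref, self.alt)

    @property
    def has_strand_counts(self) -> bool:
        return None not in (self.alt_fwd, self.alt_rev, self.ref_fwd, self.ref_rev)

    def strand_table(self) -> tuple[int, int, int, int]:
        if not self.has_strand_counts:
            raise ValueError("record lacks per-strand counts")
        return (self.alt_fwd, self.alt_rev, self.ref_fwd, self.ref_rev)


@dataclass(frozen=True)
class FilterConfig:
    """Post-calling filter thresholds.

    min_freq:
        Minimum alt-allele frequency; records with ``freq >= min_freq`` are
        kept.  Default 0.001 (0.1%).
    strand_alpha:
        Two-sided Fisher significance level; records with ``p < strand_alpha``
        are removed as strand-imbalanced artifacts.  Default 0.05.
    min_depth:
        Minimum total depth (0 disables).
    """

    min_freq: float = 0.001
    strand_alpha: float = 0.05
    min_depth: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_freq <= 1:
            raise ValueError("min_freq must be in [0, 1]")
        if not 0 < self.strand_alpha < 1:
            raise ValueError("strand_alpha must be in (0, 1)")


def classify_variant(ref: str, alt: str) -> str:
    """SNV (1->1), MNV (n->n, n>1) or indel (length-changing)."""
    if not ref or not alt:
        raise ValueError("empty allele string")
    if len(ref) == len(alt):
        return SNV if len(ref) == 1 else MNV
    return INDEL


def _info_list(value) -> list:
    if value is None:
        return []
    if isinstance(value, (tuple, list)):
        return list(value)
    return [value]


def parse_variants(
    vcf_path: str | Path, freq_denominator: str = "ao_ro"
) -> list[VariantRecord]:
    """Parse a Freebayes-dialect VCF into per-ALT-allele records.

    Multi-allelic sites are decomposed into one record per ALT allele, with
    per-allele AO/SAF/SAR counts.  ``freq_denominator`` selects the allele
    frequency convention: ``"ao_ro"`` (default) uses AO/(AO+RO), robust to
    depth inflation from overlapping alleles; ``"dp"`` uses AO/DP.  Records
    missing strand counts are kept (with a warning) but are transparent to
    the strand-balance filter.
    """
    if freq_denominator not in ("ao_ro", "dp"):
        raise ValueError("freq_denominator must be 'ao_ro' or 'dp'")
    records: list[VariantRecord] = []
    n_missing_strand = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            info = rec.info
            ao = _info_list(info.get("AO"))
            saf = _info_list(info.get("SAF"))
            sar = _info_list(info.get("SAR"))
            ro = info.get("RO")
            srf = info.get("SRF")
            srr = info.get("SRR")
            dp = info.get("DP")
            if isinstance(ro, (tuple, list)):
                ro = ro[0]
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                alt_count = ao[i] if i < len(ao) else None
                record = VariantRecord(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_fwd=saf[i] if i < len(saf) else None,
                    alt_rev=sar[i] if i < len(sar) else None,
                    ref_fwd=srf if isinstance(srf, int) else None,
                    ref_rev=srr if isinstance(srr, int) else None,
                    depth=dp if isinstance(dp, int) else None,
                    alt_count=alt_count,
                    ref_count=ro if isinstance(ro, int) else None,
                )
                if not record.has_strand_counts:
                    n_missing_strand += 1
                    logger.warning(
                        "%s:%d %s>%s: missing strand counts; excluded from "
                        "strand-balance filtering",
                        record.contig, record.pos, record.ref, record.alt,
                    )
                if alt_count is not None:
                    if freq_denominator == "ao_ro" and record.ref_count is not None:
                        den = alt_count + record.ref_count
                    else:
                        den = record.depth
                    if den:
                        record.freq = alt_count / den
                records.append(record)
    if n_missing_strand:
        logger.warning("%d record(s) lacked strand-count annotations", n_missing_strand)
    return records


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float | None:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Computed by exact hypergeometric summation in integer arithmetic: with
    margins fixed, table probabilities share the denominator C(N, a+c), so
    the two-sided p-value sums the integer numerators C(r1,k)*C(r2,a+c-k)
    that do not exceed the observed one.  No floating-point tie tolerance is
    involved.  Returns ``None`` for the all-zero table (undefined).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n_total = r1 + r2
    if n_total == 0:
        return None
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    numer = sum(w for w in weights if w <= w_obs)
    return numer / math.comb(n_total, c1)


def frequency_filter(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep records with ``freq >= min_freq`` (and depth >= min_depth).

    Removed records get ``filter_reason`` set and are logged; input order is
    preserved.
    """
    survivors: list[VariantRecord] = []
    for rec in records:
        if config.min_depth and (rec.depth or 0) < config.min_depth:
            rec.filter_reason = "low_depth"
        elif not (rec.freq >= config.min_freq):  # NaN freq also fails
            rec.filter_reason = "low_frequency"
        else:
            survivors.append(rec)
            continue
        logger.info(
            "removed %s:%d %s>%s (%s, freq=%.3g)",
            rec.contig, rec.pos, rec.ref, rec.alt, rec.filter_reason, rec.freq,
        )
    return survivors


def strand_balance_filter(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Remove records whose alt/ref strand split deviates from balance.

    Two-sided Fisher exact test on [[alt_fwd, alt_rev], [ref_fwd, ref_rev]];
    records with ``p < strand_alpha`` are removed.  Records without strand
    counts pass through unchanged (already warned at parse time); all-zero
    tables are excluded with a warning.
    """
    survivors: list[VariantRecord] = []
    for rec in records:
        if not rec.has_strand_counts:
            survivors.append(rec)
            continue
        p = fisher_exact_two_sided(*rec.strand_table())
        if p is None:
            rec.filter_reason = "empty_strand_table"
            logger.warning(
                "excluded %s:%d %s>%s: all-zero strand table",
                rec.contig, rec.pos, rec.ref, rec.alt,
            )
            continue
        if p < config.strand_alpha:
            rec.filter_reason = "strand_bias"
            logger.info(
                "removed %s:%d %s>%s (strand bias, p=%.3g)",
                rec.contig, rec.pos, rec.ref, rec.alt, p,
            )
            continue
        survivors.append(rec)
    return survivors


def normalize_indel(
    pos: int, ref: str, alt: str, reference: str
) -> tuple[int, str, str]:
    """Parsimony-trim and left-align an indel against the reference.

    ``pos`` is 1-based; ``reference`` is the full reference sequence of the
    contig/gene.  Returns the normalized (pos, ref, alt).  Homopolymer indels
    are representation-ambiguous in VCF; left alignment makes the anchor the
    base immediately 5' of the run.  SNV/MNV records are returned trimmed
    only.
    """
    ref, alt = ref.upper(), alt.upper()
    if reference[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"REF allele {ref!r} does not match reference at position {pos}"
        )
    # trim common suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-align: while both alleles end with the same base, or can be
    # extended on the left, shift the event leftwards
    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1] and min(len(ref), len(alt)) > 1:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        elif ref[-1] == alt[-1] and pos > 1:
            prev = reference[pos - 2]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
    # trim common prefix (keep one anchor base)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class HotspotAttribution:
    """Indel-to-run assignments over one reference gene.

    ``assignments`` pairs every input record with its generating run or
    ``None``; SNV/MNV records are never attributed.  ``min_len`` is the
    smallest run length considered an attribution target.
    """

    gene_id: str
    gene_length: int
    assignments: tuple[tuple[VariantRecord, HomopolymerRun | None], ...]
    min_len: int = 3

    def attributed(self) -> list[tuple[VariantRecord, HomopolymerRun]]:
        return [(rec, run) for rec, run in self.assignments if run is not None]


def _indel_event(pos: int, ref: str, alt: str) -> tuple[str, int] | None:
    """(inserted-or-deleted segment, anchor pos) for a normalized pure indel."""
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        return ref[1:], pos
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
        return alt[1:], pos
    return None  # complex substitution; not a pure anchored indel


def attribute_indels_to_runs(
    records: Sequence[VariantRecord],
    gene: NucSequence,
    runs: Sequence[HomopolymerRun] | None = None,
    min_len: int = 3,
) -> HotspotAttribution:
    """Attribute each indel to the homopolymer run it slipped in, if any.

    An indel is attributed to run R iff its net inserted/deleted bases are all
    ``R.base`` and its normalized anchor lies within R or immediately 5' of R
    (the VCF anchor-base convention for a left-aligned run indel).  Runs
    shorter than ``min_len`` are not attribution targets.  Records outside
    the gene raise.
    """
    if runs is None:
        runs = split_runs(gene)
    targets = [r for r in runs if r.length >= min_len]
    n = len(gene.residues)
    assignments: list[tuple[VariantRecord, HomopolymerRun | None]] = []
    for rec in records:
        if rec.pos < 1 or rec.pos - 1 + len(rec.ref) > n:
            raise ValueError(
                f"variant {rec.contig}:{rec.pos} {rec.ref}>{rec.alt} extends "
                f"beyond gene {gene.id!r} (length {n})"
            )
        run_hit: HomopolymerRun | None = None
        if rec.vtype == INDEL:
            pos, ref, alt = normalize_indel(rec.pos, rec.ref, rec.alt, gene.residues)
            event = _indel_event(pos, ref, alt)
            if event is not None:
                segment, anchor = event
                base = segment[0]
                if segment == base * len(segment):
                    for run in targets:
                        first, last = run.positions_1based()
                        if run.base == base and first - 1 <= anchor <= last:
                            run_hit = run
                            break
        assignments.append((rec, run_hit))
    return HotspotAttribution(
        gene_id=gene.id,
        gene_length=n,
        assignments=tuple(assignments),
        min_len=min_len,
    )


def hotspot_table(
    attribution: HotspotAttribution, atg_offset: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position and per-run mutation-frequency tables.

    Returns ``(positions, runs)``: ``positions`` has one row per variant
    (position_atg_relative, vtype, freq, attributed_run_start) for
    mutation-pattern plots; ``runs`` aggregates summed indel frequency and
    variant count per attributed run.  Positions are 1-based with the A of
    the ATG start codon as position 1; ``atg_offset`` is the 1-based start of
    the gene within the VCF contig (0 when the contig is the gene itself).
    """
    shift = atg_offset - 1 if atg_offset else 0
    pos_rows = []
    for rec, run in attribution.assignments:
        pos_rows.append(
            {
                "position_atg_relative": rec.pos - shift,
                "vtype": rec.vtype,
                "freq": rec.freq,
                "ref": rec.ref,
                "alt": rec.alt,
                "attributed_run_start": (run.start + 1 - shift) if run else pd.NA,
            }
        )
    positions = pd.DataFrame(
        pos_rows,
        columns=[
            "position_atg_relative", "vtype", "freq", "ref", "alt",
            "attributed_run_start",
        ],
    )
    run_rows: dict[int, dict] = {}
    for rec, run in attribution.assignments:
        if run is None:
            continue
        row = run_rows.setdefault(
            run.start,
            {
                "run_start": run.start + 1 - shift,
                "run_base": run.base,
                "run_length": run.length,
                "summed_indel_freq": 0.0,
                "n_variants": 0,
            },
        )
        row["summed_indel_freq"] += 0.0 if math.isnan(rec.freq) else rec.freq
        row["n_variants"] += 1
    runs = pd.DataFrame(
        [run_rows[k] for k in sorted(run_rows)],
        columns=["run_start", "run_base", "run_length", "summed_indel_freq", "n_variants"],
    )
    return positions, runs
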