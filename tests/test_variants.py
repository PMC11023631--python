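"""Variant parsing, filtering, normalization, and hotspot attribution."""

import math
from fractions import Fraction

import pytest
from scipy import stats

from polyslip import (
    FilterConfig,
    NucSequence,
    VariantRecord,
    attribute_indels_to_runs,
    classify_variant,
    fisher_exact_two_sided,
    frequency_filter,
    hotspot_table,
    normalize_indel,
    parse_variants,
    split_runs,
    strand_balance_filter,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=gene1,length=2000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="x">
##INFO=<ID=AO,Number=A,Type=Integer,Description="x">
##INFO=<ID=RO,Number=1,Type=Integer,Description="x">
##INFO=<ID=SAF,Number=A,Type=Integer,Description="x">
##INFO=<ID=SAR,Number=A,Type=Integer,Description="x">
##INFO=<ID=SRF,Number=1,Type=Integer,Description="x">
##INFO=<ID=SRR,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_text(tmp_path, body: str):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + body)
    return path


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "G", "SNV"),
        ("AT", "GC", "MNV"),
        ("A", "AA", "indel"),
        ("AAT", "A", "indel"),
    ],
)
def test_classify_variant(ref, alt, expected):
    assert classify_variant(ref, alt) == expected


def test_classify_variant_rejects_empty_allele():
    with pytest.raises(ValueError):
        classify_variant("", "A")


def test_parse_variants_freq_convention(tmp_path):
    path = write_vcf_text(
        tmp_path,
        "gene1\t100\t.\tA\tG\t.\t.\tDP=10600;AO=32;RO=10568;SAF=15;SAR=17;SRF=5284;SRR=5284\n",
    )
    (rec,) = parse_variants(path)
    assert rec.freq == pytest.approx(32 / 10600, rel=1e-9)
    assert (rec.alt_fwd, rec.alt_rev) == (15, 17)
    (rec_dp,) = parse_variants(path, freq_denominator="dp")
    assert rec_dp.freq == pytest.approx(32 / 10600, rel=1e-9)


def test_parse_variants_decomposes_multiallelic(tmp_path):
    path = write_vcf_text(
        tmp_path,
        "gene1\t100\t.\tA\tG,T\t.\t.\tDP=1000;AO=10,20;RO=970;SAF=5,9;SAR=5,11;SRF=485;SRR=485\n",
    )
    recs = parse_variants(path)
    assert [(r.alt, r.alt_count, r.alt_fwd) for r in recs] == [("G", 10, 5), ("T", 20, 9)]
    assert recs[0].freq == pytest.approx(10 / 980)
    assert recs[1].freq == pytest.approx(20 / 990)


def test_parse_variants_empty_body(tmp_path):
    assert parse_variants(write_vcf_text(tmp_path, "")) == []


def test_parse_variants_missing_strand_counts_kept_with_warning(tmp_path, caplog):
    path = write_vcf_text(tmp_path, "gene1\t100\t.\tA\tG\t.\t.\tDP=1000;AO=10;RO=990\n")
    with caplog.at_level("WARNING"):
        (rec,) = parse_variants(path)
    assert not rec.has_strand_counts
    assert "strand" in caplog.text
    # transparent to the strand filter
    assert strand_balance_filter([rec]) == [rec]


def test_frequency_filter_boundary_semantics():
    mk = lambda f: VariantRecord("g", 1, "A", "G", freq=f)
    config = FilterConfig(min_freq=0.001)
    assert frequency_filter([mk(0.0009)], config) == []
    kept = frequency_filter([mk(0.001)], config)
    assert len(kept) == 1  # >= comparison keeps the exact threshold


def test_frequency_filter_on_packaged_fixture(data_dir):
    records = parse_variants(data_dir / "filter_fixture.vcf")
    assert len(records) == 10
    survivors = frequency_filter(records, FilterConfig())
    assert len(survivors) == 6
    removed = [r for r in records if r not in survivors]
    assert all(r.filter_reason == "low_frequency" for r in removed)


def test_strand_filter_examples():
    config = FilterConfig()
    biased = VariantRecord("g", 1, "A", "G", alt_fwd=20, alt_rev=0,
                           ref_fwd=5000, ref_rev=5000, freq=0.002)
    assert strand_balance_filter([biased], config) == []
    assert biased.filter_reason == "strand_bias"
    balanced = VariantRecord("g", 1, "A", "G", alt_fwd=16, alt_rev=16,
                             ref_fwd=5000, ref_rev=5000, freq=0.0032)
    assert strand_balance_filter([balanced], config) == [balanced]
    tiny = VariantRecord("g", 1, "A", "G", alt_fwd=1, alt_rev=0,
                         ref_fwd=1, ref_rev=0, freq=0.5)
    assert strand_balance_filter([tiny], config) == [tiny]  # p = 1 at these margins


def test_strand_filter_excludes_all_zero_table():
    empty = VariantRecord("g", 1, "A", "G", alt_fwd=0, alt_rev=0,
                          ref_fwd=0, ref_rev=0, freq=0.5)
    assert strand_balance_filter([empty]) == []
    assert empty.filter_reason == "empty_strand_table"


def brute_force_fisher(a, b, c, d):
    """Independent oracle: exact rational hypergeometric summation."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return None

    def pmf(k):
        return Fraction(
            math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1)
        )

    observed = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(k)
        if p <= observed:
            total += p
    return float(total)


def test_fisher_matches_bruteforce_on_small_tables():
    for a in range(0, 13):
        for b in range(0, 13 - a):
            for c in range(0, 13):
                for d in range(0, 13 - c):
                    if a + b + c + d == 0:
                        continue
                    assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                        brute_force_fisher(a, b, c, d), abs=1e-12
                    )


def test_fisher_matches_scipy_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 200, size=4))
        if a + b + c + d == 0:
            continue
        ours = fisher_exact_two_sided(a, b, c, d)
        scipys = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(scipys, rel=1e-6, abs=1e-12)


def test_filters_commute(rng):
    records = []
    for i in range(100):
        alt = int(rng.integers(0, 60)) + 1
        saf = int(rng.integers(0, alt + 1))
        ro = int(rng.integers(100, 20_000))
        srf = int(rng.binomial(ro, 0.5))
        records.append(
            VariantRecord("g", i + 1, "A", "G", alt_fwd=saf, alt_rev=alt - saf,
                          ref_fwd=srf, ref_rev=ro - srf, depth=alt + ro,
                          alt_count=alt, ref_count=ro, freq=alt / (alt + ro))
        )
    config = FilterConfig()

    def keys(recs):
        return [(r.pos, r.alt) for r in recs]

    fs = strand_balance_filter(frequency_filter(list(records), config), config)
    sf = frequency_filter(strand_balance_filter(list(records), config), config)
    assert keys(fs) == keys(sf)


def test_every_record_is_survivor_or_has_one_reason(data_dir):
    records = parse_variants(data_dir / "filter_fixture.vcf")
    survivors = strand_balance_filter(frequency_filter(records, FilterConfig()), FilterConfig())
    for rec in records:
        if rec in survivors:
            assert rec.filter_reason is None
        else:
            assert rec.filter_reason in ("low_frequency", "strand_bias")


GENE = NucSequence("gene", "CCAAAAAAAAGG")  # 8xA run at 0-based offset 2


def mk_indel(pos, ref, alt, freq=0.1):
    return VariantRecord("gene", pos, ref, alt, freq=freq)


@pytest.mark.parametrize(
    "pos,ref,alt",
    [
        (2, "CA", "C"),    # left-aligned deletion at the run anchor
        (9, "AA", "A"),    # same deletion, right-shifted encoding
        (10, "A", "AA"),   # insertion, right-shifted encoding
        (4, "AAA", "AA"),  # non-parsimonious encoding of a 1 bp deletion
    ],
)
def test_attribution_invariant_to_indel_encoding(pos, ref, alt):
    att = attribute_indels_to_runs([mk_indel(pos, ref, alt)], GENE)
    ((_, run),) = att.assignments
    assert run is not None and (run.base, run.start, run.length) == ("A", 2, 8)


def test_attribution_type_and_base_gates():
    snv = mk_indel(5, "A", "G")           # SNV inside the run
    wrong_base = mk_indel(2, "C", "CG")   # G insertion adjacent to the A-run
    att = attribute_indels_to_runs([snv, wrong_base], GENE)
    assert [run for _, run in att.assignments] == [None, None]


def test_attribution_ignores_short_runs():
    gene = NucSequence("g", "CCAAGG")  # AA run of length 2 < min_len
    att = attribute_indels_to_runs([mk_indel(2, "CA", "C")], gene, min_len=3)
    assert att.assignments[0][1] is None


def test_attribution_rejects_out_of_gene_coordinates():
    with pytest.raises(ValueError, match="beyond gene"):
        attribute_indels_to_runs([mk_indel(12, "GA", "G")], GENE)


def test_normalize_indel_rejects_ref_mismatch():
    with pytest.raises(ValueError, match="does not match"):
        normalize_indel(1, "GG", "G", GENE.residues)


def test_hotspot_table_empty_and_single_indel():
    positions, runs = hotspot_table(attribute_indels_to_runs([], GENE))
    assert positions.empty and runs.empty
    assert list(runs.columns) == [
        "run_start", "run_base", "run_length", "summed_indel_freq", "n_variants"
    ]
    att = attribute_indels_to_runs([mk_indel(2, "CA", "C", freq=0.3)], GENE)
    _, runs = hotspot_table(att)
    assert runs.loc[0, "summed_indel_freq"] == pytest.approx(0.3)
    assert runs.loc[0, "n_variants"] == 1


def test_hotspot_table_atg_relative_positions():
    # gene begins at 1-based position 5 of the contig; records use contig coords
    contig = NucSequence("contig", "GGGG" + GENE.residues)
    rec = VariantRecord("contig", 6, "CA", "C", freq=0.3)
    att = attribute_indels_to_runs([rec], contig)
    positions, runs = hotspot_table(att, atg_offset=5)
    assert positions.loc[0, "position_atg_relative"] == 2
    assert runs.loc[0, "run_start"] == 3  # run itself starts 3 bp after the ATG A
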