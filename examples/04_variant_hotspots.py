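"""End-to-end variant pipeline: simulate, filter, attribute indels to runs.

A synthetic 999 bp ORF carries an 8xA run starting 57 bp after the ATG.  The
slippage model emits one +-1-unit indel per run (rate growing geometrically
with run length) plus background SNVs; reads are binomial at 10,000x.  The
0.1% frequency filter and the Fisher strand-balance filter are then applied
and surviving indels are attributed to their homopolymer runs.
"""

import tempfile
from pathlib import Path

from polyslip import (
    FilterConfig,
    SlippageModel,
    SyntheticGeneSpec,
    attribute_indels_to_runs,
    frequency_filter,
    generate_cds,
    hotspot_table,
    parse_variants,
    simulate_variants,
    strand_balance_filter,
    write_vcf,
)

spec = SyntheticGeneSpec(length=999, planted_runs=(("A", 8, 58),), orf_mode=True, seed=5)
gene = generate_cds(spec, "intIA_synthetic")
model = SlippageModel(strand_bias_fraction=0.1)
records, truth = simulate_variants(gene, model, seed=6)
print(f"simulated {len(records)} variants "
      f"({(truth.mechanism == 'slippage').sum()} slippage indels)")

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "sim.vcf"
    write_vcf(records, vcf, gene.id, len(gene.residues))
    parsed = parse_variants(vcf)

config = FilterConfig(min_freq=0.001, strand_alpha=0.05)
survivors = strand_balance_filter(frequency_filter(parsed, config), config)
print(f"{len(parsed)} parsed -> {len(survivors)} kept after frequency + strand filters")

attribution = attribute_indels_to_runs(survivors, gene)
positions, runs = hotspot_table(attribution)
print("\nper-run summed indel frequencies:")
print(runs.sort_values("summed_indel_freq", ascending=False).to_string(index=False))
# The planted 8xA run (run_start 58) dominates: slippage rates grow steeply
# with run length, so the longest homopolymer is the mutational hotspot.
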