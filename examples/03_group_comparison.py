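"""Two-group enrichment ratios: observed vs shuffle-theoretical frequencies.

Builds a long-run-planted panel (each sequence carries one 7-9 bp run, like
sedentary-integron integrases) and a long-run-depleted panel (no run over
5 bp, like mobile-integron integrases), then compares per-length frequencies.
"""

from polyslip import compare_groups, generate_group_panel

sci = generate_group_panel(30, length=1000, policy="sci_like", seed=1)
mi = generate_group_panel(30, length=1000, policy="mi_like", seed=1)

comparison = compare_groups(sci + mi, "SCI", "MI", n_reps=200, Lmax=10, seed=1)
cols = ["length_bin", "obs_freq_a", "obs_freq_b", "obs_ratio", "theo_ratio", "status"]
print(comparison.table[cols].round(5).to_string(index=False))

row = comparison.table.set_index("length_bin").loc[8]
print(
    f"\nbin 8: theo ratio ~{row.theo_ratio:.2f} (same compositions), "
    f"obs status = {row.status}"
)
# The depleted panel has no 8 bp runs at all, so the observed ratio at bin 8
# is flagged undefined_zero_denominator (an 'infinite' enrichment) while the
# theoretical ratio stays near 1: the depletion is a property of the observed
# sequences, not of their base composition.
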