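"""Decompose sequences into maximal homopolymer runs and build spectra.

A homopolymer run is a maximal stretch of identical consecutive bases; the
run-length spectrum counts runs by length (lengths >= 10 top-coded at 10).
"""

from polyslip import NucSequence, barcode_track, pooled_spectrum, split_runs, spectrum

seq = NucSequence("demo", "ATTTAACC")
runs = split_runs(seq)
print("runs of ATTTAACC:", [(r.base, r.length) for r in runs])
# -> [('A', 1), ('T', 3), ('A', 2), ('C', 2)]: the sequence tiles exactly
#    into 4 maximal runs.

sp = spectrum(runs)
print("spectrum counts:", sp.counts)          # {1: 1, 2: 2, 3: 1}
print("spectrum proportions:", sp.proportions)  # one quarter / half / quarter

pool = pooled_spectrum([seq, NucSequence("demo2", "GATTACA")])
print("pooled counts over two genes:", pool.counts)
print("mass conservation: total bases =", pool.total_bases, "= 8 + 7")

track = barcode_track(seq, min_len=3)
print("barcode values (runs >= 3 bp):", track.values)
# Only the TTT run reaches the barcode; shorter runs render as 0 (white).
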