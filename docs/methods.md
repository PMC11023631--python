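# Methods

## Run decomposition and spectra

A *homopolymer run* is a maximal stretch of identical consecutive bases.
Runs of a sequence are sorted, non-overlapping, and tile the sequence
exactly, which gives two conservation laws used throughout the tests: run
lengths sum to the sequence length, and joining the runs reproduces the
input. Spectra count runs by length with a top-code bin: all lengths
≥ `Lmax` (default 10) are collected in the `Lmax` bin, while raw lengths are
retained internally so conservation can still be checked after binning.
Pooled spectra concatenate per-sequence run lists; runs never span sequence
boundaries, so pooling is additive.

Coordinates are 0-based half-open internally; all human-facing tables are
1-based, with the A of the ATG start codon as position 1 for ATG-relative
reporting. Sequences are uppercased on load, `U` is mapped to `T` with a
warning, and residues outside `{A, C, G, T}` are rejected by default with a
position-naming error (an opt-in `drop` mode discards such sequences with a
logged warning instead). Silently breaking runs at ambiguity codes would
bias spectra, which is why rejection is the default.

Barcode tracks store, per position, the length of the covering run if it is
≥ `min_len` (default 3, matching the convention of showing only runs of
three or more repeats) and 0 otherwise; `max_len` (default 8) is a display
saturation only.

## The shuffle null

The theoretical ("theo") spectrum of a sequence is the expected spectrum
under uniformly random permutation of its residues — composition is
preserved exactly, ordering is destroyed. Each sequence is shuffled
independently; a group's theoretical spectrum pools the per-sequence null
means and normalizes to proportions.

The Monte Carlo estimator (default 10,000 replicates, as in the original
analysis protocol) draws permutations by argsorting i.i.d. uniform keys,
which is uniform over permutations; run counting is vectorized across
replicates. Per-bin means and standard deviations are returned; the SD is
retained for tolerance-based testing, not as a claimed analysis output.
Reproducibility: per-sequence RNG streams are derived from
`(root seed, SHA-256(sequence id))`, so results are bit-identical for a
fixed seed regardless of iteration order or parallelism.

Two independent oracles back the estimator:

1. **Exact enumeration** over all distinct permutations of the base multiset
   (equal weights, since every distinct arrangement corresponds to the same
   number of labelled orderings), refused above a configurable cap
   (default 10^5 distinct permutations).
2. **Closed form** for the i.i.d. law: the expected number of maximal runs
   of length exactly `L < n` is
   `Σ_b [(n−L−1)·p_b^L·(1−p_b)² + 2·p_b^L·(1−p_b)]` (interior + edge terms,
   interior term 0 when `n−L−1 < 0`), and `Σ_b p_b^n` for `L = n`. The
   formula is validated in the test suite against exhaustive enumeration of
   all `4^n` sequences (weighted by their i.i.d. probability) for small `n`.
   The permutation null of one long i.i.d. draw tracks the closed form
   closely because, at uniform composition, first-order fluctuations of the
   empirical base frequencies cancel in `Σ_b p̂_b^L` (the constraint
   `Σ p̂_b = 1` makes the gradient contributions sum to zero).

## Group comparison

Observed frequencies pool run counts across a group's sequences before
normalizing (`mode="pooled"`); whether published group frequencies pool runs
or average per-sequence proportions is not generally knowable, so a
`mode="mean"` alternative exists and the pooled convention is the default
assumption. Enrichment ratios are reported as group A over group B (the
"SCI over MI" orientation) for both observed and theoretical frequencies,
with per-bin status flags: `finite`, `zero_numerator`, or
`undefined_zero_denominator`. No pseudo-counts are added by default — a raw
differential is what the ratio is meant to capture; a `pseudocount` option
exists for exploration and is documented as non-canonical. No confidence
intervals are claimed for ratios.

## Variant filtering and attribution

Input is a Freebayes-dialect VCF with per-allele observation counts (`AO`,
`RO`) and per-strand counts (`SAF`, `SAR`, `SRF`, `SRR`). Multi-allelic
sites are decomposed into one record per ALT allele. The allele frequency
defaults to `AO/(AO+RO)` (robust to depth inflation from overlapping
alleles; `AO/DP` is available) — the exact denominator behind a published
"0.1% threshold" is typically unstated, so both are exposed and the choice
is configurable.

Filters:

- **Frequency**: keep records with `freq ≥ min_freq` (default 0.001,
  appropriate to ~10,000× coverage). Boundary semantics: the exact
  threshold value is kept.
- **Strand balance**: two-sided Fisher exact test on
  `[[alt_fwd, alt_rev], [ref_fwd, ref_rev]]`; remove records with
  `p < strand_alpha` (default 0.05, no multiple-testing correction). Using
  ref reads as the per-site baseline means "balance" is judged against the
  locus's own strand coverage. The p-value is computed by exact integer
  hypergeometric summation: with margins fixed, all table probabilities
  share the denominator `C(N, a+c)`, so numerators are compared as exact
  integers and no floating-point tie tolerance enters. α, sidedness and the
  2×2 construction are package choices; they are exposed as configuration.
- Records lacking strand counts are kept but excluded from the strand test
  (warned and counted); all-zero tables are excluded with a warning. Every
  input record ends as either a survivor or a removal with exactly one
  recorded reason, and the two filters commute.

Indels are parsimony-trimmed and left-aligned against the reference before
attribution (VCF encodes homopolymer indels ambiguously; without
normalization, right-shifted anchors would miss runs). An indel is
attributed to run R iff its net inserted/deleted bases are all `R.base` and
its normalized anchor lies within R or at the position immediately 5' of R;
runs shorter than `min_len` (default 3) are not targets. SNVs and MNVs are
never attributed. Outputs are a per-position table (ATG-relative position,
variant type, frequency) and a per-run table (run start, base, length,
summed indel frequency, variant count).

## Array maps

SCI spans and IS elements are given in 1-based inclusive coordinates. The
normalization maps the inclusive endpoints linearly onto [0, 1]
(`x ↦ (x − envelope_start)/(envelope_end − envelope_start)`); this
position-based convention is what makes an element at [1500, 1600] of an
envelope [1000, 2000] land exactly at [0.5, 0.6]. Reflection (`x ↦ 1 − x`,
strands flipped, `unknown` preserved) is applied when the integrase sits on
the right, and is involutive to < 1e−12. Gaps between split SCI parts are
flagged as interspace. For an IS pair, the invertible segment runs from the
end of the upstream IS to the start of the downstream IS, exclusive of the
elements themselves; pairs with equal orientations are `direct_repeat`, and
any unknown orientation yields `indeterminate`.

## Synthetic data

The generator exists so every stage has a ground-truth exercise:

- **Genes** are drawn i.i.d. from a base composition (default uniform —
  chosen as the neutral reference composition; real integrase genes deviate
  modestly). Planted runs are overwritten post-draw and *flank-guarded*
  (the bases immediately 5' and 3' are forced to differ from the run base)
  so the planted maximal length is exact. `orf_mode` enforces an ATG start,
  terminal TAA, and no internal stop codons by resampling free positions of
  offending codons; conflicts with planted runs raise rather than silently
  move the plant.
- **Panels**: `sci_like` plants one run of length 7–9 (uniform) per
  sequence at a random guarded position; `mi_like` rejection-samples until
  no run exceeds 5 bp; `iid` is unmodified. Defaults (50 sequences ×
  1,000 bp) match the scale used by the calibration and recovery analyses.
- **Variants**: each run of length L ≥ 3 emits one ±1-unit indel of its own
  base, left-aligned with the anchor base 5' of the run, at allele frequency
  `min(r1·g^(L−1), rate_max)` with defaults r1 = 1e−5, g = 4, cap 0.5. The
  geometric growth is an implementation choice for testability — slippage
  rates rise steeply with repeat number, but no quantitative SSM law is
  claimed. Background SNVs occur at 1e−3 per site with frequency 2e−3;
  read counts are Binomial(coverage, rate) at default 10,000× and split
  Binomial(n, 0.5) by strand, except for a configurable fraction of planted
  strand artifacts that put all alt reads on one strand. Ground truth lists
  every emitted variant exactly once with its generating mechanism.

What the generator does **not** emulate: codon usage and amino-acid level
constraints, sequencing error profiles beyond the flat SNV rate, read-level
artifacts (no FASTQ), selection or population dynamics. Passing tests
therefore demonstrate correctness of the statistical machinery on data whose
generating process is known, not that real integrase sets will show any
particular effect size.

## Numerical and scaling choices

- Monte Carlo nulls default to 10,000 replicates; the calibration and
  recovery analyses in the test suite and acceptance script use 100
  replicates per sequence — pooling over 50 sequences per group makes the
  effective replicate count 5,000, ample for the loose [0.5, 2] ratio band
  — and the long-sequence closed-form check uses a 10 kb sequence at 10,000
  replicates.
- The exact-enumeration oracle is capped at 10^5 distinct permutations; the
  brute-force i.i.d. enumeration at n ≤ 10.
- Degenerate inputs: an empty run list yields a spectrum with
  `total_runs = 0` and flagged-undefined proportions rather than an error;
  a single-base composition shuffles to itself with zero variance.
- Ratio bins with zero denominators are flagged, never silently dropped or
  padded.

## Known limitations

- The two-group ratio of *pooled* frequencies is sensitive to a few long
  sequences dominating a group; the `mode="mean"` alternative trades that
  for sensitivity to short sequences.
- At bins whose pooled expected count is only a few units, the observed
  enrichment ratio between two same-law panels is the ratio of two small
  Poisson-like counts and routinely leaves [0.5, 2]; calibration statements
  for such bins are unstable by nature, and the acceptance script reports
  the measured pass rate rather than asserting stability.
- The Fisher strand test assumes reads are independent; overlapping mates
  and PCR duplicates violate this upstream of the VCF.
- GFF3 support in `read_feature_table` covers the minimal fixed-field
  dialect used for these feature tables, not the full specification.
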