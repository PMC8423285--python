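# Methods

## Codon-usage comparison

Coding sequences are taken from GFF3 CDS rows (1-based inclusive
coordinates; multi-segment CDS sharing an ID are spliced in coordinate
order, minus-strand features reverse-complemented so every CDS is in
reading orientation). Validation drops, with a logged reason, CDS whose
length is not a multiple of 3, CDS with in-frame stops before the final
codon, CDS containing ambiguity codes (codon counting would be
ill-defined), and partial CDS with annotated phase ≠ 0. Each of these is a
policy flag on `ValidationPolicy`; the defaults are the strict choices.
The final stop codon is retained by default — only start codons are removed
before counting — with a flag to drop it.

Counting is pooled: one count table per organism across all retained CDS,
because the frequency definition divides by the total codon count, not by
genes. Relative frequency is `f_i = N_i / N`; the phage:host ratio is
`r_i = f_i^phage / f_i^host`. Binning uses thresholds (0.9, 1.1); the three
verbal clauses (≥ 1.1 higher; between 0.9 and 1.1 similar; < 0.9 lower)
only partition cleanly with "similar" read as the half-open interval
[0.9, 1.1), so r = 0.9 is *similar* and r = 1.1 is *higher*. A codon with
host frequency zero has an undefined ratio: it is flagged rather than
treated as infinite, and excluded from top/bottom-k rankings. Rankings
break ties lexicographically by codon so output is deterministic.

GC content is (G+C)/(A+C+G+T) with ambiguity characters excluded from both
numerator and denominator.

## tRNA-anticodon cross-reference

Anticodons are kept in the DNA alphabet, written 5'→3', matching the
output of common tRNA predictors; the exact cognate of a codon is then its
reverse complement. The adaptation report lists every defined codon with
`r_i ≥ min_ratio` (default 1.1) and whether any supplied anticodon reads
it. Wobble is off by default — the biological question ("does the phage
carry a tRNA corresponding to this codon?") is usually asked with exact
correspondence — but a rule table can be enabled: G34 also reads
third-position T (G:U pairing), T34 also reads G, and A34 is treated as
inosine-like, reading T, C and A. Wobble-on matches are by construction a
superset of wobble-off matches.

## One-step growth kinetics

No standard closed-form estimator exists for reading latent period, rise
period and burst size off a sampled one-step curve, so the package defines
an explicit rule set and treats published values as recovery targets for
simulation rather than recomputable quantities:

* scanning left to right, the baseline is the geometric mean of points seen
  so far; burst onset is the first point exceeding baseline ×
  `rise_factor` (default 2.0 — a titer doubling);
* latent period is the last sampled time before onset, reported at
  sampling resolution (no interpolation; a 10-min grid gives 10-min
  precision);
* the plateau is the maximal suffix of points whose log10 range is ≤
  `plateau_tol` (default 0.1 decades), at least 2 points, starting no
  earlier than onset;
* rise period is first plateau time − latent; burst size is plateau
  geometric mean / baseline geometric mean.

Geometric (log-space) means are used because plaque titers are
log-distributed. Latent and rise are combined across replicates by median
(both are grid-valued); burst by mean with its standard error across
replicates. Degenerate inputs raise: a curve that never exceeds the
baseline threshold ("no burst detected"), or whose tail never settles
("no plateau").

These rules invert the synthetic template exactly: a noise-free simulated
curve (baseline until latent, log-linear rise to baseline × burst, then
plateau) is recovered without error on the sampling grid, and at
multiplicative noise of 0.02 decades per point the estimates stay within
one sampling interval (latent, rise) and 20% (burst) in well over 90% of
seeds — the property the test suite checks at 200 seeds.

## Plating and EOP

Spot titers use the most dilute spot whose count lies in a countable
window, default [3, 100] plaques per 10 µL spot — the most dilute choice
minimizes plaque-overlap bias; the window is a judgment call documented
here since counting limits for 10 µL spots are rarely stated. Titer is
`count / spot_volume × 10^exponent`. EOP is `100 × titer_s / max titer`,
the reference strain taking exactly 100%; ties for the reference break by
input order. Summaries print percentages to 2 significant figures; JSON
retains full precision.

## Biofilm statistics

The gate: both groups are Shapiro–Wilk tested (scipy's implementation,
Royston approximation); if both give p > 0.05 *and* the design is paired,
a two-sided paired t-test compares the means, otherwise a two-sided
Mann–Whitney U. The normality alpha of 0.05 and two-sidedness are package
defaults, stated here because gating conventions vary. Crystal-violet
absorbance wells are treated as paired (treated/untreated wells from the
same plate layout); confocal viable-cell counts as independent groups —
unpaired data always routes to Mann–Whitney regardless of normality.

The U test is exact (full enumeration) when both groups have n ≤ 8 and no
ties, and otherwise uses the tie-corrected normal approximation with
continuity correction, mid-ranks for ties. The exact branch is verified in
the tests against brute-force enumeration of all C(n_a+n_b, n_a)
assignments for all group sizes ≤ 6.

## Synthetic data

Generators are pure functions of spec + seed (one
`numpy.random.default_rng` stream per call, no global state; fixed seed
gives byte-identical FASTA/GFF output).

*Genomes.* Each gene is ATG + body codons + one stop codon. Body amino
acids are drawn i.i.d. (uniform over the 20 by default), then codons from
per-amino-acid weight vectors; genes are placed on alternating strands
with 20 bp random spacers. The emitted truth tables condition on the
realized codon totals, so `f_i` truth sums to 1 exactly and the pipeline's
estimate is multinomial around it. `boosted(codon, factor)` multiplies one
codon's weight within its synonymous family and renormalizes the rest, so
the target codon's relative frequency rises by the factor while its
synonyms fall. The `study_like_genome_pair` preset gives the phage five
over-used codons — one threonine codon at 3.1× and four others at 2.8× —
against a host with uniform synonymous usage, emulating a phage whose
codon preferences are measurably shifted from its host's. What these
genomes do *not* emulate: real amino-acid composition, gene-length and
strand organization, operons, or mutational GC pressure — so passing
recovery tests demonstrates estimator correctness under the model, not
robustness to real genome architecture.

*Growth curves.* Deterministic piecewise log-linear template (defaults:
latent 20 min, rise 30 min, burst 12, baseline 10⁴ PFU/mL, 10-min
sampling) with multiplicative log-normal noise per point (default σ = 0.02
decades); horizon defaults to latent + rise + 3 intervals and must cover
latent + rise.

*Spot series.* Counts are Poisson with mean `titer × volume × 10^-e`, the
correct counting model for plaques from a well-mixed dilution.

*Biofilm data.* Control group around a baseline (1.0 AU absorbance, or
200 cells/field for counts); the treated mean is reduced by the effect
preset (none: 0%; strong_reduction: 60%). Noise is normal with CV 10% or
right-skewed lognormal (σ_ln = 0.5). The counts default n = 42 mirrors a
14-field × 3-replicate confocal counting design. Pairing follows the data
kind (absorbance paired, counts unpaired); paired samples are generated
independently, i.e. without well-level correlation, which makes the paired
t-test's advantage conservative in simulations.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data:
codon-ratio recovery uses ~10⁵ codons per organism (300 genes of 250–420
codons), growth recovery 200 seeds × 3 replicates, the type-I error check
2000 null simulations at n = 42 (rate required within a 3σ binomial band
of 5%), and power checks 100 seeds. Frequency sums are asserted to 1e-12,
ratio reciprocity to 1e-9. Exact-test comparisons against enumeration are
asserted to 1e-12.

## Known limitations

Codon analysis ignores gene expression weighting (every CDS counts
equally) and offers no RSCU/CAI/tAI-style indices. The kinetics extractor
assumes curves begin in the latent phase and will mistake a late secondary
rise for noise only insofar as the plateau rule tolerates it. Exact
Mann–Whitney is limited to small tie-free samples by design; larger
samples get the asymptotic p-value. The wobble rule table is a coarse
summary of pairing chemistry, intended for exploratory matching only.
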