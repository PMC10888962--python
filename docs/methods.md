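# Methods

## The screen model

A tiled spacer library assigns one spacer to every `stride`-th position of
each strand of a phage genome of length `L`; with spacer length `k` the
library holds `2·(⌊(L−k)/stride⌋+1)` members (defaults `k = 35`,
`stride = 2`; `k` is a required design parameter because published library
sizes constrain but do not fix the `(L, k)` pair). Coordinates are 0-based
half-open on the plus strand for both strands; a minus-strand spacer is the
reverse complement of its interval, so its crRNA is complementary to the
transcript made from the plus strand. Cloning oligos are
`upstream_flank + spacer + downstream_flank` with a fixed total length
(default 90 nt, flanks 30 + 25 nt). The default flanks are placeholder
sequences carrying a universal priming site and a BsaI site on each side;
real designs should supply their own `OligoLayout`.

## Spacer extraction

An amplicon read is scanned for occurrences of the direct repeat by ungapped
Hamming matching within `max_mismatches` (default 1; indels in short
amplicons are rare enough that the O(read × repeat) Hamming scan is the right
trade-off). Occurrences are selected greedily left-to-right so consecutive
repeats share no bases; every insert between two consecutive occurrences
whose length falls in `[min_insert_len, max_insert_len]` (default [30, 45],
bracketing type III-A spacer lengths and excluding repeat–repeat artifacts)
is counted verbatim. No error correction or clustering is applied — an
insert with an internal sequencing error becomes a distinct key, which the
downstream design-lookup step simply fails to match and tallies in QC.
Reads are scanned in both orientations by default; base qualities are
ignored. Internally, same-length read chunks are padded into a byte matrix
and all repeat offsets are computed vectorised; a `str.find` fast path
handles the zero-mismatch case. Both paths are property-tested against the
single-read scanner.

## Enrichment landscapes

Frequencies are raw fractions `f_s = c_s/Σc` per sample. The enrichment
ratio `E = f_t/f_0` uses no pseudocounts: spacers with a t0 count below
`min_t0_count` (default 5) are excluded (`absent_t0`) rather than inflated,
because pseudocounts would bias region means computed over ratios; spacers
undetected post-infection keep `E = 0` (`absent_t`). Landscapes place every
spacer at the start of its plus-strand interval (one shared x-axis for both
strands) and are split by matched strand. Multi-mapping and N-overlapping
spacers are excluded from landscapes and tallied, never double-counted.
Region summaries report the mean and sample SD (n−1 denominator, the
conventional reading of "±") of `E` per region × strand, plus the count of
detected spacers. Default region boundaries on the simulated genome put PE at
[1000, 15000) and PL at [15000, 42000), with the PE upstream/downstream split
at the PE midpoint; all three are configuration, not constants, because the
biological boundary between Csm6-independent and Csm6-dependent early-operon
targeting is an empirical property of each system.

## Acquisition mapping

Acquired spacers are aligned by ungapped two-strand Hamming search (budget
default 1; acquired spacers are exact genome substrings barring sequencing
error, so gapped alignment adds nothing). Ties at the best mismatch count
are multi-hits; multi-hit and unmapped queries are dropped from coverage and
tallied, avoiding inflation of repeated loci. Uniquely mapped hits increment
every covered position on their strand; RPM = 10⁶ × count / denominator,
with the denominator (all aligned reads, including any non-phage fraction)
supplied explicitly so the normalisation stays auditable. bedGraph output is
run-length encoded and floats are written with full repr precision so a
write/read round-trip is exact.

## Expression correlation

Coverage tracks are normalised by `reference/library_size` with the
reference equal to the smallest library among the timepoints — down-scaling
never extrapolates. A spacer's target expression is the *mean* normalised
coverage over its interval (length-invariant for fixed `k`); plus-strand
spacers have no transcript target and are flagged rather than scored.
Pearson r is computed from the product-moment definition (and cross-checked
against an independent implementation in the tests); correlation is computed
on untransformed values by default with a log10(1+x) option, since the scale
choice is presentation, not inference.

## Phenotype statistics

A well "regrew" when its OD600 series crosses the threshold (default 0.5)
within the horizon (default: last timepoint common to all wells), with the
crossing time linearly interpolated between bracketing samples. Fractions
are reported per replicate with binomial SD, as mean ± SD across replicates,
and pooled — published "~44%"-style figures may be either, so both are
returned. Group comparisons use Welch's unequal-variance t-test built from
the formulas (two-sided p from the t distribution with Welch–Satterthwaite
degrees of freedom); Welch is the safe default when equal variances are not
asserted. Zero-variance groups with equal means give t = 0, p = 1; with
unequal means the comparison is flagged degenerate. OD input is assumed
blank-corrected. The escaper fraction is the plaque-count ratio
targeting-host / naive-host.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular phage:

- **Genome**: seeded i.i.d. sequence with rejection-resampling until no
  20-mer repeats on either strand, which guarantees every `k ≥ 20` spacer
  maps uniquely — real genomes violate this mildly, which is why the mapper
  tracks multi-hits at all. Default layout: `L = 42,000`, PE = [1000, 15000),
  PL = [15000, 42000), both operons transcribed from the plus strand.
- **Amplicons**: reads are repeat + spacer + repeat + random filler to a
  150-nt MiSeq-like read, spacers drawn multinomially, substitution errors
  i.i.d. per base (default 0.1%). No quality-score structure, PCR
  duplicates, or indel errors are modelled, so extraction tests certify the
  matching contract, not robustness to platform-specific artifacts.
- **Selection**: spacers fall into four classes by strand and region
  (plus-strand, minus-PE-upstream, minus-PE-downstream, minus-PL);
  minus-strand spacers upstream of PE have no transcript target and share
  the plus-strand (non-targeting) class. Each lineage survives with
  probability 1 − dropout(class) and is re-sampled with weight
  f0 × fitness(class). The preset magnitudes — wt (0.3, 10, 8, 0.3), no
  dropout; dcsm6 (0.3, 10, 0.1, 0.05) with dropout (0.8, 0, 0.5, 0.9);
  cas10hd (0.3, 0.8, 0.8, 2.0), no dropout — are simulator conventions
  chosen to reproduce qualitative orderings only (early-operon dominance in
  wt, loss of Csm6-dependent classes in dcsm6, mild late-operon advantage in
  cas10hd). Tests and the acceptance script assert orderings and
  calibrations, never these magnitudes.
- **RNA-seq**: PE expressed from the first sampled minute with a linear
  5′→3′ decay to 0.2× (so downstream PE targets see less transcript); PL
  silent before 15 min, flat afterwards; Poisson noise; per-timepoint depth
  factors (1.0, 1.4, 1.8) create the library-size variability normalisation
  must undo.
- **Acquisition**: wt draws 90% of spacers from minus-PE, 5% minus-PL, 5%
  plus; dcsm6 concentrates the 90% into minus-PE-upstream; cas10hd emits a
  uniform strand-balanced background at 1% of the wt yield.
- **Wells**: Bernoulli regrowth (default p = 0.44 over 5 × 96 wells),
  logistic OD curves with lag ~ U(10, 15) h for regrowers, flat baseline
  otherwise, and initial GFP drawn from two normals with the non-regrower
  mean shifted up (higher phage burden in cells that stay arrested).

All randomness derives from one top-level seed via named substreams, making
every generated artifact byte-reproducible.

## Problem sizes and numerical choices

Deep-calibration checks (extraction recovery, neutral-model calibration) run
at 10⁶ reads over 2,000 spacers from a 3-kb genome. The three-genotype
rank-order screens run on a proportionally scaled 10-kb genome (PE
[400, 3600), PL [3600, 10000)) at 2 × 10⁵ reads per sample — rank orderings
are scale-free, so the scaled screen tests the same contract the full-size
layout would. Acquisition mapping runs at full genome scale (42 kb, 10⁴
spacers). Frequency normalisation is checked to 1e−9; the Welch statistic to
1e−8 against an independent reference; coverage round-trips exactly.

## Known limitations

Extraction assumes substitution-only errors and a single repeat species; the
aligner is ungapped by design, so spacers spanning real indel variation
would go unmapped; enrichment carries no significance model (the screen's
readout is the landscape itself, and replicate dispersion modelling is out
of scope); growth curves are summarised by threshold crossing, not fitted
growth models. Passing the synthetic suites certifies the analytic
contracts, not performance on any particular sequencing platform's error
profile.
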