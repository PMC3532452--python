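# Methods

## Problem and approach

`frcurve` evaluates a *de novo* genome assembly without a reference
sequence.  The only inputs are the assembly itself, coordinate-sorted
alignments of the sequencing libraries back to that assembly (one
short-insert paired-end library, optionally one long-insert mate-pair
library), rough insert-size estimates for each library, and an estimate of
the genome length.  The premise is that almost every class of assembly
error leaves a footprint in how read pairs align: collapsed repeats compress
the apparent fragment lengths spanning them, insertions stretch them,
inversions flip one mate of straddling pairs, misjoins strand mates across
contigs or at aberrant distances, and copy-number errors distort coverage.

The tool turns those footprints into 14 typed "features" (suspicious
regions) and summarises the assembly as a Feature Response Curve: contigs
are sorted from longest to shortest and, for each feature budget τ, the
longest prefix of contigs whose cumulative feature count stays within τ is
tallied; its summed length divided by the estimated genome size G (capped
at 1) is the approximate genome coverage — one curve point.  Steeper curves
mean more genome recovered per unit of suspicion.

## Pair classification

Every counted read (primary, non-duplicate, non-QC-fail alignments at or
above a configurable MAPQ floor, default 0) with an expected mate falls in
exactly one class:

- **singleton** — mate unmapped;
- **spanning** — mate on a different contig/scaffold;
- **outie** — pair orientation differs from the library's convention
  (innie = FR for paired-end, outie = RF for mate-pair; same-strand pairs
  are always mis-oriented), or the observed fragment length deviates from
  the library mean by more than k·σ (k = `tolerance_k`, default 3, strict
  inequality);
- **proper** — everything else.

The observed fragment is the outermost-coordinate span of the two mates
(standard TLEN semantics).  All internal coordinates are 0-based half-open;
GFF3 output is 1-based inclusive.

## Tracks and global statistics

Per contig, six per-position counters are accumulated (read coverage,
proper-pair coverage, fragment-span coverage, and singleton/outie/spanning
read counts) plus, on a sliding window grid (window 1000 bp, step 200 bp by
default), the multiset of fragment lengths of proper pairs whose span
covers each window midpoint (each pair contributes once, from its leftmost
mate).

Library means are taken over all assembled positions.  Insert statistics
are re-estimated from proper fragments after discarding values outside the
user prior ± 5σ — the user estimate is explicitly rough; the refined σ is
floored at 1 bp to survive degenerate samples.

## Feature detectors

**Coverage features (PE only).**  A position is low-coverage when its read
coverage falls below `cov_low_frac` (default 1/3) of the library mean and
high-coverage above `cov_high_frac` (default 3) times the mean; the same
rule on proper-pair coverage gives the LOW/HIGH_NORM variants.  Maximal
runs are reported, merged across gaps below `merge_gap` (default 200 bp),
and dropped below `min_region` (default 200 bp).

**CE features.**  For each window the compression/expansion statistic is
Z = (m − μ)/(σ/√n), with m the local mean of the n spanning fragment
lengths and μ, σ the (refined) library insert statistics.  Z < `ce_low`
(default −3) flags compression, Z > `ce_high` (default +3) stretch.
Windows with no spanning fragments yield no CE evidence — absence of
evidence is not compression (they may still trigger coverage features).

Two calibration details matter:

1. *Length bias.*  Fragments sampled because they span a locus are drawn
   with probability proportional to their length, so the null mean of m is
   μ + σ²/μ, not μ.  At this package's default study conditions the
   uncorrected shift is +1.1 (PE) to +1.7 (MP) z-units — enough to make
   stretch calls fire on perfectly clean data — so the windowed detector
   subtracts σ²/μ by default.  `ce_statistic` itself applies no correction
   (its argument may be any i.i.d. sample); the flag
   `length_bias_correction` selects the spanning-sample null.
2. *Mark extent.*  On the default grid adjacent windows overlap 5×, and
   each anomalous locus would be marked up to window/step times over if the
   full window were flagged; a chance exceedance would mark 1 kb.  Each
   flagged window therefore marks the step-sized stripe centred on its
   midpoint — the locus its sample actually measures.  The stripes tile the
   contig, so contiguous flagged windows still merge into full-extent
   regions, and with a non-overlapping grid (step ≥ window) the stripe is
   the whole window.  This keeps the null flagged fraction near the nominal
   2·Φ(−3) of assembled bases instead of ~5× that.

**Pair-anomaly features.**  A window is flagged when the offending-class
base fraction (class counter sum over read-coverage sum) exceeds
`anomaly_frac` (default 0.4); zero-coverage windows are skipped.  Types
follow the library (HIGH_SINGLE/HIGH_SPAN/HIGH_OUTIE, _PE or _MP suffix).
Marking and merging are as for CE features.

All thresholds are package defaults exposed as configuration; none are
claimed to reproduce any particular external tool's internal settings.

## Curves and summary statistics

The curve uses the inclusive convention (cumulative feature count ≤ τ), so
τ = 0 reads as "the clean fraction of the assembly"; a strict sweep over
integer τ gives the same point set shifted by one.  Length ties are broken
lexicographically by contig id for run-to-run determinism.  Per-feature
curves repeat the computation counting one type at a time, and therefore
dominate the global curve pointwise.  NG50 is the length of the contig at
which the descending cumulative length first reaches G/2 (0 if never);
chaff is the percentage of G held in contigs shorter than 200 bp.  Chaff
contigs are kept in the curve by default (`--exclude-chaff` removes them).

## Validation

Sensitivity and specificity are per assembled position: TP/FN partition the
truly mis-assembled bases by whether any feature covers them, TN/FP the
correct bases, so TP+FP+TN+FN equals the assembled length.  Undefined
ratios (empty truth; everything flagged) are reported as n/a rather than 0.
`slack` dilates truth intervals before scoring because breakpoint-driven
features (e.g. mis-oriented pairs at an inversion edge) flank an event
within about one insert length rather than covering its body.

## Synthetic benchmark

The generator emulates the study conditions end to end: an i.i.d. random
genome at a chosen GC (optionally with planted exact repeat families), a
corrupted assembly produced by typed events, and Illumina-like libraries —
innie PE pairs (insert 300 ± 30 bp, 80×, 100 bp reads) and outie MP pairs
(insert 3000 ± 300 bp, 20×), Gaussian fragment lengths truncated at two
read lengths, uniform substitution errors at 1%.  Pair counts are exactly
⌊coverage·L/(2·read_len)⌋.

Alignments are produced by exact liftover rather than a real mapper: each
read is placed at the image of its true reference interval, reads from
deleted or foreign sequence go unmapped, reads inside inversions flip
strand, and reads overhanging an event junction by more than 20 bp go
unmapped (a real aligner would clip or reject them); smaller overhangs are
soft-clipped.  This makes tests hermetic and the expected evidence exactly
derivable — fragments spanning a collapsed 500 bp repeat copy are shorter
by exactly 500 bp — at the cost of not modelling mapping ambiguity in
repeats or alignment noise; conclusions about real data must allow for
both (any coordinate-sorted BAM from a real mapper works at the CLI).

Event truth intervals are the affected body for inversions, expansions and
chimeric insertions, and each junction ± one PE insert mean for
compression, deletion, relocation and fragmentation junctions.  The
standard benchmark places six events on a 100 kb genome: inversions of
2.5 kb and 2 kb, a 500 bp tandem-repeat collapse, a 1 kb chimeric
insertion, a 2 kb relocation moved 8 kb downstream, and one fragmentation.
Benchmark validation uses slack of one MP insert mean, and the clean-run
false-positive accounting excludes one MP insert mean at each contig end,
where span coverage necessarily decays.  These sizes keep the full
benchmark under ~10 s on one CPU; they scale linearly via
`BenchmarkConfig`.

## Numerical and degenerate-input choices

- Empty alignments raise "empty alignment" rather than returning zeros.
- Refined insert σ is floored at 1 bp; CE requires σ > 0.
- Windows are clipped at contig ends; a contig shorter than one window is
  a single window.
- Reads extending past the contig end are a hard error (corrupt input).
- Merged regions shorter than `min_region` are dropped *after* merging.
- Co-located mates on opposite strands are treated as innie (the forward
  read is taken as leftmost).

## Known limitations

- Multi-mapping reads: a MAPQ floor is exposed (default 0 = keep
  multimappers) but no rescue of ambiguous placements is attempted; heavy
  repeat content degrades feature precision with real aligners.
- One PE plus at most one MP library; no support for merging multiple
  libraries per role.
- The simulator has no quality scores, PCR duplicates, indel errors or
  coverage bias; uniform substitutions only.
- Breakpoint-type events are localised only to within about one insert
  length; per-event boundaries are not refined.
- Scaffold gap runs (N stretches) are ordinary positions; they typically
  surface as LOW_COV/HIGH_SINGLE regions rather than being treated
  specially.
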