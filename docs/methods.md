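# Methods

## Data model

A promoter tiling-array experiment is a set of physical two-channel
hybridizations. Each hybridization (one `array_id`, `replicate_id`
pair) measures every probe of one array of the set in two channels:
ChIP (immunoprecipitated chromatin) and input (whole-genome control).
Probes tile a window around each TSS — default −3500..+750 nt oriented
by gene strand — at a configured spacing (default 100 bp, one probe
per `floor(span/spacing)+1` grid position, probe length 50 nt).
Promoters are distributed round-robin over the arrays of the set, so a
promoter's probes always sit on one physical array.

## Synthetic data generator

The generator is the package's study condition, not a tuning knob. It
emulates:

- **Binding events.** A planted event has a promoter, a genomic
  center, a multiplicative strength ≥ 1 and a fragment size (default
  550 nt, the typical sonication fragment length). The expected
  ChIP/input ratio of a probe at distance *d* from the center is
  `1 + (strength − 1) · max(0, 1 − d/fragment_size)` — a triangular
  kernel, the simplest shape consistent with fragment smearing, with
  closed-form values at every probe. Excess enrichments of distinct
  events add. `plant_events` snaps centers onto the probe grid so one
  probe sits exactly at the kernel peak.
- **Intensities.** `input = B · bright · ε`, `chip = B · bright ·
  ratio · ε′`, with base intensity `B` (default 1000), a per-probe
  brightness factor `bright` (log-normal, log-sd `probe_effect_sd`,
  default 0.5) shared by both channels and all replicates, optional
  per-channel dye scale factors, and independent log-normal
  measurement noise of log-sd `noise_sd` per channel. The brightness
  factor is what makes the chip-vs-input Pearson correlation of a
  well-behaved array high (≈0.93 at `noise_sd = 0.2`, matching the
  0.91–0.94 a good hybridization shows) while cancelling exactly in
  the raw ChIP/input ratio, so the kernel is recovered exactly at
  `noise_sd = 0`. Real sources of structure the generator does *not*
  model: dye-swap designs, spatial artifacts, and probe-sequence
  affinity bias (brightness here is i.i.d., not sequence-driven).
  Passing tests therefore demonstrate correctness of the algorithms
  under idealized array physics, not robustness to vendor-specific
  artifacts.
- **Sequences.** Promoter-window sequences are i.i.d. with a
  configurable GC fraction; motif words (octamer `ATGCAAAT`, PORE,
  MORE, a SOX2 consensus 7-mer, or literals) are inserted verbatim at
  stated offsets, reverse-complemented for '−' plantings, with
  collisions rejected. Truth records every planting, including strand,
  so scanner strand symmetry is testable.
- **Knockdown expression.** `knockdown = B·effect·noise`,
  `control = B·noise` (default B = 200); any emitted value below the
  detection floor S (default 20) is clamped to exactly S, emulating
  expression platforms that floor background-level signals.

All generators are bit-reproducible under an integer seed.

## Normalization and QC

Quantile normalization is applied **array-wise**: the two channels of
one hybridization are normalized together, leaving hybridizations
independent (whether to normalize across replicates before forming
ratios is genuinely open; the per-array choice keeps arrays with
different probe sets independent, and a cross-array call is one
`quantile_normalize` on a wider matrix away). Each column's sorted
values are replaced by the across-column mean of order statistics;
ties receive the mean of the target values over the tied ranks. On
tie-free columns the transform is exactly idempotent; with ties the
tie-averaging perturbs the target on a second application, so the
first application is the canonical one. Intensities must be finite
and strictly positive — zeros and negatives are rejected at read time
with the offending rows named.

QC computes the Pearson chip-vs-input correlation per hybridization on
raw and normalized data, plus replicate-pair correlations per channel.
An array whose raw r falls below the exclusion threshold (default 0.5
— safely between a failed array's ≈0.16 and a good one's ≈0.9) or is
undefined (zero-variance channel) is excluded. Normalized r is
reported but never asserted to exceed raw r, which is data-dependent.

## Interval peak caller

Thresholds are array-specific: `t_center` and `t_flank` are the
(1 − 0.01) and (1 − 0.05) empirical quantiles (linear interpolation)
of the array's full ratio distribution; fewer than 100 probes triggers
an instability warning. A probe qualifies as a peak centre if its
ratio ≥ `t_center` and at least one probe strictly upstream *and* one
strictly downstream within 1000 nt (inclusive) has ratio ≥ `t_flank`.
A peak's support is the centre plus every flank-qualifying probe
within the distance cap; overlapping qualifying intervals merge
(union of supports); fewer than 3 supporting probes never emit. All
comparisons are ≥, so exact-tie degeneracies (e.g. a constant track)
are resolved inclusively — a deliberately literal reading: on a
constant track everything ties at the threshold and everything
qualifies. The production implementation is vectorized
(searchsorted + prefix sums); the test suite holds it to exact
equivalence with a naive quadratic transcription of the definition on
1000 random tracks.

Peaks anchor to their interval midpoint and link to the closest TSS
within 8 kb (strict), distance signed in gene orientation (negative
upstream); equidistant TSSs break lexicographically by gene id.

## Consensus scoring

Detections from all declared (detector, replicate) combinations merge
when separated by ≤ 50 bp (a common co-localization gap setting,
configurable). The peak score of a consensus event is
`|{(detector, replicate) contributing ≥ 1 interval}| / (D × R)` with
the denominator `D × R` declared in the run config and reported
alongside every score — with 3 detectors × 3 replicates the attainable
scores are the familiar 1/9, 3/9, 4/9 … 1.0 grid. Absent combinations
count as non-detections; scores are monotone under added detections
and invariant to detector relabeling.

## Motif model

- **Harvest.** All words within Levenshtein distance ≤ 2 of the
  octamer (lengths 6–10) are collected from region sequences on both
  strands. The neighbourhood is materialized once by breadth-first
  edit expansion (BFS level = exact edit distance), making the scan a
  set-membership test; the edit-distance routine itself is the
  textbook dynamic program and is cross-checked against an independent
  alignment library in the tests.
- **Merge.** Same-strand matches with gap ≤ 1 nt fuse transitively
  into the longest match.
- **PWM.** Words anchor to the 8-column consensus frame by their best
  ungapped alignment (most matches; ties prefer larger overlap, then
  the frame-aligned placement); overhangs are dropped and uncovered
  columns receive only pseudocounts. Column probabilities are
  `(count + c)/(n_cov + 4c)` with pseudocount c = 0.5 by default. The
  information-content (logo) form scales each column by
  `2 + Σ_b p log₂ p` bits, bounded by 2 bits/column.
- **Scanning.** Window score = `Σᵢ log₂(pᵢ(b)/q(b))` against a uniform
  background by default; '−'-strand windows are scored on the reverse
  complement and reported at forward coordinates. The octamer under
  its own zero-pseudocount PWM scores 8·log₂4 = 16 bits — the scale on
  which a ≈7-bit operational threshold is meaningful.
- **Threshold calibration.** No external score scale exists, so the
  cutoff is calibrated: the median of per-region best scores over
  regions with peak score ≥ 0.5. It is a data-dependent parameter, not
  a constant; the per-gene report always carries the raw best scores
  so any cutoff can be re-derived.
- **Fixed elements.** PORE (`ATTTGAAATGCAAAT`) and MORE
  (`ATGCATATGCAT`) are matched exactly (a mismatch-tolerance option
  exists but defaults to 0). MORE is its own reverse complement, so a
  '+'/'−' pair at one offset is one physical site and is reported
  once. Note the PORE's 3′ 8-mer *is* the octamer: a PORE-containing
  region is octamer-positive by construction.
- **Quality filters.** PWM alignment difference = minimum over
  ungapped offsets (≥ `min_overlap` columns, default 1) of the mean
  per-column Euclidean distance between probability columns;
  single-linkage clusters at < 0.2 keep only the highest-total-bits
  member. Dimer entropy is the Shannon entropy of the
  overlapping-dinucleotide distribution counted **circularly** (the
  word wraps), so every position contributes one dimer and perfectly
  k-periodic words score exactly log₂ k (AAAAAAAA → 0, ATATATAT → 1,
  ACGTACGT → 2 bits); words under 1 bit are discarded as
  low-complexity.
- **SOX2.** No canonical matrix ships with the pipeline's data; a
  consensus-built 7-mer PWM (`CATTGTT`) is provided for testing, and a
  user-supplied matrix (JASPAR text) with the same median-rule
  calibration is the intended production route.

## Classification

Primary modules from the OCT4/SOX2 flags: 1 = both, 2 = OCT4 only,
3 = SOX2 only, 4 = neither — a partition by construction. PORE (5) and
MORE (6) are overlays, independent of the primary label, because one
gene can legitimately carry both a SOX2 motif and a MORE element.
Module 1 requires co-occurrence anywhere in the scanned window, with
no adjacency requirement (an optional max-spacing filter exists, off
by default). Regulation: fold ≥ 2 is up, ≤ 0.5 is down (both
inclusive), otherwise unchanged; genes absent from the expression
table are unmeasured. Gene-list overlap reports normalize identifiers
(uppercase, version suffixes stripped); ortholog mapping is out of
scope.

## Numerical and procedural choices

- Quantile estimator: linear interpolation everywhere (thresholds and
  normalization targets).
- Peak midpoint is the TSS-distance anchor; ties in TSS distance,
  center-probe choice and best-hit offsets all have deterministic
  documented tie-breaks (lexicographic / leftmost / '+' strand).
- Degenerate inputs: empty tracks, zero-variance channels, regions
  shorter than the PWM, and missing expression conditions are all
  reported (error or flagged row) rather than silently dropped.
- Problem sizes in the test suite — 1000 random tracks for caller
  equivalence, 50 promoters × 10 replicates for noisy recovery, 50 ×
  2 kb regions for motif recovery — were chosen as the smallest sizes
  at which the asserted properties are statistically unambiguous.

## Known limitations

- The caller inherits the quantile definition's assumption that
  binding is rare (\<5% of probes); arrays where most probes sit under
  events push the thresholds into the signal and detection degrades —
  visible directly in simulations where every promoter carries an
  event under noise.
- Quantile normalization forces both channels onto a common value
  multiset; when the two channels genuinely differ in distribution
  (strong global enrichment), ratios after normalization are
  rank-faithful but not scale-faithful.
- External detectors are ingested as interval lists only; their
  statistical models are not reproduced, and consensus scores depend
  on the declared denominator, which is always reported next to the
  score.
- The expression integration is a fold-change call with a floor, not
  an error-model-based differential test.
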