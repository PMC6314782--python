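# Methods

## Coordinates and orientation

All internal coordinates are 0-based half-open with explicit strand. An
origin is oriented by the T-rich strand of its primary ACS; relative
position 0 is the 5'-most base of the ACS match on its own strand, negative
positions are upstream. Transcription along the T-rich strand is *sense*,
the opposite strand *antisense*. The bundled origin table encodes 1-based
strand-aware coordinates in which `Start` is the match's 5' end (so
`Start > End` on the minus strand) and `End = Start ± L` for a match of
length L; the parser converts to the internal convention and verifies, for
every row, that the 5'-to-5' distance between primary and secondary ACS
equals the printed protected length, and that the secondary ACS lies on the
opposite strand. Both properties hold for all 228 bundled rows.

Two conventions here were genuinely open and are fixed as follows. First,
relative position 0 is the first base *of* the match (not the base before
it); this makes "the 25 nt immediately preceding the ACS" the interval
[−25, −1] and is consistent with the protected-length identity. Second, the
+10..+400 secondary-ACS scan range is anchored at the primary ACS **5'**
end, again because the 5'-to-5' reading reproduces the printed protected
lengths exactly.

## Window extraction

Origin-relative windows are dense vectors indexed −upstream..downstream−1.
For minus-strand origins the genomic slice is reversed and the strands
swapped, so that sense/antisense always refer to the origin's own frame;
this makes profiles of mirrored constructions bit-identical (tested).
Positions overhanging a chromosome end are marked missing (NaN) rather than
zero-filled: the aggregation statistic is a median, and zero-padding would
bias it downward at the window edges. Each profile records the number of
informative origins per position.

## Metasite statistics

*Median occupancy* is the per-position median over informative origins,
computed separately for sense and antisense. No smoothing is applied.

*Termination events* are scored as presence/absence of at least one RNA
3'-end per origin and position; the profile value is the count of origins
with an event. This is deliberately scale-free — multiplying counts by any
positive factor, or applying any strictly positive monotone transform,
leaves the profile unchanged — so a few heavily transcribed loci cannot
dominate the aggregate.

*Positional significance.* The null hypothesis is that termination occurs
with a uniform frequency around origins. The baseline p₀ is the aggregate
event frequency (events summed over origins and positions, divided by the
corresponding origin-position count) in a 100-nt window starting at −500,
far enough upstream to be outside the roadblock footprint. For an observed
count k of n at a position, the raw p-value is the inclusive upper tail
P[Bin(n, p₀) ≥ k]; "at least as many events as observed" is the natural
one-sided reading of enrichment. Correction is Bonferroni —
p·M clipped at 1, with M the number of positions actually tested — the form
that matches a multiplicative multiple-testing factor. Tested positions
default to the full profile minus the null window; sense and antisense are
tested separately, each with its own M. A degenerate null (p₀ = 0 with
k > 0) is reported as p = 0 with an explicit flag rather than an error, so
a single pathological window cannot abort a scan.

## PWM model

Weights are log₂ odds of the (lightly pseudocounted) column frequencies
against a uniform background: w(b, j) = log₂((f(b,j) + pc·q)/(1 + pc)/q)
with pc = 0.0025 and q = 0.25. Raw window scores are min–max normalised by
the column-wise attainable extremes, so the column-argmax sequence scores
exactly 1 and the argmin sequence 0. A uniform matrix yields a degenerate
model (raw_max = raw_min) and scoring raises an explicit error. Windows
containing non-ACGT symbols either raise or are skipped, per caller choice;
the genome scan skips them. Because the original frequency matrix behind
the bundled table's score columns is not distributed with it, scores
recomputed on real sequence are not expected to be bit-identical to the
bundled values; no test or acceptance check requires score equality.

The secondary-ACS scan enumerates every opposite-strand window whose
own-strand 5' end lies 10–400 bp downstream of the primary anchor, keeps
the maximal normalised score, and breaks ties deterministically toward the
smallest distance. Only the single best hit per origin is retained.
Distance summaries report median (midpoint convention for even n) and mode
(smallest value on count ties), optionally after restricting to the 70–200
bp range considered biologically meaningful for a licensing-competent
spacing; both restricted and unrestricted summaries are available because
the restriction is an interpretive choice, not a property of the scan.

## Region quantification and replication metrics

The "area of origin activity" (region B) is under-determined in general;
the default is the only origin-intrinsic extent available — the protected
span between the two ACS 5' anchors, inclusive (length d+1) — with a
fixed-length fallback for origins lacking a secondary ACS annotation.
Region A is the 200 bp immediately 5' of B summed on the sense strand,
region C the 200 bp immediately 3' of B summed on the antisense strand;
each captures transcription incoming toward one origin border. B is summed
on both strands (B_a + B_as). A separate ranking window — both-strand sum
over the first 100 nt from the ACS 5' end — is kept as its own named
quantity because ranking analyses and region-B correlation analyses use
different definitions.

The coverage filter for "origins exposed to incoming transcription" is
strict (> 10 reads) on *both* flanks, the literal reading of its
definition. Ranking is descending with ties broken by origin id; the group
comparison is the classical unpaired, equal-variance, two-tailed t-test
(scipy's `ttest_ind`), and regressions are ordinary least squares with the
slope's two-sided p from the t distribution with n−2 df
(scipy's `linregress`). P_F|L = P_F/P_L is undefined at P_L = 0 (origin
excluded with a warning); ratios above 1 are flagged as inconsistent but
returned, since they can arise from independently estimated probabilities.
The two-class partition threshold (P_F|L ≥ 0.9) is a documented choice; no
canonical rule exists for separating the near-diagonal class from the rest.

## Synthetic cohorts

The generator produces, from one seed, a toy genome, origin records, two
occupancy and two 3'-end track conditions (wild type and exosome-depleted),
a metrics table and a ground-truth table. Defaults describe the conditions
the analysis is designed for:

* **Origins:** 190 per cohort, on a single chromosome sized at 1600 bp per
  origin; strands random; primary and secondary motifs sampled per column
  from a peaked T-rich frequency matrix (consensus probability 0.85,
  17 columns) and planted in opposite orientations.
* **ACS spacing:** discretised gamma (shape 12, scale 10 → mode 110 bp),
  rejection-truncated to 70–200 bp, matching the observed preference of
  primary-to-secondary distances around ~110 bp.
* **Occupancy:** Poisson counts around a piecewise-linear mean — background
  2 reads/base (scaled per origin by a lognormal intensity, σ = 0.5),
  linear build-up to 4× over the 200 bp before the ACS, sharp linear drop
  over the final 25 bp to a crossing level of 0.1× background, which
  persists through the origin interior; the antisense strand mirrors this
  at the secondary anchor with pause gain 3×. These spans reproduce the
  qualitative roadblock footprint (accumulation over ~200 nt, loss within
  ~25 nt); the *linear* ramp shape is a free modelling choice recorded
  here, as only accumulation per se is constrained.
* **3'-ends:** Poisson, background 0.05/base genome-wide; elevated to
  0.45/base (times the origin intensity) over the sense drop span and over
  an 11-nt antisense window centred 50 nt past the secondary anchor in the
  antisense travel direction. The background and peak rates correspond to
  per-position termination frequencies of roughly 5% and 35% of origins,
  the regime in which presence/absence scoring is informative. The
  depleted condition multiplies the roadblock-proximal rates by 3,
  emulating stabilisation of exosome-degraded termination products.
* **Metrics:** P_L = σ(2 − 0.04·B) on the realised region-B sum; a 50/50
  two-class mixture with P_F|L ≈ N(0.97, 0.02) (high class, transcription-
  independent) versus N(0.55 − 0.004·(B−B̄), 0.08) (low class), clipped to
  [0.02, 1]; P_F = P_L·P_F|L; firing time 20 ± 2 min for the high class and
  25 + 0.12·(B−B̄) ± 2 min for the low class. The slopes are set so the
  low class shows a strong transcription dependence and the high class
  essentially none.

Sub-streams for genome, placement, occupancy, end sites and metrics are
spawned from one `SeedSequence`, so adding an output never perturbs the
others, and a fixed seed yields byte-identical files.

What the generator does *not* emulate: real chromatin context, overlapping
or clustered origins, annotated-gene structure, replication-fork dynamics,
non-Poisson overdispersion of crosslinking counts, and mappability
artefacts. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated generative assumptions, not
performance on real sequencing data.

## Problem sizes and numerical choices

Recovery checks run at the cohort size the metric tables are built for
(190 origins; 150 for the footprint check, which needs only ≥50); the
type-I-error estimate uses 50 origins over ~2000 tested positions across
replicates (200 in the test suite). Oracle-equivalence checks compare
against literal brute-force implementations (per-position Python medians,
pmf summation for binomial tails, exhaustive window enumeration for the
scan, normal-equations OLS, the textbook pooled-t formula) at 1e-10
relative tolerance. Floating scores at the normalisation endpoints are
clamped to [0, 1] to absorb last-ulp error; no other tolerance enters the
implementation itself.

## Known limitations

* The binomial null assumes independence of termination events across
  origins at a position; clustered artefacts in real data would inflate
  significance.
* Bonferroni is conservative for thousands of correlated neighbouring
  positions; it matches the multiplicative-correction definition used
  here, but an FDR variant would be more powerful.
* Region definitions assume non-overlapping origins; each origin is
  windowed independently.
* The PWM scan reports a best hit for every origin, including origins
  where no biologically meaningful secondary ACS exists; downstream
  restriction (70–200 bp) is the only guard.
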