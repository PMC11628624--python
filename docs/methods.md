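# Methods notes

This note records the modelling conventions, defaults and numerical
choices behind `notchsig`, and what the synthetic generators do and do
not emulate.

## Signature curation

A curated signature is built as
`((union of washout gene sets) ∩ gain-of-function set) ∪ canonical targets`,
with symbols uppercased, whitespace-stripped, deduplicated and sorted.
Thresholded selection interprets a "fold-change threshold of 1" as
|log2FC| ≥ 1 — a linear fold-change cut of 1 would be vacuous, and the
upstream differential-expression tools report log2 fold changes. The
default direction is *up* (washout and gain-of-function experiments define
the pathway-ON state); *down*/*both* are available. The adjusted-p filter
is optional per call: washout selections are fold-change-only, the
gain-of-function selection adds padj ≤ 0.05. No gene-alias resolution is
attempted; symbols absent from a cohort matrix are reported, never
imputed.

## Scoring and stratification

- HIGH requires expression strictly greater than the per-gene cohort
  median; ties at the median are LOW. This guarantees ≤ 50% HIGH calls
  per gene and makes scores invariant under monotone per-gene transforms
  (only ranks matter).
- Medians are computed within the scored cohort — each cohort is its own
  reference distribution.
- Tertiles: samples sorted ascending by (score, sample ID) and cut into k
  contiguous groups with sizes differing by at most one; when n mod k ≠ 0
  the larger groups sit at the low end. The ID tie-break makes labels
  independent of input order. Exactly equal groups are impossible when
  n mod 3 ≠ 0; the remainder rule is a package convention.
- Single-gene dichotomization: bottom/top ⌊q·n⌋ samples (q = 1/3 by
  default) labeled LOW/HIGH, remainder EXCLUDED and dropped from
  downstream contrasts. Floor, not interpolation.
- Genes with any missing expression value are dropped from scoring and
  surfaced through the coverage fraction.
- NOTCH alteration calls: *mutated* = any missense record on NOTCH1–4,
  *amplified* = any high-level amplification (cna code 2); the flags are
  independent, other copy-number codes (−2…1) never count.

## Survival

- Follow-up cap (default 120 months): times strictly beyond the cap are
  censored at the cap; an event exactly at the cap remains an event (the
  boundary convention is a package choice).
- Kaplan–Meier: standard product-limit with joint handling of tied
  events; censored-only times leave the curve unchanged; censoring at an
  event time counts as at-risk through that time.
- Log-rank: hypergeometric expected counts and covariance per distinct
  event time; scalar (O−E)²/V for two groups, quadratic form with a
  dropped group and pseudo-inverse for k > 2 (the covariance matrix is
  singular by construction). p-values are chi-square upper tails with
  k−1 df, no continuity correction. The two forms agree to < 1e-9 for
  two groups, which the test suite asserts.

## Peak co-localization

- Co-localization is strict: summit distance < 500 bp, same chromosome
  only. Distances are computed by sorted merge per chromosome and are
  identical to the quadratic all-pairs scan.
- narrowPeak summits are start + column-10 offset; an offset of −1, or a
  BED6 input, falls back to the floor midpoint.
- Background: positions drawn uniformly over the concatenated base-pair
  space of the enhancer regions (length-weighted region choice, uniform
  offset, with replacement); the default draw count equals the query
  set's size.
- Fisher enrichment is two-sided by the probability-mass definition,
  computed vectorized over the hypergeometric support with the
  conventional 1 + 1e-7 relative tie tolerance; it matches exact integer
  enumeration for every table with margins ≤ 30 (exhaustively tested)
  and `scipy.stats.fisher_exact` to machine precision.
- The PWM scanner is deliberately minimal: log-odds from count matrices
  with pseudocount 0.8 distributed by the background composition
  (uniform default), hits at ≥ threshold_frac × maximum attainable
  score, N-containing windows skipped, reverse strand scanned against
  the reverse complement with coordinates mapped back. No p-value or
  q-value calibration is provided; the score-fraction threshold is not
  comparable to FIMO p-value cutoffs.
- A co-localized pair "contains both motifs" when at least one hit of
  each motif lies entirely inside the union footprint (merged intervals)
  of the two partner peaks; the footprint definition is a package
  convention.

## Drug screens

- Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| with sample (n−1) standard deviations.
- 4PL fits run on the log10-dose scale with multi-start least squares
  (Hill starts 0.5–4, five IC50 starts across the dose range extended
  100×); bounds: bottom ∈ [−20, 50], top ∈ [50, 120], hill ∈ (0, 10],
  IC50 within 100× the tested range. Near-constant responses return
  `converged=False` (IC50 and Hill are unidentifiable) instead of
  raising.
- The Hill-slope hit filter is strict on both sides: 0.5 < h < 5.
- HSA synergy: per-cell excess over max(mono A, mono B), summarized as
  the arithmetic mean over combination cells in percentage points. The
  mean is a convention of common synergy software; published scalar
  scores do not define their aggregation, so absolute comparability is
  not claimed.

## Synthetic generators — what they emulate, and what not

- **Cohorts** emulate a cohort with a planted signature-active fraction:
  per-gene baselines ~ Normal(8, 2) (a plausible log2 intensity range),
  Normal noise (sd 0.5 default), active samples shifted +1.5 log2 units
  on signature genes (defaults chosen as a clearly detectable but not
  degenerate effect), exponential survival (Weibull via a shape flag)
  with hazard ratio 2.5 active-vs-inactive, baseline hazard 0.01/month,
  and 30% censoring. Censoring is independent uniform administrative
  censoring; its upper bound is calibrated to the requested censored
  fraction by solving (1/u)∫₀ᵘ S(c)dc = target with Brent's method on
  the closed-form mixture survival.
- **Peak pairs**: peaks occupy slots spaced 10× the threshold apart on a
  synthetic chromosome, so non-partner summits can never co-localize;
  planted partners get truncated-Normal jitter (sd 100 bp) strictly
  inside the threshold. Recovered fractions are therefore exact up to
  rounding of the planted count.
- **Dose matrices**: monotherapy rows follow each drug's 4PL exactly;
  combination cells are max(monoA, monoB) + δ + Normal(0, noise),
  clipped to [0, 100]. Exact δ recovery holds only when clipping does
  not bind.
- None of the generators mimic real cohort marginals, batch structure,
  genome annotation, linkage between expression and survival beyond the
  planted group effect, or plate artifacts. A green recovery test
  establishes that the estimators invert the stated generative model —
  not that they are robust to features of real data the model omits.

## Degenerate inputs and tie-breaking (summary)

- All sample orderings that feed label assignment are tie-broken by
  sample ID; all generators are bit-reproducible from (config, seed).
- Parsers reject malformed input (duplicate IDs, non-numeric cells,
  malformed lines) with the offending coordinate rather than coercing.

## Known limitations

- No Cox regression, competing risks or survival confidence bands.
- No batch correction or cross-platform harmonization of expression.
- The PWM scanner is not a FIMO replacement for p-value-calibrated
  scanning.
- Published cohort percentages, ChIP overlap statistics and synergy
  scalars require the corresponding primary datasets and full upstream
  processing pipelines; this package reproduces the procedures, not
  those numbers.
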