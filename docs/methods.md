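# Methods

This note documents the models and procedures `nemaquant` implements, the
conventions it fixes where the underlying protocols leave choices open,
what the synthetic generators do and do not emulate, and the package's
known limitations.

## Mann–Whitney U test (`nemaquant.stats`)

The U statistic counts rank wins for the first sample using midranks, so
`u_statistic` for x is Σᵢⱼ [xᵢ > yⱼ] + ½·[xᵢ = yⱼ] and swapping the samples
maps U → n₁n₂ − U.

- **Exact path** (pooled n ≤ 20, at most 10⁶ arrangements): the p-value is
  the tail mass of the full permutation null over every C(n₁+n₂, n₁)
  assignment of the pooled values into the two groups.  Tie-free pooled
  samples use the classical counting recurrence for the U distribution
  (identical to the enumeration but cacheable per (n₁, n₂)); tied samples
  enumerate index subsets explicitly over the midranks.
- **Normal approximation** (larger samples): mean n₁n₂/2, variance
  n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] over tie groups of size t, with a 0.5
  continuity correction.
- Two-sided p is min(1, 2·smaller one-sided tail).  `alternative="greater"`
  tests that the *second* sample is stochastically greater (small U of the
  first) — the orientation used by the detection window, which passes the
  control group first.
- The n ≤ 20 cutoff keeps the assays' native group sizes (7–9 worms per age
  group, 8 wells per plate group) on the exact path, while image batches of
  20 + 20 and larger use the approximation, which at that size is within
  0.02 of exact (property-tested).

Both exact sub-paths are property-tested against a literal
pair-counting/enumeration oracle; the approximation is cross-checked
against `scipy.stats.mannwhitneyu`.

No multiple-testing correction is applied to pairwise morphometry
comparisons by default (letters reflect raw p < α); a Bonferroni flag is
available.

## Compact letter display

Insert-and-absorb: start with one letter column containing all groups; for
each significant pair still sharing a column, duplicate the column, strike
one member from each copy, then drop columns that are subsets of another.
Columns are ordered by their smallest group index before letters are
assigned, so the first group always starts at "a".  The output satisfies,
and is checked per run against, the defining invariant: two groups share a
letter iff their pairwise p ≥ α.

## Box summaries

Quartiles by linear interpolation of order statistics (the common plotting
default; fixed here for reproducibility).  Whiskers extend to the most
extreme observations within 1.5×IQR of the quartiles; points beyond are
listed as outliers.

## Fluorescence pixel scoring (`nemaquant.fluorescence`)

Unit of analysis: one 2-D grayscale section per worm (the most in-focus
optical section; Z-stack handling is out of scope).  Pipeline per worm:
crop (half-open 0-based box) → invert (p → 255−p) → brightness → contrast
→ intensity → threshold count.

The three adjustments, applied in that order with round-half-away-from-zero
and clamping to [0, 255] *after each stage*:

- brightness B %:  p′ = p + 255·B/100
- contrast C %:    p″ = 127.5 + (p′ − 127.5)·(1 + C/100)
- intensity I %:   p‴ = p″·(1 + I/100)

Interactive image editors do not publish their transfer functions, so these
formulas are this package's fixed, documented semantics (additive
brightness scaled to full range, linear contrast about mid-gray,
multiplicative intensity); with them the whole pipeline is bit-exactly
reproducible, which is the property the scoring statistic needs.  Defaults
are B = −17, C = +71, I = −27.

The score counts pixels whose absolute deviation from the reference
background gray strictly exceeds the integer shade variance ("exceeded"
reads as strict >; deviation exactly v is background).  The reference gray
defaults to 0xD1 = 209 but, because the processed background depends on the
adjustment semantics, `estimate_background` (modal gray, ties toward
lighter) and batch calibration are provided and are what the estimator uses
by default.

**Variance calibration**: the smallest v ∈ [0, 255] such that a chosen
quantile (default: median) of control bright-pixel fractions is ≤ a target
fraction (default 0.01).  The returned v is non-decreasing as the target
tightens.  This is the package's operationalisation of an "empirically
derived" threshold; the value used in the original assay was never printed,
so no attempt is made to reconstruct it.

Fold change is the ratio of arithmetic means (treated/control), matching an
"on average" reading; a ratio of medians is available
(`fold_method="median"`).  Color input is collapsed by luminance averaging
with a warning; 16-bit images are rescaled to 8-bit on load with a warning.

## Luminescence decay (`nemaquant.luminescence`)

Model: Intensity(t) = a + b·2^(c·t); a is the persistent baseline
(instrument + well background), b the decaying amplitude, c the rate per
second (c < 0 for decay), half-life −1/c seconds.  Time is seconds from the
first read — the 176 s sampling interval is the only clock the protocol
states — and half-lives are reported in seconds (hours in the CLI output).

Fitting: damped least squares (Levenberg–Marquardt via
`scipy.optimize.least_squares`, ftol 10⁻¹⁰, xtol 10⁻¹²) from the fixed
start (1000, 1000, −10⁻⁴), with restarts at ±1 decade on c if the first
attempt fails — single-start fits occasionally stall on flat series.
Degenerate wells are flagged rather than raised: constant series (b = 0
true, c unidentifiable) and vanishing fitted amplitude come back
`converged=False`; fitted c > 0 is flagged `non_decaying`.  Flagged wells
are excluded from the half-life comparison with a warning and reflected in
the reported group sizes; all wells, control included, are fitted with the
same model.

**Detection window.** "Above background" has no canonical rule, so two
endpoints bracket it: at each read, a one-sided exact Mann–Whitney
(treated > control) across wells; the *conservative* end closes the
contiguous run of p < α from t = 0, the *liberal* end is the last
significant read anywhere.  Under the null the per-read significance rate
is the largest attainable exact level below α (≈ 0.0415 for 8 + 8 wells at
α = 0.05, verified by the null-calibration test).  Limitation: on long
grids the liberal end is dominated by that false-positive rate (with 1000
reads it almost always lands near the end of the run), so it should be read
as "no later than", while the conservative end is the defensible detection
claim.

## Morphometry (`nemaquant.morphometry`)

Gonad proportion = 100·gonad/body (scale-invariant; requires
0 < gonad ≤ body).  `analyze_groups` computes, for proportion, body length
or gonad length: per-group box summaries, all pairwise exact Mann–Whitney
p-values, and letters at α (default 0.05).  Groups with fewer than two
records are excluded with a warning.  Lengths arrive as a CSV measured
externally (e.g. in FIJI); in-image measurement is out of scope.

## Synthetic data (`nemaquant.simulate`)

All generators are pure functions of (parameters, seed).  Noise streams are
derived per entity from (seed, stream_key, index), so enlarging a batch
never changes existing entities, and distinct groups use distinct stream
keys.

**Worm images.** A stylised sinusoidal tube, not an anatomical model — the
scoring statistic is geometry-agnostic, so geometry only needs to provide
body/gut/background regions with known masks.  Defaults: 120×200 canvas,
background gray 10, body 40, gut stripe +60 (autofluorescence concentrated
in the intestine), reporter increment +80 body-wide in treated worms
(signal well above noise, as in a strongly expressing batch), Gaussian
noise sd 3 rounded and clamped.  Deliberately not emulated: confocal
optics, Z-stacks, photon (Poisson) noise — the scoring threshold is a hard
cut, so distribution shape is secondary — bleed-through, and worm motion.
Passing tests therefore show the *scoring rules* behave as specified, not
that the generator reproduces real micrograph statistics.

**Plates.** Wells on the 176 s grid over 48.84 h (exactly 1000 reads);
intensities are the model curve plus Gaussian noise (default sd 40 ≈ 2 % of
a+b), clamped at 0.  The default synthetic control group decays faster with
a smaller amplitude (a = 1000, b = 200, c = −3·10⁻⁴) — a stylised
background-luminescence well; real negative-control kinetics were not
reported and are not claimed.

**Morphometry.** Body ~ Normal(µ_b, σ_b) truncated > 0; proportion ~
Normal(µ_p, σ_p) truncated to (0, 100]; gonad = body·proportion/100.
Default groups 0–1 / 2–3 / 5–6 dpe: proportion means 65/55/45 % (sd 5,
n = 8) — the 55 % centre of the middle group is an interpolation, not a
measured value — and body means 1050/1150/1250 µm with sd 300 µm.  The
large body-length sd reflects the considerable between-animal size
variation in emerged males and is chosen so the individual body- and
gonad-length contrasts are sub-threshold at n = 8 in most draws while the
20-point proportion separation is overwhelming, i.e. the generator
reproduces the qualitative statistical structure of the real measurements
(proportion significant, components individually not).

## Problem sizes and numerical conventions

- Exact Mann–Whitney enumeration is capped at pooled n = 20 / 10⁶
  arrangements; beyond that the corrected normal approximation is used.
- The null-calibration check of the detection window runs 200 replicates of
  8 + 8 wells on a 4.884 h grid (100 reads per replicate, 20 000 tests
  pooled); the per-read rate is grid-length-independent, so the shorter
  grid measures the same quantity as the full 48.84 h one.
- Power-style checks (letter separation, fluorescence significance) use
  200 and 10 replicates respectively at the generators' default sizes.
- Quartile convention, rounding rule (half away from zero), strict
  threshold inequality, and background tie-breaking (toward lighter) are
  fixed as stated above; changing any of them changes scores by design.

## Known limitations

- The brightness/contrast/intensity semantics are this package's fixed
  definition of an under-specified manual step; absolute pixel counts are
  comparable within this pipeline, not with scores produced by other
  software.
- The calibrated variance threshold depends on the control batch; scores
  from different calibrations should not be pooled.
- The liberal detection-window endpoint inherits the per-read false-positive
  rate (see above).
- Baseline a and amplitude b are nearly collinear when |c|·span ≪ 1; such
  wells fit poorly and surface as non-converged or wildly uncertain rather
  than being silently accepted.
- The synthetic worm is 2-D and rigid; segmentation, detection and any
  spatial statistics beyond the gut/body masks are out of scope (bounding
  boxes are inputs).
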