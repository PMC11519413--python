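# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data can and cannot establish.

## Synthetic cohort model

The generator emulates a repeat-biopsy study on discarded deceased-donor
kidneys.  The design defaults are fixed by the study structure the package
analyses: 12 donors of which four contribute both kidneys (16 kidneys),
three retrieval techniques (punch, core, wedge) repeated three times per
kidney (144 biopsies), 19 biopsies excluded after pathologist review, two
stains (H&E, PAS) per retained biopsy (250 slides), and 27 retained
biopsies (54 slides) carrying medulla, which makes their cortex area — and
hence every intensive variable — unavailable.  Exclusions and medulla flags
are drawn as exact counts, uniformly without replacement, so these totals
are reproduced deterministically; the medulla flag is assigned at biopsy
level, shared by both stained sections.  Which four donors contribute two
kidneys is not identifiable from the design totals; the default assigns the
first four and the map is configurable.

Every continuous variable follows a three-level random-effects model:
latent value = baseline + donor effect + kidney effect + slide effect, with
independent Gaussian effects whose variances are per-variable configuration
(`variance_components`).  Strictly positive quantities (cortex area, vessel
dimensions, densities) carry the effects on the log scale (lognormal
values); bounded fractions (IF, TA, GS propensity) on the logit scale;
biopsy depth and width are additive Gaussian, which makes the configured
donor-level variance fraction exactly the population η² and is the variable
used by the parameter-recovery tests.  Counts are rounded products of a
latent per-area density and the latent cortex area, so they inherit the
hierarchy without a separate noise channel; sclerotic counts are
Binomial(total, p) with the propensity p carrying donor/kidney effects on
the logit scale (a fully degenerate propensity switches to the rounded
expectation so that a no-noise configuration produces identical slides
within a kidney — used by the degenerate-config test).

Processing effects enter as configured shifts: technique-specific means for
cortex area (wedge 60 > core 25 > punch 10 area units), depth and width,
and an additive +3 percentage-point shift of IF% and TA% on PAS sections
(PAS highlights basement membranes and fibrotic matrix, so PAS-measured
IF/TA runs higher than H&E).  `null_config()` equalizes all technique means
and removes the stain shift, making every processing null hypothesis true;
it is the basis of the Type-1 calibration test.

The glomerular density is lognormal with log-scale variance components
(0.0625, 0.0225, 0.04) and its location chosen in closed form so that the
*marginal* 0.10 quantile equals exactly 1.5 glomeruli per area unit, the
anchor of the adequacy area recommendation.  With the default technique
areas this yields a median of ≈57 glomeruli per slide and a small minority
of slides above 156 — the qualitative regime the adequacy analysis is
about.

Units are abstract.  The source domain reports glomerular densities "per
µm²" alongside a 104 µm² area recommendation, which is physically
impossible for ~200 µm structures (mm² is the plausible unit); the package
therefore never hard-codes a unit and reports "area units" throughout.

### What the generator does not emulate

No spatial tissue structure, no within-kidney regional heterogeneity
(biopsies of one kidney are exchangeable), no scanner or stain-colour
variation, no pathologist disagreement, and no correlation between
variables beyond what the shared hierarchy and shared cortex area induce.
Passing tests therefore demonstrate that the *estimators* behave correctly
under the assumed hierarchical model — not that real biopsies satisfy that
model.

## Derived variables and Remuzzi scoring

Formulas: healthy = total − sclerotic; GS% = 100·sclerotic/total (missing
when total = 0 — an empty slide carries no evidence, and 0% would
masquerade as a healthy reading); IF%/TA% = 100·area/cortex area; intensive
variables = count/cortex area, all missing when medulla is present; ratio =
wall thickness / lumen diameter, missing with a warning when the lumen is
zero (collapsed or fully occluded vessel).

Sub-score intervals are right-closed as printed in the scoring table:
GS [0,2]→0, (2,20]→1, (20,50]→2, (50,100]→3; IF and TA share [0,6]→0,
(6,20]→1, (20,50]→2, (50,100]→3; artery [0,0.5]→0, (0.5,0.8]→1,
(0.8,1.2]→2, (1.2,∞)→3.  A GS of exactly 50 therefore scores 2.  The
published decision sentence leaves total scores 4 and 7 unassigned
("lower than 4" / "5 or 6" / "larger than 7"); this package follows the
standard convention — 0–3 single, 4–6 dual, ≥7 discard — and flags the gap
here rather than silently choosing.

## Sensitivity (discriminating power)

"Fraction of variance explained by differences between donors" is
implemented as the one-way sum-of-squares ratio η² = SS_between/SS_total
with donors as groups, not as REML variance components: groups are
unbalanced, no mixed model is implied by the quantity's definition, and η²
is its direct reading.  A variance-components estimator (which shrinks the
small-sample upward bias of η², roughly (G−1)/(N−1) under pure noise) is a
possible refinement and is deliberately left as future work.  Missing
values are dropped per variable (available-case).  Vessel-related variables
(wall, lumen, diameter, ratio, vessel counts and their densities, and the
artery sub-score) are computed on PAS slides only, reflecting clinical
practice.  The unit of analysis is the slide by default; `unit="biopsy"`
averages the two stained sections first.

## Dependence testing

To stop inter-kidney differences from masking processing effects, each
continuous variable is first rank-normalized within its kidney: values are
ranked (ties get midranks), then divided by the kidney's observation count,
giving values in (0,1] whose distribution is identical across kidneys under
the null.

Continuous-vs-categorical pairs use the k-sample Anderson–Darling test in
its tie-adjusted (midrank) form A²akN, standardized by its exact null mean
(k−1) and finite-N standard deviation — the appropriate variant because
rank normalization creates heavy ties.  The statistic is implemented
directly (and vectorized over label permutations); the test suite verifies
it against an independent reference implementation to 1e-10.  Three p-value
modes exist: `permutation` (default, seeded Monte-Carlo relabelling,
p = (1+#{perm ≥ obs})/(1+n_perm), n_perm = 9999), `asymptotic`
(interpolated critical values; fast, but clipped to [0.001, 0.25]), and
`exact` (exhaustive enumeration of relabellings, for small samples; added
because a sampled permutation p can only approximate the enumerated value
that tiny worked examples pin down).  Categorical pairs use Pearson's χ²
without continuity correction (a flag enables Yates).

The default battery pairs the 3 processing variables (technique, stain,
medulla presence) with 26 continuous/ordinal morphometric and derived
variables, 78 tests in total; the list ships as an editable YAML config and
the count is derived from it.  Categorical derived variables (the
transplant decision, missingness indicators) can be added to the config and
are then tested with χ².  Pairs of medulla presence with intensive
variables are structurally untestable — the variable is missing exactly
when medulla is present — and are reported with an `untestable` flag and a
missing p-value rather than dropped.

Rejections are controlled with Benjamini–Hochberg at q = 0.015.  Note the
granularity floors: with m = 78 the BH threshold for a single rejection is
q/m ≈ 1.9e-4, below both the asymptotic clip (1e-3) and the default
permutation resolution (1e-4 at 9999 draws), so under a true global null
the battery rejects essentially nothing — the Type-1 calibration check is
one-sided (observed rejection fraction ≤ q + 2 Monte-Carlo SEs) for exactly
this reason.  Strong effects are unaffected: a stain shift of two slide
standard deviations reaches the permutation floor p ≤ 1e-3 and survives BH.

## Glomerular adequacy

The observed GS fraction on a slide with n glomeruli is modelled as
Binomial(n, p)/n.  At the Remuzzi boundary p_high = 0.5, declare "below the
boundary" when the observed fraction falls under a cutoff t.  The criterion
asks for the smallest n such that (i) P(declare low | p = p_high) ≤ α and
(ii) P(declare high | p = p_low) ≤ β, with an indifference region
(p_low, p_high) where no control is promised.  Defaults α = 0.15, β = 0.2,
p_low = 0.425 — the edge that a 156-glomerulus sample controls, which
`max_controlled_p_low(156)` recovers (42.5% after one-decimal rounding, by
bisection of the closed-form condition, which is strictly decreasing in p
on [0, p_high]).

Two modes:

- `closed_form` (default): the normal-approximation sample size
  n\* = ⌈((z_α √(p_h q_h) + z_β √(p_l q_l))/(p_h−p_l))²⌉ with
  t = p_h − z_α √(p_h q_h / n).  At the defaults n\* = 156.
- `exact_binomial`: incremental search for the smallest n admitting an
  integer cutoff c with Bin(n, p_high) ≤ c having probability ≤ α and
  Bin(n, p_low) > c probability ≤ β; the feasible c with maximal power is
  reported.  At the defaults this also gives n = 156 (c = 71), with
  achieved errors 0.149 and 0.200.

Agreement window: the exact search can exceed the closed form because the
integer cutoff cannot sit at the optimal fraction; over a grid of
(α, β, margin) configurations the gap reaches ~3% of n at large n and ~10%
at n < 100, documented and asserted as |Δ| ≤ max(5, 0.12·n).  Whether a
continuity correction would close the gap is a presentation choice; the
closed form is the default because it is the transparent, reproducible
formula, and the exact mode exists to verify its error budgets by direct
tail computation.

The area recommendation divides n\* by a low quantile (default 0.10,
inverse-ECDF/lower interpolation) of the observed glomerular density per
unit cortex area, computed on cortex-only slides: area = n\*/density, so a
biopsy of that cortex area has ≈90% probability of containing enough
glomeruli.  At the calibration density 1.5 this is 156/1.5 = 104 area
units.  Per-slide adequacy is simply glomeruli_total ≥ n\*.

## Pipeline and reproducibility

`run_all` executes simulate → derive → sensitivity → dependence → adequacy,
materializing every intermediate as CSV so each stage is independently
inspectable and resumable, and writes a manifest with the seed, a hash of
the scientific configuration (output paths excluded), and per-stage row
counts, exclusion/medulla tallies and file SHA-256 digests; re-running with
the same seed reproduces every digest bit-for-bit.  A stage failure aborts
with the stage named, retaining completed outputs.

## Numerical choices

- Random numbers: numpy `default_rng`; effects are drawn per latent
  variable in a fixed order, so output is byte-identical across runs and
  platforms for a given seed.
- Permutation p-values use a relative tolerance of 1e-9 when comparing
  permuted statistics to the observed one, so exact ties (e.g. mirrored
  relabellings) count as "at least as extreme".
- The bisection for the controlled-region edge uses Brent's method with
  xtol = 1e-12 on [0, p_high].
- η² with zero total sum of squares is reported missing with a warning
  rather than 0 or 100.
- All-identical samples short-circuit the AD test to (statistic 0, p 1).

## Problem sizes used by the test suite

Parameter-recovery tests use 100 donors × 20 slides; the Type-1 calibration
runs 200 null cohorts of the default 250-slide design in asymptotic mode;
permutation-vs-enumeration comparisons use n = 8 with all C(8,4) = 70
relabellings.  These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands (±5 percentage points for recovery; q + 2 SE for
calibration).

## Known limitations

- η² is upward-biased for small donor counts; the decomposition quantifies
  explained variance in the observed sample, not a population variance
  component.
- The asymptotic AD p-value is clipped to [0.001, 0.25]; use permutation
  mode when tail accuracy matters.
- The adequacy criterion treats glomeruli within a slide as an i.i.d.
  sample of the kidney's cortex; spatially clustered sclerosis would make
  156 an underestimate.  Extending the criterion to non-uniform tissue and
  to IF/TA area fractions is future work.
- Medulla-vs-intensive-variable dependence is structurally untestable under
  the missingness rule; only its effect on missingness itself (a
  categorical indicator, addable to the battery config) can be tested.
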