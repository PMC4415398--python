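# Methods

`lapref` implements a desk-scale version of a three-part analysis from
affective neuroscience / neuroeconomics: (1) a keypress-based behavioral
measure of loss aversion derived from relative preference theory, (2) a
block-design fMRI measure of neural differential sensitivity (NDS) to
negative versus positive face stimuli in the ventral striatum / nucleus
accumbens (VS/NAc), and (3) the three-way group inference relating loss
aversion, NDS and age.  Because no subject-level data are publicly
available for this paradigm, the package ships a synthetic-cohort
generator whose defaults encode the study conditions, so every stage is
exercised end to end with known ground truth.

## Task design

Two scanning runs present 20-s blocks of seven conditions: five facial
expressions (angry, fearful, happy, sad, neutral), phase-scrambled
faces, and fixation.  Block order within a run is counterbalanced so
that no condition follows or precedes another more than once — i.e. the
24 ordered transitions of a 25-block run are pairwise distinct out of
the 7 x 6 = 42 possible ordered pairs — and per-condition block counts
differ by at most one.  The second run opens with an extra block
repeating the first run's final condition, preserving the pair
constraint across the session boundary.

No construction algorithm is prescribed for such sequences, so
`generate_counterbalanced_sequence` uses randomized backtracking over
conditions, pruning on transition reuse and count ceilings, with a
10,000-node expansion budget; exhaustion raises a distinct
design-infeasible error rather than returning a constraint-violating
sequence.  Face blocks contain 8 identities x 5 repetitions = 40
presentations at 200 ms on / 300 ms ISI (a 0.5-s inter-onset interval,
filling the 20-s block); within-block order is pseudorandom with no
identity shown twice in a row.  Timelines are exchanged as BIDS-style
events TSVs (onset, duration, trial_type, stim_id).

## Keypress valuation (K, H)

In the offline task each picture defaults to 6 s of viewing plus a 2-s
decision window; keys 1/2 lengthen and keys 3/4 shorten viewing.  The
exchange rate between keypresses and seconds is not published for this
task, so the package models viewtime as
`clamp(6 + 0.1 * (n_approach - n_avoid), 0, 14)` seconds; the increment
and bounds are configurable and viewtime is a derived diagnostic — the
dependent measure throughout is the keypress count itself.

Per category, the value-graph coordinates are:

* **K** — the mean over the category's pictures of net keypresses
  (approach minus avoid) per presentation; positive K defines the
  approach limb, negative K the avoidance limb.  Mean viewtime
  deviation from the default can substitute via `measure="viewtime"`.
* **H** — the Shannon entropy (bits) of how total keypress effort
  distributes across the category's pictures,
  `H = -sum p_j log2 p_j`, `p_j` the picture's share of the category's
  total presses.  Eight pictures bound H at 3 bits; an all-zero
  category is degenerate and assigned H = 0 with a warning.

Net (rather than gross) counts are the canonical K here; gross
per-class counts remain available from the trial table.  Neutral-face
and baseline categories never enter curve fitting; a dead band
(default |K| <= 0.05) additionally labels near-indifferent categories
as limb-neutral.

## Value curves and the loss-aversion ratio

Each limb is fitted through the origin in (H, |K|) space with one of
three monotone forms: power `a*H^b` (default), linear `a*H`, or
quadratic `a*H + b*H^2`.  The power form is fitted by log-log
regression, which is exact on noiseless power-law data.  Two numerical
guards matter in practice:

* a limb whose H values are (nearly) identical cannot identify an
  exponent; if the relative H spread `(Hmax - Hmin)/Hmax` is below
  0.05, the power fit raises and the pipeline falls back to the linear
  form (recorded in the fit's `form` field);
* the face set has exactly one approach category (happy), so the
  approach limb is routinely a single point; the through-origin linear
  form is defined down to one point (exact interpolation), while power
  and quadratic require at least two.

Loss aversion uses the local slope-ratio definition: for each limb the
mean slope over the window covering the fraction of the H-range
(default 10%) nearest the origin — the endpoint of smallest fitted |K|,
since the limbs meet near K = 0 — computed as
`(f(h0 + w) - f(h0)) / w` with `w = fraction * (H-range)`.  Then
`lambda = |s- / s+|`.  The mean-slope (integral-over-width) reading
makes lambda a dimensionless ratio, invariant to rescaling all counts;
"10% of the curve" is taken as 10% of the H-range, not of arc length.
A zero approach slope yields an infinite-lambda sentinel that is warned
about and excluded from group statistics.

Cohort-level lambda outliers are flagged once, before any
lambda-involving statistic: value i is an outlier iff
`|x_i - mean| > 2 * sd` with the sample (n-1) standard deviation over
all finite values; non-finite values are always flagged.  Note an
arithmetic consequence of this single-pass rule: since the squared
deviations sum to `(n-1) * sd^2`, at most `(n-1)/4` values can exceed
2 SD, e.g. at most four of seventeen.

## Block-design GLM and NDS

The design matrix holds one boxcar regressor per condition present in
the timeline (fixation is the implicit baseline), convolved with the
canonical double-gamma HRF (gamma-density difference; response peak
6 s, undershoot 16 s, peak:undershoot ratio 6, peak-normalised),
sampled at volume midpoints at TR = 2.5 s on a 0.1-s convolution grid,
plus an intercept and a linear drift column.  Per-voxel ordinary least
squares gives betas and residual variance with
`df = n_volumes - n_columns`; rank-deficient designs are rejected by
name.

The NDS contrast is `mean(beta_angry, beta_fearful, beta_sad) -
beta_happy`.  Neutral faces get a regressor but enter neither side of
the contrast; scrambled blocks are modeled but uncontrasted.  The
contrast t statistic (OLS standard error) is mapped to a
standard-normal z by two-sided tail matching; a zero-residual
(noiseless) voxel with a nonzero contrast maps to +/- infinity, which
thresholding handles naturally.  A subject's NDS is the mean contrast
over ROI voxels with z > 1.96 (per-subject p < 0.05 sampling rule);
left VS/NAc is the default ROI, with right and bilateral options.  If
no ROI voxel survives, the subject's imaging is invalid and the subject
is excluded from NDS statistics downstream — the same bookkeeping a
motion-artifact exclusion follows.  Group-level cluster-corrected
mapping (z = 2.3 whole-brain correction) is out of scope at desk scale;
the per-subject sampling rule is the implemented selection step.
Whether a subject's NDS should be a mean beta difference or a
peak-voxel value is not settled by the source material; the mean over
supra-threshold ROI voxels is the convention here.

## Group inference

Three associations are computed on the cohort table:

* `nds_la` — Pearson correlation of NDS with lambda at alpha = 0.05,
  over subjects who are neither lambda outliers nor NDS outliers and
  have valid imaging;
* `nds_age` — OLS regression of NDS on age, F statistic and two-sided
  p, alpha = 0.05/2 = 0.025 (Bonferroni for the two age tests), over
  valid-imaging subjects (NDS outliers retained by default,
  excludable by config);
* `la_age` — OLS regression of lambda on age at alpha = 0.025,
  excluding lambda outliers.

All p-values are two-sided.  Every association reports `n_used` plus
the excluded subject ids with reasons, and `n_used + n_excluded` always
equals the cohort size.  Correlations are reported as plain Pearson r
with n; degenerate inputs (constant vectors, fewer than three usable
subjects) raise rather than returning undefined statistics.

## Synthetic cohort: what it emulates and what it does not

Defaults encode the study conditions: 17 subjects, ages uniform on
20-55 years.  Ground-truth lambda is log-normal with median 2
(log-sd 0.3) — the scale of published loss-aversion estimates — and is
independent of age by default (`beta_age_la = 0`, applied on the log
scale per year when nonzero).  With probability `outlier_rate`
(default 5/17) a subject's lambda is drawn with inflated log-sd 1.5,
producing the heavy tails that exercise the 2-SD exclusion.  True NDS
is `0.2 + 0.02 * age + eps` contrast units, and the non-age component
eps (sd 0.25) is correlated at `rho_nds_la = 0.64` with the
standardized core lambda, so the NDS~LA association is present while
the NDS~age slope stays unbiased.  With these values an n = 17 cohort
typically shows a clearly significant NDS~age regression, an NDS~LA
correlation near the 0.5-0.65 range, and a null LA~age test —
the qualitative three-way pattern the inference layer is meant to
detect.

Keypress counts per presentation are Poisson with mean
`gain * max(v, 0)` (approach) and `gain * lambda * max(-v, 0)` (avoid),
`gain = 10` presses per unit valence; each of the 40 pictures is shown
4 times (a ~21-minute task at 8 s per trial).  Picture valences are the
category base (+1 happy, -1 negative, 0 neutral) plus per-picture
Uniform(-0.2, 0.2) jitter so within-category effort varies and H is
non-degenerate.  Because the Poisson has no free dispersion, the
subject-level `keypress_noise` parameter interpolates the draw around
its mean (`round(mean + noise * (Poisson(mean) - mean))`, clipped at
zero): 1 is exact Poisson, 0 the deterministic limit used by the
recovery tests, > 1 overdispersed.

Voxel tables are built from the same design-matrix model the analysis
fits: a third of voxels are left VS/NAc, a third right, a third
unlabeled pure-noise voxels; responsive voxels respond to every face
condition with negative-minus-positive amplitude equal to the subject's
true NDS (happy amplitude 1, scrambled 0.5), on a baseline of 100 with
a linear drift of 0.5, plus iid Gaussian noise (sd 0.5).  The generator
deliberately omits motion, physiological noise, autocorrelated noise,
spatial structure and nonlinear drift — so passing tests demonstrate
the correctness of the estimation chain, not robustness to real
scanner artifacts.  Likewise the keypress model omits within-trial
dynamics (alternation timing, fatigue), and the latent-valence model is
a modeling choice, not a published fact.

## Problem sizes and numerical choices

Recovery tests use the cohort-scale defaults: 20 seeded 17-subject
cohorts for the NDS~age slope (median within 10% of the generator
slope at `noise_sd_nds = 0.01`), 5 cohorts in the deterministic
keypress limit for per-subject lambda recovery within 5% (the
`approach_gain = 100` ceiling there keeps integer rounding below 1%),
and 2,000 truth-table cohorts for the type-I calibration of the LA~age
test at alpha 0.025 (the lightweight truth-table path regenerates only
ages and lambdas; the estimation chain it feeds is identical to the
full pipeline's).  Noiseless end-to-end NDS recovery is asserted at
1e-6 relative error.  All generators run from
`numpy.random.default_rng` with explicit integer seeds; per-subject
child seeds are drawn from the cohort seed, so a cohort spec
byte-reproduces its CSVs on rerun.

## Known limitations

* Category-level limbs give the avoidance fit three points and the
  approach fit one, so per-subject curve shape (the power exponent) is
  weakly identified at desk scale; the linear fallback makes lambda a
  ratio of through-origin slopes in that regime.
* The 2-SD outlier rule is single-pass; iterated or leave-one-out
  variants would flag more aggressively in heavy-tailed cohorts.
* The t-to-z mapping assumes iid Gaussian residuals; with temporally
  autocorrelated noise the per-voxel z would be anti-conservative
  (prewhitening is out of scope).
* With lambda log-normal, the OLS LA~age test is slightly conservative
  after outlier trimming; its measured type-I rate at alpha 0.025 sits
  near 0.021-0.027 across calibration runs, within the tested band.
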