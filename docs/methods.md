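# Methods

## Problem and scope

During standard automated perimetry (SAP) the subject must hold central
fixation for several minutes while stimuli are presented across the visual
field.  How steady that fixation is — and whether it differs between
dominant-eye, non-dominant-eye and binocular viewing — is quantified from
wearable eye-tracker recordings.  `fixstab` implements the full analysis
chain for such recordings: calibrated pixel→degree conversion, blink and
setup exclusion, bivariate contour ellipse areas (BCEA) and gaze-deviation
statistics per trace, and cohort-level paired comparisons.  The perimetric
measurement itself (thresholds, fixation-loss monitoring, clinical
examinations) is out of scope; its outputs enter only as covariates.

## The fixation-stability model

Retained gaze samples `(x, y)` in degrees of visual angle are summarised
by their bivariate dispersion: per-axis sample standard deviations σH and
σV (n−1 denominator) and the product–moment correlation ρ.  For a chosen
coverage proportion `p ∈ (0, 1)` the ellipse scale is

    k = −ln(1 − p)        (equivalently p = 1 − e^(−k)),

and the area of the iso-density ellipse at squared Mahalanobis radius 2k is

    BCEA(p) = 2·k·π·σH·σV·√(1 − ρ²) = 2·k·π·√(det Σ)    [deg²].

For bivariate-normal scatter this ellipse contains exactly the proportion
`p` of samples (the χ² tail identity with 2 degrees of freedom), which is
the property the test suite verifies by simulation.  Note that some
published reports drop the factor π and the square root on (1 − ρ²) when
printing the formula, and round k inconsistently with the coverage
relation (e.g. 1.147 where −ln(1 − 0.6827) = 1.1479, or 3.079 where the
relation gives 3.0900); this package derives k from p and treats those
printed constants as typographical variants.  `CoverageSpec.from_k`
accepts an explicit k for replication of such reports.

Default coverage levels are the 1-, 2- and 3-SD masses of a univariate
normal: p = 0.6827, 0.9545, 0.9973.

Two centres are used deliberately.  Dispersion (hence BCEA) is centred on
the **mean gaze position**, per the symbol definitions of the dispersion
statistics.  Gaze-deviation metrics — mean Euclidean distance, the
within-2°/4° frequencies, and the deviation histogram (1° bins by
default) — are measured from the **fixation target** at the origin.

## Calibration and preprocessing

* Pixel→degree conversion is a homogeneous linear scale per axis
  (`deg_per_px_h/v`), target at the origin, +x right, +y up (screen pixel
  y grows downward, hence the sign flip).  Fixational excursions span only
  a few degrees, so tangent-plane corrections are deliberately omitted.
  The scale factors are user-supplied calibration constants.
* Blink removal: maximal runs of invalid samples lasting ≥ 100 ms
  (run length × nominal sample period) are dilated by 2 samples (40 ms at
  50 Hz) per side and removed.  Both knobs are configurable; the values
  are standard practice for pupil-loss artifacts at 50 Hz, not a claim
  about any particular study's (unpublished) criterion.  Shorter dropouts
  are also removed (retained samples are always valid) and counted with
  the blink category.  No interpolation is performed.
* Setup removal: explicit user-supplied time windows.  There is no robust
  automatic signature for "the operator is still adjusting the glasses",
  so no detector is attempted.
* A sample falling in both a setup window and a blink interval is counted
  once, as setup.

## Statistics

Condition contrasts are two-sided paired t-tests on participant-matched
differences; the three condition pairs form a Bonferroni family of m = 3
and adjusted p-values are presented as min(1, m·p) (matching published
tables where adjusted values cap at 1).  Zero-variance differences return
t = 0, p = 1 with a degenerate flag.  Covariate associations use
Pearson's r with the t transform (n−2 df).

The a priori sample size for the within-factors repeated-measures F test
uses noncentrality λ = f²·N·m·ε/(1 − ρ_rm), numerator df (m−1)·ε and
denominator df (N−1)·(m−1)·ε, searching N upward until the noncentral-F
power reaches the target.  With the conventional medium effect f = 0.25,
α = 0.05, power 0.80, m = 3 and ε = 0.5 this gives N = 44 when the
repeated-measures correlation ρ_rm is 0.5 (a common software default);
with no sphericity penalty (ε = 1) it gives N = 28.  Published a priori
computations for this design rarely state ρ_rm, so exact replication of a
printed N is not possible in general; the package treats the convention
above as canonical and exposes every input.

## Synthetic data

`simulate_trace` produces what the preprocessing stage consumes: a
pixel-unit 50 Hz trace with a leading off-target setup segment and blink
gaps.  The gaze process is a discrete-time mean-reverting (AR(1) /
Ornstein–Uhlenbeck) bivariate drift with Poisson-timed instantaneous
jumps (microsaccades; exponential amplitudes, uniform directions) and
white sensor noise.  The AR innovation covariance is solved as
`(1 − a²)·Σ − λ·dt·μ²·I` (a = e^(−dt/τ); λ, μ the microsaccade rate and
mean amplitude), so the stationary covariance of drift + jumps equals the
requested Σ(σH, σV, ρ) **exactly by construction** — ground truth is
analytic.  Defaults: σH = 1.5°, σV = 1.0°, ρ = 0.4 (dispersion of the
order observed in long perimetric tests), τ = 0.5 s, microsaccades
1 Hz × 0.3°, sensor noise 0.05°, blinks 12/min with gamma-distributed
durations clipped to ≥ 120 ms (so every programmed blink exceeds the
100 ms detection threshold), 10 s setup, 300 s measurement.  Blink onsets
are thinned to ≥ 10 samples apart so margin dilation cannot merge two
programmed gaps.

What the generator does **not** emulate: main-sequence microsaccade
velocity profiles (jumps are instantaneous), slippage of the glasses,
gaze attraction toward projected stimuli, vergence, or pupil-size signals.
Passing recovery tests therefore shows the pipeline is unbiased for a
stationary dispersion process with realistic artifact rates — not that
real recordings satisfy those assumptions.

`simulate_cohort` draws per-participant summary metrics log-normally
(these metrics are positive with SDs comparable to their means), with
moments matched in arithmetic space and a Gaussian-copula correlation of
0.5 across conditions within a participant (the correlation is specified
on the latent scale; the arithmetic-scale correlation is slightly
smaller).  Default parameterization is the study-scale condition
means/SDs for BCEA at all three coverage levels and mean gaze deviation,
in both phases; covariates are normal (near ocular position −7.5 ± 6.5 Δ,
fusional amplitude 38.6 ± 15.1 Δ) with zero default correlation to BCEA.

## Numerical choices

* Ellipse geometry via the symmetric eigendecomposition of Σ; semi-axes
  √(2k·λᵢ).  Contour-area agreement with the closed form is tested to
  1e−9 relative (analytic) and 1e−6 (20 000-vertex polygon oracle).
* Degenerate traces (zero variance on an axis) report ρ = 0 with a flag
  and BCEA 0 rather than raising, so cohort pipelines proceed.
* `k_from_p` uses `log1p`/`expm1`; the p↔k round trip holds to 1e−12.
* Monte-Carlo tolerances account for autocorrelation: the effective
  sample size of a τ-timescale AR(1) trace of duration T is T/(2τ), and
  stochastic assertions use 3 standard errors on that basis; binomial
  checks use 3 binomial SEs.
* Problem sizes in the test-suite and acceptance script (100 trace seeds,
  200–500 cohort seeds, 50 000-sample coverage checks) were chosen so the
  Monte-Carlo error is several times smaller than the tolerance being
  asserted while the whole suite runs in well under a minute.

## Known limitations

* The linear pixel→degree map ignores scene-camera lens distortion and
  parallax; acceptable for ±5° excursions, not for peripheral gaze.
* Blink criteria are heuristics; recordings from other hardware may need
  different `min_gap_ms`/margin settings.
* `compare_conditions` implements pairwise Bonferroni-adjusted paired
  tests only; it is not a full repeated-measures ANOVA, and no normality
  diagnostics are run.
* The spreadsheet replication route assumes one row per participant ×
  condition × phase; other layouts must be adapted via the column
  mapping.
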