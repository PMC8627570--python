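# Methods

This note records the models, estimators, parameter choices and known
limitations behind swimtrack, in the order data flows through the package.

## Kinematic model of the synthetic swimmer

The generator produces a purely kinematic anguilliform swimmer: a
head-to-tail traveling wave of lateral displacement

    h(s, t) = A(s) · sin(2π(s/λ − f·t)),   A(s) = A_tail · r^(s−1),

with `s` the arc-length position in [0, 1] (0 = head), `λ` the body
wavelength (BL), `f` the wave frequency (Hz), `A_tail` half the
peak-to-peak tail amplitude and `r ≥ 1` the caudal/rostral amplitude
ratio, so `A(1)/A(0) = r` exactly.  The geometric (exponential) envelope
is a modeling choice: group comparisons of envelope growth are reported in
the literature as a single tail/head ratio, and the one-parameter
exponential family is the natural curve with that ratio as its parameter.

Two properties are enforced exactly rather than approximately:

* **Inextensibility.**  The axial coordinate of each body point is
  `x(s) = ∫₀ˢ √(1 − (∂h/∂σ)²) dσ`, so the curve's arc length is one body
  length at every instant.  Amplitude/wavelength combinations with
  `|∂h/∂s| ≥ 1` (a body that would have to fold back on itself) are
  rejected with a validation error.
* **Constant forward speed.**  The body frame translates at `U` BL s⁻¹
  along the heading; there is no recoil, acceleration or fluid coupling.
  The analysis layer only consumes kinematics, so hydrodynamics are out of
  scope by design.

Sampling adequacy is enforced as `frame_rate ≥ 10·f` (ten samples per wave
period).  Gaussian noise of configurable SD (BL) is added per point to the
observed copy; the noise-free truth is always returned alongside.

Defaults follow the published group kinematics of the study design the
package serves: sham λ = 0.79 BL, A_pp = 0.16 BL, f = 3.6 Hz,
U = 1.83 BL s⁻¹, r = 4.8; rostrally transected 0.53 / 0.11 / 4.1 / 1.12 /
1.7; mid-body 0.61 / 0.13 / 3.7 / 1.12 / 1.9.  The mid-body group's speed
is not reported separately in the source material (only a pooled
transected value), so both transected groups share 1.12 ± 0.35 BL s⁻¹.

## Rendering

Silhouette frames are drawn as a tube around the midline: half-width
`w(s) = w_max · s^0.30 (1−s)^0.20` (blunt head, pointed tail), default
`w_max = 0.035 BL`, rasterized as a union of sub-pixel-spaced disks with a
one-pixel anti-aliased edge.  The terminal taper exponent is deliberately
steep so the silhouette keeps a resolvable, super-pixel width until very
near the tip, as a real body ending in a caudal fin does.  An earlier,
shallower taper left a sub-pixel-wide sliver over the last few percent of
the body that no segmentation (and no real camera) could see, which made
the rendered body's length systematically unmeasurable by about one pixel
— a property of the artificial silhouette, not of any tracker.

Rendered ground truth (the analytic midline mapped to pixel coordinates)
accompanies every stack, so image-processing error can always be measured
against exact truth.

## Virtual cohorts

`generate_cohort` draws individual-level parameters from truncated-normal
distributions at the group mean/SD (truncated at physical bounds), percent
axon regeneration uniformly over 33.3–84.2% for transected individuals
(missing for sham), and per-trial jitter of frequency and speed with CV
8% around the individual mean.  Speed jitter co-varies with frequency
jitter, reflecting that these animals modulate speed mainly through
tail-beat frequency at roughly constant stride; amplitude, wavelength and
envelope ratio are treated as individual traits.  A single RNG stream with
a documented draw order (per individual: λ, A_pp, f, U, r; then
regeneration; then per-trial jitters and trial seeds) makes cohorts
bit-for-bit reproducible.  Default design: 3 sham, 11 rostrally
transected, 3 mid-body individuals, 3 trials each.  The number of analyzed
tail-beat cycles per trial is a configuration choice of this package
(default 1.2 s at 250 fps ≈ 4–5 cycles), not a value inherited from any
particular study.

## Midline tracking

Per frame: Otsu threshold (overridable); foreground is whichever side of
the threshold holds fewer pixels; largest connected component, holes
filled.  The centerline is the longest geodesic path through the skeleton
(tree-diameter heuristic on an 8-connected pixel graph with Euclidean
weights); a path covering < 80% of the skeleton, or one not elongated
relative to the blob's equivalent diameter, raises an "ambiguous
centerline" error (a disk has no midline).  The path is smoothed by a
cubic smoothing spline (fixed residual scale 0.4 px, identical for all
treatments — processing is treatment-blind), resampled to ~1 px spacing,
and then **refined across the band**: each point moves to the
intensity-weighted centroid of the body band along its local normal,
restricted to the contiguous foreground run containing the window center
(so a tight tail hairpin cannot drag points onto the adjacent body limb).
This sub-pixel refinement removes the skeleton-quantization and
spline-attenuation bias that would otherwise damp the measured wave
amplitude by several percent.  A light Savitzky–Golay pass (window 7,
order 2) irons out residual vertex jitter; body tips are then extended
from the refined curve to the sub-pixel intensity boundary along the
end tangent of a local quadratic fit (a straight fit misstates the end
direction by ~L/2R on a curved tail).  Final output is `n_points = 100`
points equally spaced in arc length (resolving the shortest wavelengths
of interest with ≥ 50 samples per wave).

Head/tail identity is assigned per sequence, not per frame: after
enforcing frame-to-frame end consistency, the head is the candidate end
whose lateral excursion about the travel axis has the smaller variance
(anguilliform amplitude grows caudally).  If the variance ratio between
the ends is below 1.2 the orientation is reported as ambiguous rather than
guessed.  Orientation by excursion variance rather than motion direction
is deliberate: transected swimmers' paths can be erratic.

Measured performance on rendered synthetic swimmers across the three
group-mean parameter sets: midline RMS error < 1 px over the interior 94%
of arc length, body-length stability CV < 2%, point-spacing uniformity
< 1%.

## Wave-parameter estimators

All estimators operate on the excursion field `h(s, t)`: the signed
perpendicular distance of each midline point from the heading line, where
the heading is the principal axis of the body-centroid track (sign from
net displacement) and distances are normalized by the measured body
length.  This makes every output invariant to rigid transforms and to the
pixel scale.

* **Input conditioning.**  Raw midline tables may carry independent
  per-point noise.  Two effects are handled separately: lateral jitter is
  suppressed by a zero-phase moving average over time (window ~1/10 of
  the dominant period — temporal smoothing cannot distort the amplitude
  envelope or wavelength the way along-the-body smoothing can), and the
  body length is re-measured on a decimated copy of each midline, because
  the naive arc length of a noisy polyline is biased upward by
  ~(σ/spacing)² (at σ = 0.005 BL and 100 points this is a +20% error that
  would silently deflate every BL-normalized quantity).  An
  along-the-body smoothing spline was evaluated for this role and
  rejected: its end-whip measurably distorted the amplitude envelope.
  Already-smooth input (tracked or noise-free) passes through unchanged;
  the noise scale is estimated from second differences along the body.
* **Speed**: net centroid displacement along the heading over elapsed
  time, per body length.
* **Frequency**: reciprocal mean period between same-sign zero crossings
  of the tail-station excursion (s = 0.95; the extreme endpoint of a
  tracked midline is its least reliable part), crossings located by
  linear interpolation on a lightly low-passed series; spuriously short
  intervals (< half the median) are merged.  Zero crossings were chosen
  over a spectral peak because short clips of a few cycles bias coarse
  spectra, while interpolated crossings are unbiased for near-sinusoids.
* **Amplitude & envelope**: per tail-beat cycle, the excursion at every
  station is projected onto a mean-plus-harmonics model (harmonics 1–3 of
  f) and the peak-to-peak value read off the smooth reconstruction;
  per-cycle envelopes are averaged.  Raw sample extremes were rejected:
  max − min is biased upward by any per-frame measurement jitter, enough
  to violate the package's own noise-recovery targets.  `A_pp` is the
  envelope maximum over the reliable core (s ≤ 0.95), log-linearly
  extrapolated to s = 1 when the envelope is still growing there — exact
  for a geometric envelope, a no-op for a uniform one.  The
  caudal/rostral ratio is `exp(slope)` of a log-linear fit of the
  envelope over s ∈ [0.05, 0.95]: the growth across one full body length.
  Reading the ratio at the stations directly would systematically
  understate it (for r = 4.8, `r^0.9 ≈ 4.1`); the fit uses the whole
  envelope and is exact for the geometric family.
* **Wavelength**: per frame, the excursion profile is normalized by the
  per-station envelope (so the quiet head region is not suppressed),
  extrema are found with a prominence filter of 20% of the local
  peak-to-peak and refined by parabolic interpolation, and λ is twice the
  mean spacing of adjacent extrema, pooled over frames.  When no frame
  shows two interior extrema (λ comparable to or longer than the body), a
  single sinusoid in s is fitted instead and flagged `fit_based`.
* **Wave speed**: the phase of the dominant-frequency component at 14
  stations in s ∈ [0.3, 0.95] over a whole number of periods; V = −2πf /
  (slope of unwrapped phase vs s).  A fit with R² < 0.9, or a
  non-negative slope (no rearward wave), raises an "incoherent wave"
  error — a standing wave is reported as such, not as a number.  V is
  cross-checked against λ·f (flag at 10%).
* **Steady-state filter**: the clip passes if every cycle-averaged
  centroid speed is within 15% (configurable, logged) of the clip mean —
  the quantitative version of requiring that instantaneous velocity not
  deviate from the sequence average.

Measured accuracy over a 3×3×3×3 grid spanning the group means, through
the full render-and-track pipeline (1.2 s clips at 250 fps, 100 px/BL):
λ, f, A_pp, U within 2% noise-free and 5% at 0.005 BL point noise; the
envelope ratio within 5% / 10%; V within 10% of λ·f everywhere.

## Efficiency indices

`St = 2fA/U` with `A` the **half** peak-to-peak amplitude, i.e.
`St = f·A_pp/U`.  Feeding the peak-to-peak value directly would place
steadily swimming control animals near St ≈ 0.63, far outside the
0.25–0.35 optimal band they are classified into — internally
inconsistent — so the half-amplitude convention is the default and the
alternative is exposed behind a flag.  The optimal band is treated as
inclusive at both endpoints.  Stride length is `U/f` (BL per beat).
Percent axon regeneration is `100 × distal/proximal` labeled-axon counts;
a zero proximal count is an explicit error, not a NaN.

## Statistics

The trial table has one row per swimming sequence with individual,
treatment, regeneration percentage, kinematics and indices.  Unit of
analysis: ANOVA and post hoc comparisons run on **individual means**, so
repeated trials of one animal do not masquerade as independent samples;
the mixed model runs on **trials**, which is exactly the correlation
structure its random intercept exists to absorb.  Both tables are
emitted.

* Parametric-assumption diagnostics (Shapiro–Wilk per group, Levene) are
  advisory and never switch the test automatically; groups under n = 3
  are flagged "underpowered".
* One-way ANOVA (scipy); the F statistic is verified in the test suite
  against a hand-coded sums-of-squares oracle to 6 significant digits.
* Holm–Šidák step-down: the i-th smallest of m p-values becomes
  `1 − (1 − p)^(m − i + 1)` with running-maximum monotonicity, capped at
  1; implemented directly (closed form) and cross-checked against
  statsmodels' implementation.  Calibration: under the global null, ANOVA
  rejects at 5% ± 1.5% and the family-wise error of the adjusted pairwise
  comparisons stays at/below 5% (2000 replicates each).
* Regressions of responses on regeneration percentage: OLS on individual
  means, transected animals only (sham have no regeneration value).
* Mixed model: `speed ~ frequency * regeneration + (1 | individual)`,
  REML, Wald p-values from the single fit.  With one trial per individual
  everywhere the random intercept is unidentifiable and the model
  degrades to OLS with an explicit warning record.  On the study-shaped
  design (11 individuals × 6 trials, true frequency slope 0.30,
  individual-intercept SD 0.1, residual SD 0.1, frequency ~ N(3.9, 0.6²),
  regeneration ~ U(33.3, 84.2)), the slope estimate is unbiased to < 1%
  and the joint event "CI covers the true slope and both null terms
  non-significant" occurs in ≥ 90% of replicates.
* α = 0.05 throughout.

## Orchestration and reproducibility

`run_pipeline` executes the configured stages and writes per-stage
artifacts (cohort, kinematics, performance, stats JSON, text summary)
plus a provenance log (package version, seed, stage list, row counts) and
an echo of the full merged configuration — every tolerance any stage used
is in that file.  Outputs carry no timestamps; identical configuration
and seed give byte-identical artifacts.  Default problem sizes (1.2 s
trials at 250 fps, 100-point midlines, rendering off in the cohort run)
keep a full synthetic study in the seconds-to-minutes range; rendering
and tracking are enabled per config when the image pipeline itself is
under study.

## What the synthetic benchmark does and does not show

The generator produces steady, single-frequency, noise-stationary
swimmers with an exactly exponential envelope and a rigid width profile.
Passing the recovery suite therefore demonstrates correctness of the
measurement chain under the model's assumptions — it does not certify
performance on real video with background clutter, partial occlusion,
depth changes, multi-frequency or accelerating swimming, or body-shape
variation.  The steady-state filter and the QC flags
(`wavelength_fit_based`, `wave_speed_consistent`, `steady`) are the
first line of defense on real data; tracking failures surface as explicit
errors rather than silent numbers.  No hydrodynamic quantities (thrust,
pressure, vorticity, Froude efficiency) are computed; St and stride
length are kinematic surrogates for efficiency.
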