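# Methods

This note documents the models, numerical choices and limitations behind
`opticard`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic recordings

The generators stand in for raw optical-mapping recordings and micrographs
of ChR2-expressing cardiomyocyte monolayers; every downstream estimate has
an exact ground-truth twin.

**Transient templates.** A transient is a half-cosine upstroke of duration
`rise_time` (5 ms for action potentials, 30 ms for calcium transients)
followed by a stretched-exponential repolarisation
`exp(-((t-rise)/τ)^p)` (`p` = 3 for the AP plateau shape, 1.5 for the slower
calcium decay), renormalised to reach exactly zero at `1.6 × duration80`
past the upstroke. The decay constant τ is root-solved (Brent) so that the
time from the 10%-amplitude upstroke crossing to the 80%-recovery point
equals `duration80` exactly. The compact support matters: a 552-ms calcium
transient paced at 1 Hz would otherwise still be decaying when the next
beat arrives, leaving no clean diastole for baseline estimation — a real
property of long transients that the generator deliberately avoids so that
ground truth stays exact.

**Waves.** Activation time is `distance / cv` (planar: distance along
columns; point source: Euclidean distance from the origin), with the
template delayed accordingly per pixel. Defaults follow the acquisition
described for this preparation: 3.33-ms frames (300 fps) for voltage, 5-ms
frames (200 fps, binned 2×) for calcium, 0.05 mm/pixel so a 14-mm dish
spans a few hundred pixels. Noise is additive i.i.d. Gaussian at a stated
amplitude-to-sigma ratio (`snr`); optional multiplicative photobleaching
drift `exp(-t/τ_bleach)`. The generator rejects recordings too short for
the last beat to traverse the field and fully repolarise.

**Micrographs.** Nuclei are placed by grid-hashed rejection sampling with a
minimum separation of one diameter plus 2 px (bounded retries, then an
error). DAPI renders all nuclei as soft-edged disks; the PI channel renders
exactly `round(dead_fraction × n_cells)` of them; the eYFP channel renders
per-cell disks (radius 2× the nucleus radius) of mean amplitude
`expression_per_cell` with 10% cell-to-cell spread over a uniform
autofluorescence floor. What the micrographs do **not** emulate: spatially
varying illumination, optical point-spread, overlapping/clumped cells, and
non-nuclear PI signal. Passing tests therefore demonstrate correctness of
the quantification chain, not robustness to those real-data artefacts.

**Capture oracle.** A virtual paced monolayer captures a pulse iff
`irradiance ≥ rheobase · (1 + chronaxie/duration)` (Lapicque). Within ±5% of
that boundary, each would-be capture can fail independently with probability
`capture_noise`; the noise stream is keyed on (seed, irradiance, duration),
so replies are reproducible regardless of query order.

## Pre-processing

Order is fixed — baseline removal → full-range scaling → Bartlett 3×3 →
Savitzky-Golay (order 2, 7 frames) — and recorded in the movie's provenance
metadata.

- *Baseline*: per-pixel polynomial (default order 2) fitted to diastolic
  samples. Diastole is detected as frames within a small band (5% of
  amplitude + 3 robust noise sigmas) of the rolling minimum over an
  1100-ms window; because the window exceeds one transient at 1-Hz pacing,
  the selected frames spread uniformly across beats regardless of the
  transient duty cycle, which keeps the fit from tilting. A temporal
  morphological top-hat (same window) is available as an alternative.
- *Scaling*: per-pixel affine to [0, 1] by default (global optional); flat
  pixels are set to 0 and counted, not raised.
- *Bartlett*: convolution with `outer([1,2,1],[1,2,1])/16`, reflected
  borders; constants and interior affine ramps pass unchanged.
- *Savitzky-Golay*: scipy's `savgol_filter` with polynomial edge fitting;
  interior weights are `(-2, 3, 6, 7, 6, 3, -2)/21` (verified against the
  least-squares solution in the tests).

## Transient measurement

Events are temporal-derivative peaks above an adaptive threshold (8 robust
sigmas of the derivative and ≥25% of its maximum) with a 200-ms refractory
lockout — transients here last 260–550+ ms at 1-Hz pacing, so the lockout
cannot merge genuine beats but does suppress notched upstrokes. Each event
must also rise ≥6 noise sigmas above its local baseline, which is the
*median* of a pre-upstroke window that excludes the 15 ms just before the
foot: symmetric filters undershoot there, and a minimum- or low-quantile
baseline would inherit a systematic bias from noise (a low percentile sits
~1σ below rest, which measurably lengthens durations at snr ≤ 10).

The transient beginning is the upstroke's 10%-of-amplitude crossing
(configurable: maximum-derivative time); 80% recovery is the first downward
crossing of `baseline + 0.2 × amplitude` after the peak. Both are linearly
interpolated between bracketing frames — at 5-ms calcium frames the
quantisation would otherwise dominate. Events whose recovery is cut off by
the next event or the end of the recording are flagged unmeasurable and
excluded; a sample's value averages its first four measurable beats, and the
count used is reported. All crossing levels are defined relative to the
event's own baseline and amplitude, so measurements are invariant under
affine intensity changes.

Measurements default to the mean trace of a central ROI (25% of each side)
rather than per-pixel averaging; per-pixel traces at snr 5–10 leave
threshold-crossing noise of several ms on flat AP tails, while a ~50-pixel
ROI brings the median error below one frame across durations of 150–600 ms.

## Mapping

Activation time is the temporal-derivative argmax within a beat window,
refined by parabolic interpolation of the three derivative samples around
the peak (a 5-ms frame is ~10% of typical inter-isochrone timing, so
sub-frame refinement is not optional). Pixels whose amplitude falls below
20% of the field median are set NaN — dead-cell patches otherwise produce
spurious times. Isochrones are `find_contours` level sets at multiples of
10 ms above the earliest activation. CV paths default to three parallel
lines through the valid-pixel centroid along the median activation-gradient
direction; per path, CV is the inverse slope of activation time regressed
on distance (endpoint differencing is available), paths with fewer than 10
valid samples or less than 80% monotone increments are flagged and excluded,
and the mean is taken over valid paths. Phase movies use the analytic
signal of the mean-centred trace; constant pixels are NaN.

## Micrograph quantification

The PI threshold is a single constant shared by all groups: mean + 3 SD of
the pooled reference-group background (pixels below each image's Otsu
level). Viability fold change is the ratio of group means of summed
suprathreshold PI fluorescence. Because it is unstated whether a dead-cell
percentage refers to cells or pixels, both are computed and labelled:
`dead_fraction` (PI-positive nuclei / DAPI nuclei, a nucleus being positive
if the mean PI signal in a half-radius disk at its centre exceeds the
threshold) and `dead_pixel_fraction`.

The eYFP noise threshold is the 99.5th percentile of the pooled matched
control (non-expressing) images per condition; ChR2 images are corrected by
subtracting it (floored at zero), summed and divided by the DAPI nucleus
count. Subtracting a constant from suprathreshold pixels removes a small
signal-proportional share that is larger for dim cells than bright ones, so
fold changes of dim preparations are biased slightly upward (a ~2–4% effect
at a per-cell amplitude of 300 over an autofluorescence floor of 20); with
gain chosen for bright, unsaturated cells the bias is well inside the
reported uncertainty. Nucleus counting is Otsu thresholding, small-object
removal, distance transform and watershed splitting of touching nuclei.

## Excitability

The threshold search walks a geometric irradiance grid (ratio 1.25 from a
1 µW/mm² floor) until ≥10 of 10 consecutive 1-Hz pulses capture, then
bisects in log space to 2% relative precision; the certified capturing
bracket end is reported, and every oracle evaluation is kept as a
certificate. With stochastic capture failures near the boundary, the
10-of-10 rule biases thresholds toward the top of the noise band (up to
~+5% at high failure rates); this is inherent to the criterion and is
documented rather than corrected. The strength-duration model is the
Lapicque hyperbola (the asymptote at long durations *is* the rheobase, and
the fitted curve passes 2× rheobase at the chronaxie by construction); the
Weiss linear-charge form `E·d = r·d + r·c` is selectable. The
threshold-versus-dose hyperbola `k/(a+a₀)+E∞` is fitted only on doses up to
the observed minimum threshold: above ~2 µM, toxicity raises thresholds
again, which the conductance theory does not model, so those doses are
excluded and flagged.

## ChR2 threshold theory

The photocycle is the standard four-state scheme — closed C1/C2, open O1/O2
(O2 conducting a fraction γ), with irradiance-proportional activation rates
ε·F·E·p, voltage-dependent closure and recovery rates, light-dependent
inter-open transitions, and an activation variable p relaxing with
τ = 1.3 ms. All rate constants live in `src/opticard/data/chr2_h134r.yaml`,
not in code; they follow a published empirical H134R parameterisation and
are configuration, not claims. The generator matrix has zero column sums, so
occupancy is conserved exactly by the RK4 stepper (and C2 is eliminated as
`1 − C1 − O1 − O2` inside the ODE right-hand side). The photocurrent is
`g_ChR2 · f(V) · (O1 + γ·O2)` with an empirical inward-rectifying driving
function f(V) crossing zero near the ~0 mV reversal.

Two cell models are provided. The default excitable membrane is a
Hodgkin-Huxley-type fast sodium current (m³h gating) plus a linear
background current resting at −85 mV: it gives an all-or-none upstroke
crossing 0 mV, a monotone threshold in irradiance, and the qualitative
steep/flat two-region structure of threshold versus conductance. A full
multi-current human ventricular model was deliberately not transcribed: the
quantities this module is asked for are shape properties (monotonicity, the
ideal-current 1/x limit, the hyperbolic dose curve, the two-region
structure), which the light model satisfies verifiably, whereas an
unvalidated transcription of a ~19-state model would add error that could
not be checked here. The cell model is a plug-in (`initial_state`, `rhs`,
`v_index`), so a heavier model can be supplied. The second model, an ideal
fixed-charge-threshold cell with rectangular light-to-current conversion,
has the closed-form threshold `E_th = Q/(g·d)` and anchors the exact-1/x
tests.

Excitation integrates the coupled membrane+photocycle ODEs (LSODA,
rtol 1e-6) in two segments (light on, light off) with a terminal 0-mV
upward-crossing event; threshold bisection runs in log space to 1%
precision. `eth_vs_g` labels grid points by local log-log slope (steep
≤ −1); on the composed dose curve the two sensitivity regions appear on
linear axes, as for any hyperbola. The dose-to-conductance mappings are
linear (`g₀ + slope·a`), saturating (`g₀ + g_max·a/(a+a_half)`) and
parabolic (`max(g_floor, g₀ + b·a − c·a²)`, unique interior maximum); the
baseline g₀ is strictly positive so unsupplemented preparations remain
optically excitable, as observed.

## Problem sizes and determinism

Tests and the acceptance script use small fields (24×36 to 40×120 pixels,
3–4 beats, ≤10 micrographs of ≤1000 nuclei, conductance grids of ≤12
points) — sizes at which every recovery sits well inside its tolerance
while the full suite runs in a couple of minutes on one CPU. All randomness
descends from one run-level seed through named substreams
(`SeedSequence([seed, stage])`), so identical seeds reproduce every table
byte for byte.

## Known limitations

- The noise model is Gaussian and white; EMCCD/CMOS-specific noise,
  motion, and contraction artefacts are out of scope (the preparation is
  typically imaged with excitation-contraction uncoupling or handled
  upstream).
- Dead-cell and expression quantification assume nuclei are resolvable;
  heavily clumped cultures would need a different segmentation stage.
- The threshold theory is single-cell: tissue-level source-sink effects on
  the optical threshold are not modelled, so comparisons to monolayer
  thresholds are qualitative (shape, not absolute irradiance).
- Statistical testing (ANOVA across dose×duration) is intentionally not
  reimplemented; the package emits tidy per-sample tables for any stats
  environment.
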