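# Methods

`streakvision` simulates what the early visual system sees when a
target moves rapidly across the retina during a saccade, and how the
resulting response dynamics could trigger a corrective gaze shift.  The
package has two model layers: an early-vision filter model that turns a
retinotopic contrast movie into channel-resolved population responses,
and a predictive "switch" model that converts those responses into the
time at which an unexpected target displacement is first noticed.  All
inputs are produced by a seeded synthetic trial generator; no empirical
recordings enter the pipeline.

## Synthetic trials

A trial emulates the following stimulation protocol.  A bandpass noise
patch (−3 dB cutoffs 0.33 and 1.02 cpd, 100% Michelson contrast before
a Gaussian aperture of SD 0.56 dva, footprint 3.36 dva ≙ 51 px at full
resolution) sits 18.25 dva from fixation.  The observer saccades to it;
during the saccade the patch either stays put (static) or is displaced
6.6 dva in 25 ms (36 frames at 1440 fps) upward, downward, outward (in
saccade direction) or inward — either as continuous constant-velocity
motion (streak present) or with the motion interval blanked and the
patch reappearing at the endpoint (streak absent).

The saccade generator uses a minimum-jerk position profile: smooth,
unimodal, symmetric velocity with peak velocity 1.875·amplitude/duration
(≈616 dva/s for the mean 17.6 dva, 53.6 ms saccade, inside the
empirically observed 410–644 dva/s range).  Trial-to-trial variability
is Gaussian around the study means: amplitude SD 1.0 dva (clipped at
±2.5 SD to bound the canvas), duration SD 3.3 ms (clipped to
40–70 ms), an upward vertical bias of 0.15 ± 0.10 dva, and a
motion-onset latency of 10 ± 1.5 ms after saccade onset (the protocol
only constrains the motion to lie strictly inside the saccade; the
latency emulates an online detection delay).  These SDs are our choice
of realistic within-observer variability; they are the source of the
landing-position scatter that the switch model's threshold has to
absorb.  Leftward saccades are equivalent to mirrored rightward ones,
so the generator only produces rightward trials.

The renderer subtracts gaze from the target position frame by frame and
inserts the patch at the retinal position with bilinear sub-pixel
interpolation.  Coordinates are retinotopic: fovea at the origin, x
rightward, y upward (image rows run top-down; the filter bank uses the
same convention so orientation channels are not mirrored).  The default
canvas spans [−10.5, 20.5] × [−9, 9] dva — wide enough for the inward
condition, whose target reaches ≈ −8.5 dva on the retina including the
patch footprint.  When the model rate is below the display rate each
movie frame averages interpolated placements over the frame interval
("subframes").  This matters: at 240 Hz a target moving at several
hundred dva/s hops 2–3 dva between frames, which destroys the oriented
intra-frame smear that constitutes the motion streak; averaging
subframe placements restores the blur that a 1440 fps projection
produces physically.  Interpolation is applied to gaze always and to
target position only for steps below 2 dva per frame, so the
displacement jump of streak-absent trials is not smeared into a
spurious streak.

### Resolution presets

* full: 1440 Hz, 0.0659 dva/px (the display resolution).
* test: 480 Hz, 0.118 dva/px.
* coarse: 240 Hz, 0.124 dva/px — used for the many-trial batteries in
  the test suite and demonstrations in this repository.

The pitch of any preset must keep the 4 cpd channel below Nyquist,
which caps it at 0.125 dva/px.  Physical parameters are always in dva
and seconds and rescale automatically.

## Spatial filter bank

Seven spatial frequencies (0.25–4 cpd in half-octave-ish steps) × eight
orientations (22.5° spacing) × even/odd quadrature phases.  Filters are
log-Gabors constructed in the frequency domain — Gaussian in log radial
frequency and in orientation, single-sided so that the inverse
transform's real and imaginary parts form the quadrature pair — hence
exactly zero DC response.

Bandwidths are physiologically scaled rather than constant:

* SF bandwidth (FWHM) is 1.5 octaves at and above the critical SF of
  2 cpd and grows by 0.26 octaves per octave below it.
* RF size follows σ_RF(θ) = β₀/(2θ) above 1 cpd and β₀θ^(−1/2)/2 below,
  with β₀ = 1 dva of RF width at 1 cpd.
* Orientation bandwidth follows from the Gabor aperture–frequency
  trade-off, w_ω = 2·arctan(√(2 ln 2)/(2π σ_RF θ)): constant ≈41° at
  and above 1 cpd (σ_RF·θ constant there) and growing to ≈100° at
  0.1 cpd.

Kernels are cropped to 8·σ_RF(θ) (odd pixel count), and convolution is
zero-padded (mean-grey surround).  The production path shares one
padded frame FFT across all 56 channels and obtains both phases from a
single complex kernel; a double-precision mode exists for numerical
cross-checks against direct convolution.

## Temporal response functions

Spatial responses alone would carry temporal frequencies far beyond
what vision resolves.  Per SF, an impulse response

H(t) = A (t/τ)ⁿ e^(−t/τ) [1/n! − B (t/τ)ᵏ/(n+k)!]

is fitted so that convolving 7.5-s Gaussian-ramped flicker envelopes
(SD δ/8; sampled at 500 Hz) with H and collapsing by temporal
probability summation, S(f) = [∫|I∗H|^β dt]^(1/β), reproduces flicker
contrast sensitivity across 33 TFs (0.5–50 Hz).  The sensitivity
targets come from Kelly's stabilised spatiotemporal surface
G(α,v) = (6.1 + 7.3|log₁₀(v/3)|³)·v·(2πα)²·exp(−4πα(v+2)/45.9)
evaluated at v = f/θ and halved (flicker thresholds are about twice
motion thresholds).  β is not empirically constrained here and defaults
to 3, the conventional probability-summation exponent; it is exposed in
configuration and recorded in outputs.

Fitting minimises the RMSE in log₁₀ sensitivity.  A has a closed-form
profile solution; (τ, B) are optimised by bounded quasi-Newton descent
(τ ∈ [1.5, 90] ms, B ∈ [0, 2]) inside each integer-order cell, with a
batched coarse scan and a cheap local refinement of all 27 cells
(n ∈ 3…11, k ∈ 1…3) before full refinement of the best candidates —
the coarse ranking alone is an unreliable predictor of the refined
error.  Near-tied cells (within 1% relative error) resolve to the
lowest integer orders.  The winning cell gets a derivative-free
simplex finish from several coarse starts, because the (τ, B)
objective can hold needle-like minima separated by ridges that stall
finite-difference gradients.  Everything is deterministic.

Low SFs have bandpass temporal sensitivity and yield biphasic kernels;
high SFs are lowpass and yield monophasic kernels.  The transition
falls between ≈2.0 and ≈2.4 cpd.  Near the transition the data barely
constrain the kernel's phase behaviour: a strong-undershoot and a
no-undershoot solution fit almost equally well, and independent per-SF
fits flip between near-tied integer cells from one SF to the next.  A
polish pass therefore refits all SFs within the single modal (n,k)
cell by continuation — upward through the biphasic regime, downward
through the monophasic one — keeping the smoothed solution whenever its
error stays within 10% (relative) of the independent fit.  The
independent fits still decide each SF's shape class and the regime
boundary.  "Biphasic" is operationalised as a sign change whose lobes
both exceed 5% of the kernel peak; numerically negligible tail lobes do
not count.

The 31 fitted kernels are summarised by least-squares tensor-product
cubic splines over (time, log SF) with 50 time knots and a 10-knot
budget in log SF.  Kernels are peak-normalised before the surface fit,
with a separate 1-D log-amplitude spline across SF, so SFs with very
different gains are represented at comparable relative fidelity.  The
surface is piecewise in SF, split where the normalised kernel family
jumps (relative L2 distance between adjacent kernels above 0.4 — in
practice, at the biphasic→monophasic branch flip): no single smooth
tensor spline can track a discontinuity between adjacent grid SFs.
Surface evaluation at a training SF reproduces that SF's kernel within
a few percent relative RMSE, and re-predicting sensitivity from
surface-extracted kernels over the full 31 × 33 grid gives a mean
squared error of ≈0.004 log₁₀ units (run `scripts/acceptance.py` to
recompute it).

Discrete kernels for the main pipeline are sampled from the surface at
the movie rate, scaled by 1/rate (rate-invariant gain), and truncated
where |H| < 10⁻⁴ of its peak or at 600 ms.

## Energy and delayed normalization

Even/odd responses are squared and summed into a phase-invariant energy
R_E (the φ axis disappears).  The normalization pool R_LP is R_E passed
through a causal exponential lowpass (τ = 0.75; the source prints no
unit, we read seconds — configurable), a spatial Gaussian of SD
0.5 dva, and a weighted average over the ±2-cell SF/orientation
neighbourhood with Gaussian distance weights (σ = 1 octave, 11.5°;
orientation wrapped at 180°, SF truncated at the grid edge with weight
renormalisation).  Both lowpass kernels are unit-sum, so constant input
has unit steady-state gain.  The printed form of the pooling weight in
the source material is corrupted (it is not a Gaussian and would be
minimal at zero distance); the Gaussian form is used, with the literal
printed form available behind a configuration flag for sensitivity
analysis.  The output is

R_N = R_E^n / (σ^n + R_LP^n),  σ = 0.07, n = 1.4.

Because R_LP lags R_E, onset transients pass nearly unnormalised while
sustained stimulation is compressed — the transient/sustained dynamics
of early visual cortex.  With τ = 0.75 s the pool builds slowly; over a
seconds-long fixation it saturates, but within the ~150 ms trial epochs
simulated here normalization acts mostly through the growing
denominator at sustained locations.

## Response summaries

Spatial aggregates sum R_N over channels and time; channel engagement
sums over space and time; the streak contribution is the engagement
difference between yoked present/absent trials.  Trial pairs are yoked
(identical saccade and timing; only the motion interval differs)
because with small trial counts an unpaired contrast is dominated by
saccade-jitter sampling noise of the much larger sweep response.  The
peak channel is reported with the circular mean (period 180°) of the
per-trial retinal trajectory directions and ±2 circular SDs.

One behaviour of the engagement summary deserves a caveat: summed over
a whole trial, engagement is dominated by the response to the
stationary pre- and post-saccadic patch, so the peak orientation of a
single condition reflects the orientation content of the specific
noise realisation rather than the saccadic sweep.  Claims about
sweep- or streak-driven orientation tuning are therefore made on
contrasts (present − absent) or on direction differences, never on a
single condition's absolute engagement.

The single-RF demonstration passes a small Gaussian dot (SD 0.1 dva)
horizontally through one log-Gabor RF whose stripes are parallel or
orthogonal to the motion.  The default SF is 0.63 cpd, placing the
orthogonal polarity flicker at ≈6 Hz for a 10 dva/s pass — the sweet
spot of temporal sensitivity; the movie continues 0.3 s beyond the pass
so the lagged response plays out.  At 10 dva/s both RF types respond at
similar strength; at 100 dva/s the orthogonal response collapses (the
polarity flicker is far above the resolvable TF range) while the
parallel RF still emits a brief burst — motion coded as orientation.

## The switch model

The sensorimotor contingency x̄ is the mean channel-collapsed R_N of
static-condition trials: the visual change a saccade over a static
scene typically produces.  The prediction Δx̄⁺ is the positive temporal
difference of x̄, maximum-filtered over a ±w_i window (w_i = 15 ms);
during a saccade the retinal image moves, so temporal tolerance grants
spatial tolerance along the sweep path.  The measurement Δz⁺ is the
instantaneous positive temporal difference of the current trial
(asymmetric by design; a configuration flag symmetrises both).  The
prediction error y_k compares the two *pointwise in retinotopic space*
and pools the largest local error:

y_k = max_{y,x} [ Δz⁺_k(y,x) − Δx̄⁺_k(y,x) ].

The location-resolved comparison is essential: activity appearing where
the saccade alone never produces any is inherently surprising even when
its magnitude resembles the prediction, and without it the directional
asymmetries between target motion conditions vanish.  A location-blind
variant that compares the two spatially pooled scalar series is
available (`comparison="global"`), and the scalar series themselves are
exposed as `predicted_change`/`measured_change`.

The threshold is λ = median(d⁺) + c·1.4826·MAD(d⁺) over the positive
change maxima of x̄ within the saccade window, with c = 3 by default —
a conventional robust outlier criterion; the source only specifies a
"median-based deviation".  The switch indicator is K_k = 1 iff
y_k > λ, the first switch sample is the model's gaze-correction
trigger time, and a position estimate x_{k+1} = x_k + Δx̄⁺_k + K_k·y_k
is maintained as a scalar accumulated-change state for completeness
(only the switch time is treated as a validated output).  Switch times
are also reported with subsample precision by linearly interpolating
the crossing of y through λ, since coarse model rates otherwise
quantise crossing times to several milliseconds.

On synthetic batteries the model reproduces the qualitative pattern of
the paradigm: errors are absent in the first half of the saccade;
above-threshold errors arise mainly after the target shift, driven by
the post-saccadic onset transient at the target's final retinal
position; outward motion triggers much earlier errors (the target
briefly stabilises on the mid-saccade retina, injecting unpredicted
activity); vertical motion follows; inward motion — whose retinal
trajectory stays within the horizontally smeared territory of the
static contingency — triggers the latest errors among moving targets;
and static trials still occasionally cross threshold because of
landing-position scatter.

## What the generator does and does not emulate

The generator reproduces the stimulus statistics, timing and first-order
saccade kinematics of the paradigm, but idealises: minimum-jerk
velocity profiles instead of recorded saccades (no post-saccadic
oscillations, no skewed velocity profiles, no main-sequence
amplitude–duration coupling), no pre-saccadic fixation epoch (trials
start 10–20 ms before saccade onset, so slow normalization pools are
not pre-charged by the long pre-saccadic target exposure), no
eccentricity dependence of RF size or sensitivity, and no response
noise.  Passing tests therefore demonstrate the internal consistency
of the mechanism under controlled conditions, not quantitative
agreement with recorded eye-tracking or EEG data.

## Problem sizes and numerical choices

The test suite and the demonstrations run at the coarse preset (240 Hz,
0.124 dva/px, trials spanning 10 ms before saccade onset to 120 ms
after the 70 ms saccade budget) with 4 trials per direction × streak
cell and 6 static trials for the contingency — sizes chosen so a full
battery plus the TRF derivation completes in minutes on one CPU while
every qualitative effect remains resolvable.  The single-precision
pipeline matches the double-precision path to float32 rounding; all
randomness flows from explicit seeds, and repeated runs are
bit-identical.  Degenerate inputs (zero-amplitude patches, zero-length
kernels, all-zero contrasts) raise typed errors rather than propagating
NaNs.

Known limitations: switch-time differences between upward/downward/
inward conditions are a few milliseconds at coarse resolution — real
condition effects but small relative to trial jitter, so small
batteries order them correctly only on average; the biphasic/monophasic
class of TRFs between 2 and 2.5 cpd is genuinely under-determined by
flicker sensitivity alone; and absolute response units are arbitrary
(only ratios and timings are meaningful).
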