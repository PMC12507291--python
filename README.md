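# streakvision

When the eye makes a saccade, the image of the world — and of anything
that moves while the eye is in flight — sweeps across the retina at
hundreds of degrees per second, leaving oriented smears: motion
streaks.  `streakvision` is a computational model of how early vision
represents these intra-saccadic streaks and how the visual system could
exploit them to notice, still during the saccade, that a target has
moved and a corrective (secondary) saccade is needed.

The package is aimed at visual-psychophysics and active-vision
researchers who want a physiologically grounded, fully synthetic
sandbox: every input is generated by a seeded trial simulator (bandpass
noise target, minimum-jerk saccades, intra-saccadic target
displacement with or without a continuous motion streak), so all
results are reproducible from a single seed.

## The model

1. **Spatial filtering.** A bank of log-Gabor quadrature pairs
   G(θ, ω, φ) with seven spatial frequencies (0.25–4 cpd) and eight
   orientations (22.5° apart).  Bandwidths scale physiologically: SF
   bandwidth w_θ = 1.5 octaves above 2 cpd, growing by 0.26 oct/oct
   below; RF size σ_RF = β₀/2θ above 1 cpd (β₀ = 1 dva); orientation
   bandwidth w_ω = 2 arctan(√(2 ln 2)/(2π σ_RF θ)) ≈ 41° above 1 cpd,
   ≈ 100° at 0.1 cpd.
2. **Temporal filtering.** Per-SF impulse responses
   H(t) = A (t/τ)ⁿ e^(−t/τ)[1/n! − B(t/τ)ᵏ/(n+k)!] are fitted so that
   probability summation over flicker responses,
   S(f) = [∫|I(t,f) ∗ H|^β dt]^{1/β}, reproduces Kelly's flicker
   sensitivity surface; a tensor-spline surface over (t, log θ) then
   yields a kernel for any SF.  Kernels are biphasic below ≈2 cpd and
   monophasic above.
3. **Energy and delayed normalization.** Quadrature energy
   R_E = R_even² + R_odd² is divisively normalised,
   R_N = R_E^n / (σ^n + R_LP^n), by a delayed pool R_LP (temporal
   exponential, spatial Gaussian, ±2-cell SF/orientation
   neighbourhood), producing transient/sustained dynamics.
4. **The switch model.** A sensorimotor contingency x̄ — the average
   saccade-induced response over static trials — predicts the positive
   visual change Δx̄⁺ at every retinotopic location within ±15 ms.  The
   measured change Δz⁺ of the current trial is compared pointwise; the
   largest local prediction error y_k = max_{y,x}(Δz⁺ − Δx̄⁺) crosses a
   robust threshold λ when the target's displacement becomes
   detectable.  The first crossing is the model's gaze-correction
   trigger time.

## Worked example

```python
import numpy as np
from streakvision import (BankSpec, COARSE_SCALE, TemporalFilterModel,
                          build_bank, channel_engagement,
                          condition_difference, orientation_bandwidth,
                          run_model, simulate_trial)

# orientation bandwidth of the RF model at its anchors
print(f"w(2 cpd)  = {orientation_bandwidth(2.0):.1f} deg")
print(f"w(0.1 cpd)= {orientation_bandwidth(0.1):.1f} deg")

# derive temporal kernels (about 3 minutes, deterministic)
fit = TemporalFilterModel().fit()
print(f"sensitivity round-trip MSE = {fit.reconstruction_mse():.4f}")

# a yoked pair of upward trials (same saccade, streak on/off) through
# the full model at coarse resolution: the streak's contribution is the
# engagement difference between the two
bank = build_bank(BankSpec(), pitch=COARSE_SCALE.pitch)
kernels = fit.kernels_for(bank.sf_set, COARSE_SCALE.rate)
eng = {}
for streak in ("present", "absent"):
    trial = simulate_trial("upward", streak, seed=101, scale=COARSE_SCALE)
    resp = run_model(trial.movie, bank, kernels)
    eng[streak] = channel_engagement(resp)
    if streak == "present":
        axis = (trial.retinal_motion_angle() + 90) % 180 - 90
contrast = condition_difference(eng["present"], eng["absent"])
i, j = np.unravel_index(np.argmax(contrast), contrast.shape)
print(f"streak contrast peaks at {bank.sf_set[i]:.2f} cpd, "
      f"{bank.ori_set[j]:.1f} deg (retinal trajectory axis {axis:.1f} deg)")
```

prints

```
w(2 cpd)  = 41.1 deg
w(0.1 cpd)= 99.7 deg
sensitivity round-trip MSE = 0.0036
streak contrast peaks at 1.00 cpd, -22.5 deg (retinal trajectory axis -28.8 deg)
```

The bandwidth anchors land on the published values (41°, ~100°).  The
round-trip error says the 31 fitted kernels, compressed into a spline
surface, re-predict the whole 31 × 33 sensitivity grid to within
0.0036 log₁₀ units.  The streak contrast peaks at a mid-low SF (inside
the 0.33–1.02 cpd stimulus band) and in the orientation channel closest
to the target's oblique retinal trajectory: the upward-moving target,
swept leftward on the retina by the rightward saccade, leaves an
oblique streak that the model codes in the parallel orientation
channel.

A command-line interface mirrors the library:

```
streakvision fit-trf --out trf.h5
streakvision simulate-trial --direction upward --streak present --seed 7 --out trial.h5
streakvision build-bank --scale test --out bank.h5
streakvision run --trial trial.h5 --bank bank.h5 --trf trf.h5 --out resp.h5
streakvision switch --trf trf.h5 --scale test --out switch.csv
```

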