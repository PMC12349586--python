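# sprpol — quad-polarization phase-sensitive SPR imaging

`sprpol` is a simulation and analysis toolkit for phase-sensitive surface
plasmon resonance (SPR) imaging with a polarization filter array (PFA)
camera. It is written for instrument builders and analysts who want to
study, end to end, how a quad-polarization SPR phase imager turns
refractive-index changes into phase images, how collaborative-filtering
denoising improves the refractive-index resolution, and how binding
kinetics are extracted from the resulting sensorgrams.

The package covers five things:

1. **Forward optics.** Kretschmann-prism SPR reflection from a
   ZF5 / Cr(3 nm) / Au(30 nm) / sample stack at 633 nm via the recursive
   Fresnel multilayer model, and Jones-calculus propagation through a
   half-wave plate (fast axis at 22.5°) onto the four PFA analyzer
   orientations (0°, 45°, 90°, 135°).
2. **Synthetic acquisitions.** Rendering of four-channel video for
   constant, step-switching (glycerol ladders, dilute NaCl) and
   binding-kinetics protocols, with additive Gaussian sensor noise,
   frame-global source-power fluctuation, and 12-bit quantization.
3. **PPBM4D denoising.** A two-stage collaborative filter for
   quad-polarization video that augments BM3D/BM4D grouping with virtual
   *polarization pairs* derived from total-intensity conservation, shares
   block matching across the four channels, and filters 4-D groups with a
   separable biorthogonal-wavelet / Hadamard / DCT transform (3σ hard
   threshold, then λ = 1 empirical Wiener refinement).
4. **Phase extraction and metrics.** Per-pixel phase maps, ROI
   sensorgrams, linear sensitivity calibration (rad/RIU), and the 3σ
   refractive-index resolution.
5. **Binding kinetics.** The 1:1 Langmuir association/dissociation model
   with global nonlinear fitting of (k_a, k_d, Γ_max) across a
   concentration ladder, KD = k_d / k_a, and multi-ROI statistics.

## The model in brief

With amplitude reflection coefficients r_p, r_s (phases φ_p, φ_s) and the
polarizer at α = 45°, the four detected intensities satisfy

    I0   = (E²/2)(r_p²cos²α + r_s²sin²α + 2 r_p r_s cosα sinα cos Δφ)
    I90  = (E²/2)(r_p²cos²α + r_s²sin²α − 2 r_p r_s cosα sinα cos Δφ)
    I45  = E² r_p² cos²α
    I135 = E² r_s² sin²α,        Δφ = φ_p − φ_s

so that

    cos Δφ = (I0 − I90) / (2 √(I45 · I135)),

an estimator that cancels the source intensity E² exactly and the
common-mode part of I0/I90 by subtraction. Conservation
I0 + I90 = I45 + I135 makes each channel virtually re-measurable from the
other three (e.g. I′0 = I45 + I135 − I90) — the redundancy the PPBM4D
denoiser exploits. Refractive-index changes move the SPR resonance and
sweep Δφ; a linear calibration S (rad/RIU) converts the phase noise SD σ_φ
into the resolution 3σ_φ / S.

## Worked example

Simulate the phase response of the default instrument and fit binding
kinetics on a synthetic antibody dilution ladder:

```
$ spr simulate-curve --out curve.csv --steps 50
wrote curve.csv (aoi = 58.166 deg)

$ spr run kinetics --seed 0
{
  "name": "kinetics",
  "seed": 0,
  ...
  "metrics": {
    "ka": 100085.49827578204,
    "kd": 0.00019542720317779585,
    "gamma_max": 0.049944506158106375,
    "KD_M": 1.952602590230436e-09,
    "true_KD_M": 1.97e-09,
    "kd_rel_diff_percent": 0.8831172471859808
  },
  ...
}
```

The curve CSV gives |r_p|, |r_s|, Δφ and the four channel intensities
versus the sample refractive index over 1.333–1.393 at the automatically
selected operating angle (the angle of maximal mid-range phase
sensitivity whose phase stays on one monotone arccos branch across the
whole range). The kinetics run simulates sensorgrams for eight
goat-anti-rabbit-IgG concentrations (20 down to 0.15625 µg/mL, about
133 nM to 1 nM at 150 kDa), adds 1% proportional noise, refits the shared
rate constants, and reports the recovered equilibrium dissociation
constant: here KD = 1.95 nM against a simulated truth of 1.97 nM, a 0.88%
error.

A full denoising experiment (simulate → denoise → extract → metrics):

```
$ spr run noise_floor --seed 1
```

renders a 60-frame 128×128 steady-water stack whose raw ROI-phase noise
is calibrated to 6.14×10⁻⁵ rad, denoises it with the two-frame
polarization-pair filter, and reports raw/denoised phase SDs and the
corresponding 3σ refractive-index resolutions.

Other subcommands: `spr simulate`, `spr denoise`, `spr extract`,
`spr calibrate`, `spr resolution`, `spr fit-kinetics`, and
`spr run {ablation_table,frames_table,glycerol_calibration,nacl_steps,...}`.

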