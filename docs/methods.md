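# Methods

This note documents the models implemented in `sprpol`, the conditions the
synthetic-data generator emulates, the numerical choices behind each stage,
and the limits of what the flat-field surrogate experiments demonstrate.

## Optical forward model

Reflection from the prism-coupled layer stack is computed with the
recursive (Parratt) Fresnel formulation; an independently coded
characteristic-matrix (Abeles) oracle is held against it in the test
suite. Conventions, fixed package-wide:

* layer-normal wavevectors take the `Im(kz) >= 0` branch;
* the sign convention gives, at normal incidence,
  `r_s = (n1 - n2)/(n1 + n2)` and `r_p = (n2 - n1)/(n2 + n1)`;
* `delta_phi = arg(r_p) - arg(r_s)`, wrapped to `(-pi, pi]`, and defined
  as 0 when the reflection vanishes.

Default stack: ZF5 prism (n = 1.734), Cr 3 nm, Au 30 nm, water
substrate, 633 nm. The metal constants at 633 nm are not a measurement of
this package; a small built-in table ships Palik-class literature values
(Au 0.1834 + 3.4332i, Cr 3.58 + 4.36i) so results cannot silently depend
on an external optical-constants database. Both are configurable per
layer. With these defaults the p-reflectance shows the expected deep
resonance dip (|r_p|min ≈ 0.31 near 58°) while |r_s| stays near unity.

Jones propagation uses the (p, s) basis with x = p; the analyzer and
polarizer angles are measured from the p axis. The closed-form channel
intensities are verified against explicit Jones matrix products to 1e-12.
The interference sign is fixed so that the quad-channel estimator
`(I0 - I90)/(2 sqrt(I45 I135))` returns `+cos(delta_phi)` on noise-free
data; with that convention the quadrature (non-interference) term of
I0/I90 is `r_p² cos²α + r_s² sin²α`, which the products force once
I45 = E² r_p² cos²α and I135 = E² r_s² sin²α are required.

**Operating angle.** The instrument's angle of incidence is a free design
parameter. The default is chosen deterministically by a dense sweep:
among angles for which `delta_phi(n)` is strictly monotone and stays
inside `(0.1, pi - 0.1)` over the working range n ∈ [1.333, 1.393], take
the one maximizing |d delta_phi / dn| at the mid-range index n = 1.363.
The branch constraint exists because the phase readout is the principal
arccos branch: a wide-dynamic-range instrument whose calibration is
linear over the whole range cannot tolerate a fold inside it. For the
default stack this yields 58.17° and a forward sensitivity of
≈ 48.7 rad/RIU over the 0.06 RIU range (the corresponding reference
instrument calibration is 52.504 rad/RIU; the absolute value depends on
the exact metal constants and angle, so only the shape and order of
magnitude are meaningful).

## Synthetic acquisitions

`render_video` maps a protocol n(t) (piecewise-constant steps, a constant
baseline, or a 1:1-binding-driven time course expressed in RIU) through
the forward model to the four channel intensities per frame, optionally
adds a static smooth spatial refractive-index field (tilt plus low-order
sinusoid) for spatial-domain studies, and applies the acquisition chain:

1. a fixed camera gain anchoring the first frame's I0/I90 mean at half
   the ADC full scale, capped so that no clean channel exceeds 98% of
   full scale anywhere in the protocol (the exposure rule of a camera set
   up to avoid both overexposure and quantization starvation — the
   resonance sweep would otherwise saturate I90 during a glycerol
   ladder);
2. a frame-global multiplicative source factor `(1 + eps_t)`,
   `eps_t ~ N(0, source_cv²)` (laser-power fluctuation, default CV
   1e-3);
3. i.i.d. additive Gaussian noise per pixel per channel (`sigma_add`
   counts) — dark current, readout and shot noise folded into one
   Gaussian, as is appropriate for a sensor operated at a fixed mid-scale
   exposure;
4. rounding to the ADC grid (12-bit default) with clipping at full scale.

The pre-noise stack is returned as ground truth. Rendering is
bit-reproducible under the seed. Analyte-to-RIU conversion uses linear
engineering coefficients fixed from the working-range endpoints
(glycerol 0.060/46 RIU per mass-%, NaCl 1.7e-3 RIU per mass-%); they are
approximate by construction. The 2×2 mosaic layout defaults to
`[[90°, 45°], [135°, 0°]]` (the common order of the sensor family used
for this kind of imaging) and is configurable; pack/unpack round-trips
are bit-exact.

**Noise calibration.** `calibrate_noise_to_phase_sd` bisects `sigma_add`
until the temporal SD of the mean-ROI phase of a rendered constant-index
stack hits a target (e.g. the 6.14e-5 rad raw noise floor of the
reference instrument). The same seed is reused for every bisection
evaluation, making the objective deterministic and monotone. Calibration
runs without quantization: on a *perfectly flat* synthetic field an
undithered quantizer produces ROI-correlated rounding artifacts that no
spatially heterogeneous real acquisition shows, and at the default
operating point the calibrated sigma is below one count. For the same
reason the flat-field denoising surrogates (noise floor, ablations,
frame-count sweep, PSNR, dilute-NaCl steps) are rendered with purely
additive Gaussian noise — quantization off, source term off. The source
term stays off there for a second reason: the quad-channel estimator
cancels a common-mode factor *exactly* on raw data, but a nonlinear
filter applied per channel transmits it inconsistently across channels,
so a surrogate with a large source term would measure that artifact
rather than the filter. Source-fluctuation cancellation is tested
separately as a property of the estimator.

**Default measurement ROI.** ROI statistics default to the central
H/4 × W/4 block (32×32 on a 128×128 frame). ROIs on the reference
instrument class are a small fraction of the per-channel sensor area, and
the ROI-mean phase over a modest region is the noise-floor statistic of
interest; the package takes a proportionally small central region.

## The collaborative polarization-pair denoiser

Two-stage BM3D-family filtering of the four-channel video, with three
additions specific to quad-polarization data.

**Polarization pairs.** Conservation I0 + I90 = I45 + I135 yields a
virtual re-measurement of each channel from the other three
(I′0 = I45 + I135 − I90 and cyclic variants — the four identities are the
unique ones conservation determines). Virtual frames carry the same
signal with independent noise of variance 3σ² and are stacked with the
measured frames, enlarging each group without new acquisitions. Virtual
values are not clipped at zero.

**Shared, stack-based block matching.** 8×8 reference patches on a
stride-4 grid (trailing positions forced onto the frame edges so every
pixel is covered) are matched within a 40×40 search window, on the
0-degree channel only — the channel carrying the full interference
signal. The distance is the mean squared patch difference *averaged over
the stacked channel-0 layer images* (measured + virtual + temporal
context), which suppresses the noise-driven selection bias a
single-image distance suffers at low contrast. The best 16 candidates
(L2, ties broken in raster order, the reference always present at
distance 0) are kept, and the coordinates are shared by all four
channels.

**Causal pilot context.** The temporal context of frame t consists of
the best *causally available estimates* of the preceding frames: in
stage 1 the pass's own already-computed output frames, in stage 2 the
stage-1 ("standard") video. Frame 0 replicates its own input. This makes
the filter a streaming, real-time-capable recursion, and it is what
produces the characteristic frame-count signature of the method: a
recursive causal average has steady-state noise variance σ²/3 already at
a two-frame context, so adding a third frame yields only a marginal
further gain, whereas plain averaging of noisy past frames would predict
a clearly visible improvement from 2 to 3 frames. The default context is
2 frames; 1 and 3 are supported.

**4-D transform.** Separable: a biorthogonal-1.5 wavelet on the 8×8
patch axes, orthonormal Hadamard across the block axis (zero-padded to
the next power of two when a group is smaller), orthonormal DCT-II
across the frame-layer axis. The patch wavelet uses the *full*
multi-level decomposition (8→4→2→1, periodized), so the patch DC is a
single coefficient; a single-level transform would leave a constant
patch spread over 16 approximation coefficients, and hard thresholding
could then destroy flat plateaus — fatal for near-flat phase images. The
depth is configurable. Because the wavelet is biorthogonal (not
orthonormal), per-coefficient noise gains are computed numerically once
per patch size from the analysis operator; the frame-axis DCT propagates
the layer covariance (variance 3σ² for virtual layers, perfect
correlation for the duplicated layers of the no-pair ablation). The hot
path applies the patch transform as a cached 64×64 matrix product and
the layer/block transforms as one fused Kronecker product, in single
precision; reconstruction error is at the 1e-6-count level, orders of
magnitude below the noise.

**Filtering and aggregation.** Stage 1 zeroes transform coefficients
with |c| < 3σ_c (the group DC coefficient is exempt) and aggregates the
target-frame patch estimates by weighted averaging with weights
1/N_retained. Stage 2 re-matches on the standard video and applies
empirical Wiener shrinkage `w = G²/(G² + λ σ_c²)` with λ = 1, the guide
coefficients G taken from the standard video's groups, weights
1/Σ(w²σ_c²). The per-channel σ is user-supplied (known for synthetic
data) or estimated as MAD/0.6745 of the finest diagonal wavelet subband
of the first frame. No Kaiser windowing is applied in aggregation.
Ablation modes: `bm4d_no_pp` (virtual layers replaced by duplicates) and
`bm3d_single_frame` (each channel filtered independently, single frame,
no pairs).

**What the flat surrogates show — and a structural limit.** On flat
calibrated stacks the pair mode lowers the denoised ROI-phase SD
relative to the duplicate-layer ablation (paired over seeds), both beat
the raw data, and the frame-count sweep reproduces the large-1→2 /
negligible-2→3 pattern. The two-stage pipeline reduces the ROI-phase SD
by roughly 40–46% on such stacks while the hard-threshold stage alone
reaches about 60%: on a *perfectly flat* field the pilot's residual is
spatially coherent and temporally persistent, the block-Hadamard and
frame-DCT gains amplify it into guide coefficients G ≫ σ at exactly the
coarse scales the ROI mean measures, and the Wiener shrinkage therefore
re-transmits about half of the target frame's coarse noise. Per-pixel
error tells the opposite story — the Wiener stage clearly improves
pixel-level MSE and phase-image PSNR. Real acquisitions, which carry
genuine spatial structure at those scales and whose ROI statistics sit
on textured fields, are not bound by this flat-field behavior; the
flat-stack numbers should be read as properties of the surrogate, not
forecasts for instrument data.

## Phase extraction and metrics

`cos_delta_phi` evaluates the estimator per pixel, clamps to [−1, 1]
(clamped pixels are reported in a mask — inevitable near branch ends
under noise), flags zero-denominator pixels invalid (NaN), and
`phase_image` takes the principal arccos branch [0, π]. No 2π unwrapping
is attempted; the operating-point design keeps the working range on one
branch. ROI sensorgrams average the per-pixel *phase* over the ROI
(matching the phase-image-first workflow); an intensity-first variant is
provided for comparison. Calibration fits plateau phase means (central
60% of each protocol segment, transitions excluded) against refractive
index by ordinary least squares; the 3σ resolution is `3 sd(phase)/S`.
The smoothing filter is a centered moving average with truncated edge
windows.

## Binding kinetics

The 1:1 model: association
`G(t) = Gmax · C/(C + KD) · (1 − exp(−t(ka·C + kd)))` and dissociation
`G(t) = G(t_pbs) · exp(−(t − t_pbs)·kd)`, both the closed-form solutions
of `dG/dt = ka·C·(Gmax − G) − kd·G`; the test suite verifies them
against direct ODE integration to 1e-8. Fitting is global nonlinear
least squares (Levenberg–Marquardt on log-rates) sharing ka, kd and Gmax
across the concentration ladder — the default for identifiability; a
per-curve mode exists. Initialization: kd from a log-linear fit of the
dissociation tails, Gmax from the largest observed plateau ×1.5, ka by a
coarse log-spaced scan. 95% intervals come from the Jacobian at the
solution on the log-parameter scale. Residuals are unweighted; no
mass-transport term is modeled (the measurement geometry, ROIs parallel
to the flow, reduces it physically). Mass concentrations convert to
molarity with a configurable molecular weight, default 150 kDa
(IgG-class), so 0.15625 µg/mL ≈ 1.04 nM. Multi-ROI analysis fits each
ROI's sensorgram separately and summarizes the per-ROI KD by geometric
mean and geometric SD, `exp(sd(ln KD))`.

## Problem sizes and tolerances

Defaults in the surrogate experiments: 128×128 frames, 60-frame noise
stacks, 10-seed replicate studies at 48×48 × 10 frames for ordering
properties, glycerol ladders at shortened 5–10 s holds, kinetics ladders
at 0.5–1 s sampling over single association/dissociation cycles — sizes
chosen so a complete run of the suite and the reproduction script stays
in the minutes range on a single core while keeping the statistics
meaningful (ROI-mean SD estimates at these sizes carry ~10% sampling
error, which the tolerances reflect). Key numerical tolerances: Fresnel
recursion vs characteristic-matrix oracle 1e-12; closed-form vs
Jones-product intensities 1e-12; forward/inverse 4-D transform identity
1e-10; forward/extract phase round trip 1e-9; kinetics closed forms vs
ODE 1e-8.

## Known limitations

* No spatial flow/mass-transport modeling, no thermal drift, no lateral
  registration errors; synthetic fields are flat or smoothly graded, so
  texture-dependent denoiser behavior (match quality on real structure)
  is not exercised.
* The arccos-branch readout is single-branch by design; protocols whose
  phase would cross 0 or π are out of range.
* Absolute sensitivities and resonance positions depend on metal optical
  constants and the chosen angle; they are configurable inputs, not
  predictions.
* The Wiener refinement's flat-field ROI-mean limitation described
  above.
* The noise model folds shot noise into a signal-independent Gaussian;
  strongly exposure-varying protocols would need a Poisson branch.
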