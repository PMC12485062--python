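# Methods

This note documents the models, defaults and numerical choices behind
`specdim`, and what its synthetic data do and do not establish about real
instruments.

## Emitter and motion model

Motion is isotropic Brownian diffusion on a fixed grid: per-axis increments
are independent Gaussians with variance `2 D dt`, plus an optional constant
drift; there is no inertial term and no anomalous-diffusion model. The
photon-physics step defaults to 10 µs; a coarser step may be configured for
long runs, which leaves the per-update count statistics unchanged because
emission is integrated per step.

Emission is an inhomogeneous Poisson process with rate
`peak_rate · G(r_emitter − r_focus) + background_rate`, where `G` is a
separable Gaussian excitation volume with 1/e² radii `w_xy = 0.5 µm`
laterally and `w_z = 1.0 µm` axially (typical high-NA confocal values; the
radii are free parameters of the simulator). `peak_rate` plays the role of
the photon count rate a single-photon detector would report with the
emitter centered, and is a free parameter — the mapping from excitation
power to emission rate is fluorophore-specific and not modeled. Blinking is
a two-state telegraph process and bleaching a one-way exponential clock;
both default off.

Spectra are Gaussian emission profiles (static, drifting, stepping, or a
time-weighted mixture). Each detected photon (or photon bin) may carry one
wavelength draw from the spectrum at its detection time.

## Target-locking loop

The focus visits a centered 5×5 lateral grid (0.25 µm pitch) in a
non-adjacent ("knight's-tour-like") order so consecutive dwells do not
sample neighbouring lattice points; for grids where no such tour exists
(3×3) the order falls back to a row scan with a logged warning. The axial
focus oscillates sinusoidally with 0.5 µm amplitude.

The axial modulation frequency defaults to 68.317 kHz. The value is chosen
deliberately *incommensurate* with both the 10 µs physics step and the
1 ms feedback period: a frequency that divides the dwell clock evenly
(e.g. exactly 70 kHz) pins the same few axial phases to each lateral dwell
forever, and the resulting correlation between lateral weighting and axial
offset biases the axial centroid estimate by tens of nanometers. A
free-running TAG lens is also the physically realistic situation — it is
not phase-locked to the deflector clock.

Every feedback period (default 1 ms, covering one full scan cycle) the
counts per scan sample are turned into a deviation estimate:

- **centroid** (default): background-corrected photon-weighted mean of the
  3D sample offsets, `Σnᵢsᵢ/Σnᵢ`. On a symmetric grid this is unbiased at
  the center with a shrinkage factor ≈0.92 laterally for the default
  geometry, which the unit loop gain absorbs.
- **max_likelihood**: maximizes the multinomial log-likelihood
  `Σnᵢ log pᵢ(δ)` with `pᵢ ∝ G(sᵢ−δ)+β` by a coarse grid search refined
  with Nelder–Mead. The normalization term `−N log Σⱼ(G(sⱼ−δ)+β)` matters:
  without it the estimate is pulled toward scan-dense regions
  (≈100 nm axial bias in the default geometry). Estimates are clipped to
  the scanned region, where they are meaningful.

Updates with fewer than `min_photons_per_update` (10) photons hold the
last stage position. The commanded stage position is
`stage + gain·δ̂` (gain 1.0) filtered through a first-order lag with a 2 ms
time constant standing in for the piezo response. A run ends with
`locked = False` once the emitter–focus distance exceeds 3·`w_xy`
(1.5 µm) for longer than a 100 ms grace period; loss-of-lock has no
standard definition, so both numbers are explicit configuration.

The recorded "trajectory" deliverable is the **stage position series**, as
in the physical instrument; the true emitter path is retained as ground
truth. Consequence for analysis: the stage is a low-passed copy of the
motion, so an MSD fit to the recorded trajectory of a fast emitter
(2.67 µm²/s at a 2 ms stage time constant) underestimates D by ~10–15% at
short lags. This is a property of the measurement, not of the estimator —
the same fit applied to the true path recovers D to within sampling error,
which is what the diffusion-recovery checks assert.

## Spectral camera

Detected photons split binomially between the reference and spectral
channels (default 0.7 to the spectral side, emulating a 30/70 splitter).
The reference channel images the emitter as a Gaussian spot (σ = 2 px) at
the position offset projected at 100 nm/px; each spectral photon lands at
the reference column plus a prism shift `Δp(λ) = c₀ + c₁λ + c₂λ²`,
defaults spanning ~120 columns over 450–750 nm with prism-like
nonlinearity (0.55 px/nm in the blue falling to 0.25 px/nm in the red,
zero shift at 600 nm so the stripe straddles the reference column).

Photoelectrons pass the EM register modeled as Gamma(n, gain) — the
standard approximation to the multi-stage avalanche cascade, reproducing
the excess-noise factor of 2 — then Gaussian read noise (3 e⁻ RMS) and a
100-count baseline, clipped to 16 bits. The default EM gain of 60 with the
2 px PSF keeps the brightest stripe pixel below the 16-bit ceiling at
10⁵ photons/frame while still swamping read noise at 10³; at gain 100 the
stripe saturates above ~5·10⁴ photons and the apparent precision floor is
set by clipping, exactly as on a real camera driven too hard.

Frame timing is `period = exposure + overhead` with the overhead default
1.5528 ms chosen so the zero-exposure limit `1/overhead` reproduces the
644 fps single-stripe maximum; a printed overhead of "1.55 ms" is treated
as that value rounded.

## Calibration and profile extraction

Calibration renders monochromatic frames at six known wavelengths,
registers the stripe against the reference spot by background-subtracted
center of mass, and fits the degree-2 shift polynomial; monotonicity over
the band is enforced and wavelength residuals (typically <0.1 nm RMS at
2·10⁵ photons) are reported. Center-of-mass registration is used rather
than cross-correlation because the stripe is not a translated copy of the
spot. Spot centroids are computed in a window around the brightest pixel:
a whole-frame centroid is dragged toward the image center by
positively-clipped read noise, which added a ~0.15 nm wavelength jitter
floor before windowing.

Per-frame profiles subtract the median of four 10×10 corner blocks, sum
the stripe rows per column, divide by the local nm-per-column Jacobian of
the dispersion, and resample to a uniform 1 nm grid anchored at the
reference-spot centroid. Peak localization is nonlinear least squares of a
four-parameter Gaussian; the scale-free fit error is RMSE/amplitude, so
the 0.3 QC cutoff applies across brightness levels. QC additionally
requires the central 5×5 mean of the position image to exceed 2× the
corner background. Precision is the raw standard deviation of the fitted
peak over QC-passed frames (no drift correction).

The optional learned localizer is a small ridge regression from
normalized profiles to peak wavelengths, trained on simulator output. It
is a plug-in interface with deterministic inference and a mandatory
fallback to Gaussian fitting; on high-photon synthetic stripes it matches
the Gaussian fit's spread. It makes no claim about transformer-based
localizers on real data.

## Unmixing and pH

Reference spectra are unit-sum normalized columns, so unmixing
coefficients are directly comparable intensity contributions. The default
three-component set emulates a yellow pH-sensitive protein (548/20 nm), an
orange pH-stable dye (580/30 nm) and a deep-red lysosome marker
(670/20 nm): Gaussian stand-ins placed from the dyes' published emission
regions with realistic overlap across the default 500–570 / 570–640 nm
split bands. OLS is computed by QR-based `lstsq` and is required (and
tested) to match the normal-equation formula to 1e-8 on well-conditioned
inputs; the condition number of `SᵀS` is reported and bounded. When
unmixing camera-derived profiles, the reference set uses the emission
widths convolved with the stripe PSF expressed in nm — unmixing against
the unblurred spectra leaves a small but systematic residual.

The pH calibration is a logistic (Henderson–Hasselbalch-form) curve with
R_min = 0.2, R_max = 2.5, pKa = 5.5. No published calibration curve is
available for the probe pair, so the same curve serves as forward model
(simulation) and inverse (analysis): the testable claim is *parameter
recovery and the crosstalk contrast*, not absolute pH. At a true pH of 4.5
the unmixed pipeline recovers 4.5 within ±0.2 while the wavelength-split
ratio, inflated by the pH-stable dye's leakage into the short band, reads
≈5.2 — biased toward neutral, the qualitative failure mode spectral
unmixing corrects.

## Trajectory and kinetics analysis

MSD uses all overlapping pairs; the default diffusion fit is a
count-weighted line over lags 1–10 with an intercept absorbing static
localization noise. Stokes–Einstein conversion takes temperature and
viscosity as explicit arguments; the worked example uses T = 296 K,
η = 0.183 Pa·s (90 wt% glycerol near room temperature) with
D = 2.67 µm²/s, giving d ≈ 0.89 nm.

Windowed kinetics use non-overlapping 60 s windows on the stage
trajectory: vertical speed `|Δz|/T`, translational speed `‖Δxy‖/T`
(µm/min), signed vertical displacement, planar displacement projected on
the first window's motion direction (the sign convention must be stated
because a signed planar displacement is otherwise ambiguous), and the
spectral change rate as the within-window linear regression slope of
λ(t) in nm/min. Displacement-based speeds and MSD-based diffusion
coefficients are distinct quantities and are labeled distinctly.

Switch detection uses a sliding two-window mean difference with threshold
`max(min_jump, 3·pooled std·√(2/window))`, merging detections within one
window; a linear drift below `min_jump` per window is not a switch. The
detector is validated against an exhaustive two-segment mean-split oracle
at small n.

Onset kinetics fit `y = a(1−e^{−bx})` to the empirical cumulative onset
fraction (events / tracks observed, censored at the observation span)
evaluated on a uniform 200-point time grid — evaluating at event times
only over-weights the early rise and inflates the variance of b̂. The half
time is `−ln(1−0.5/a)/b`, defined only for a > 0.5. At n = 200 tracks the
sampling error of b̂ is ~5–7%, so recovery checks compare medians over
replicate cohorts rather than a single draw.

## Volume reconstruction

Each photon is registered to `stage(t) + lateral scan offset +
axial TAG offset(t)` and binned into 50 nm voxels on a grid auto-sized to
the stage excursion plus scan margins. Photons outside the grid go to an
overflow counter so `Σ counts + overflow = N` holds as an exact integer
identity. Dwell-time normalization is available but off by default (raw
counts are displayed with intensity coding). A spherical-shell phantom is
recovered with its radius correct to one voxel.

## Synchronization

Camera frames are mapped to tracking samples by exposure windows
`(t_start, t_start + exposure]`; tracking samples are stamped at the end
of each feedback period, so with a 1 ms exposure and 1.55 ms overhead each
frame covers exactly one sample. Gap frames (e.g. brightfield
interruptions) are forward-filled from the last valid spectral value on
request.

## Problem sizes and determinism

Default test and acceptance problem sizes — 6 s tracking runs at a 10 µs
physics step, 50–100 frames per photon budget, 50 seeds for diffusion
recovery, 20 seeds per locking arm, 2·10⁴ photons per phantom — were
chosen so the statistical checks have comfortable margins while the whole
suite runs in well under a minute per module. All randomness flows from a
single master seed split per sub-process; fixtures are byte-reproducible.

## What the synthetic data do not show

The simulator establishes the correctness and statistical behavior of the
estimators, not instrument performance. It omits optical aberrations,
field-dependent dispersion, chromatic PSF variation, clock-induced charge
and pixel non-uniformity, piezo dynamics beyond a first-order lag,
hardware latency and real fluorophore photophysics beyond telegraph
blinking. Published instrument-level numbers (nanometer-scale spectral
precision on real beads, live-cell pH values and organelle speeds) depend
on the physical system and trained learned models, and are used here only
as scale references for the synthetic generators — passing tests show the
pipeline recovers its own ground truth at matched photon budgets, nothing
more.
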