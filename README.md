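# specdim

Simulation and analysis toolkit for **3D target-locking single-molecule
spectral dynamics imaging** — active-feedback single-particle tracking
combined with a prism-dispersed spectral camera.

In this imaging mode, a laser focus is scanned rapidly around a moving
emitter (electro-optic deflectors laterally, a tunable acoustic gradient
lens axially). Photon counts collected at each scan offset yield an
estimate of the emitter's deviation from the focus center, and a piezo
stage is driven to cancel it, locking the emitter in the excitation volume
while its 3D trajectory is recorded at kilohertz rates. A fraction of the
fluorescence is dispersed by a prism onto an EMCCD as a single spectral
stripe, so the full emission spectrum is captured in synchrony with the
position — enabling spectrally resolved tracking, unmixed ratiometric
imaging (e.g. pH), and photon-registered 3D volume reconstruction.

`specdim` implements the computational core of such an instrument as a
simulator plus analysis pipeline, with no hardware or external data
required. It is aimed at instrument builders and analysts who want to
prototype estimators, quantify precision budgets, or validate analysis
code against known ground truth.

## The models at the core

- **Tracking loop** — Brownian motion (per-axis increments
  `N(0, 2 D dt)`), Poisson photon emission modulated by a separable
  Gaussian excitation volume
  `G(r) = exp(-2(x²+y²)/w_xy²) · exp(-2z²/w_z²)`, photon-weighted-centroid
  or maximum-likelihood deviation estimation each feedback period, and a
  first-order-lag stage update.
- **Spectral camera** — photons split 30/70 between a reference spot and a
  prism stripe; pixel shift `Δp(λ) = c₀ + c₁λ + c₂λ²`; EM gain as a Gamma
  cascade (excess-noise factor 2), Gaussian read noise, 16-bit output.
  Frame period = exposure + overhead (1.5528 ms readout ⇒ ≈644 fps limit).
- **Peak localization** — Gaussian fit `A·exp(−(λ−μ)²/2σ²)+b` to each
  extracted profile; precision = std of `μ` across frames; QC drops frames
  with weak central signal or fit error (RMSE/A) above 0.3.
- **Unmixing** — `M = S·C + E` solved by least squares
  `C = (SᵀS)⁻¹SᵀM` (QR-stable, optional non-negativity); component ratios
  map to pH through a logistic calibration
  `pH = pKa − log₁₀((R_max−R)/(R−R_min))`.
- **Trajectory analysis** — time-averaged MSD with `MSD(τ) = 6Dτ` fits,
  Stokes–Einstein sizing `d = k_BT/(3πηD)`, 60-s-window speeds and
  spectral change rates, two-window change-point detection, and
  saturating-exponential onset kinetics `y = a(1−e^{−bx})`.

## Worked example

Simulate a single far-red fluorophore (emission peak 647 nm) diffusing at
2.67 µm²/s, tracked for 6 s with 100 ms spectral exposures, then analyze
the frames:

```bash
specdim simulate --preset fig2 --out demo --seed 7
# wrote fixture with 59 frames to demo
specdim spectra --preset fig2 --inputs demo --out demo_spec
# {"n_frames": 59, "n_passed": 59, "precision_nm": 0.260..., "mean_peak_nm": 646.99...}
specdim analyze --preset fig2 --inputs demo --out demo_an
# {"D_um2_s": 2.22..., "D_stderr": 0.056..., "intercept_um2": -0.016..., "hydrodynamic_diameter_nm": 1.06...}
```

Reading the numbers: all 59 frames pass quality control; the fitted peak
wavelength averages 647.0 nm with a frame-to-frame standard deviation
(spectral localization precision) of 0.26 nm at roughly 10⁵ photons per
frame. The diffusion coefficient fitted to the *recorded* (stage)
trajectory, 2.22 µm²/s, sits below the true 2.67 µm²/s because the piezo
lag low-passes the fastest motion — a real property of the recorded
trajectory that the methods note discusses; fitting the ground-truth
trajectory in `demo/tracking_record.csv` returns 2.68 µm²/s. In Python the
same example is three calls: `generate_fixture`, `extract_profile` +
`fit_peak_gaussian` per frame, and `fit_diffusion(compute_msd(...))`.

The Stokes–Einstein worked example is one call:

```python
>>> from specdim import stokes_einstein_diameter
>>> stokes_einstein_diameter(2.67, temperature=296.0, viscosity=0.183)
0.887...   # nm — a single-fluorophore-sized emitter
```

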