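# Methods

This note documents the models behind `nanosolder`, the defaults they ship
with, and what the synthetic test conditions do and do not demonstrate.

## Ratiometric Boltzmann thermometry

Nd³⁺-doped nanothermometers (e.g. BiVO₄:Nd³⁺) emit from two thermally
coupled levels, producing NIR peaks near 820 and 870 nm. The relative
population of the levels follows a Boltzmann factor, so the band-integrated
fluorescence intensity ratio obeys

    ln(FIR) = a + b / T,    FIR = Σ I(λ), λ ∈ [790, 840) nm  /  Σ I(λ), λ ∈ [840, 945] nm

with `T` in kelvin. The integration bands follow the characterization
protocol (790–840 and 840–945 nm); the shared 840 nm boundary is assigned
to the second band — a deterministic tie-break, immaterial beyond band
edges because the ratio is scale-invariant. Band integration is a plain
sample sum on the uniform wavelength grid (counts semantics of a
spectrometer); trapezoid integration would differ only at band edges and
cancels in the ratio.

**Units of the slope.** `b` multiplies `1/T`, so it carries kelvin. The
shipped defaults are `a = 1.33`, `b = −1320 K`, consistent with the
~700 cm⁻¹ level splitting of the Nd³⁺ 820/870 nm emission
(ΔE/k_B ≈ 1.0×10³ K). A slope printed as "−1.32 K⁻¹" elsewhere is read as
−1.32×10³ K; both constants are configurable. The calibration fit is
ordinary least squares of ln(FIR) on 1/T, exact on noiseless model data;
inversion is `T = b / (ln FIR − a)` with a pole at `ln FIR = a` and a
warning (never an error) outside the fitted temperature range.

**Synthetic emission database.** No measured spectra are distributed, so
the package synthesizes a stand-in database: two Gaussian peaks (centers
820/870 nm, σ = 8 nm — 50 nm apart, beyond the >40 nm separation dichroics
need), with the 820-peak amplitude solved per node so the band ratio equals
the Boltzmann model *exactly* (cross-band Gaussian tails are accounted for
in the solve). Default nodes follow the measurement protocol, 30–80 °C in
10 °C steps; rendering and plant simulation use wider node ranges
(15–120 °C, 5 °C steps) generated from the same law so every simulated
temperature is interpolable. Spectra between nodes interpolate linearly per
wavelength, mirroring the linear expansion used to densify a measured
database. The optional 1064 nm peak is excluded from both bands and is off
by default (its temperature dependence is not modeled).

## Forward model of fiber-collected fluorescence

The spectrum collected by a fiber above a laser-excited fluorescent surface
is a weighted pixel sum

    I(λ) = Σ_i I_i(λ, T_i) · P_i · F_i · c_i

- `P_i`: normalized beam irradiance. Gaussian TEM₀₀:
  `exp(−2r²/w(z)²)` with `w(z) = w₀·sqrt(1 + (z/z_R)²)`; the beam quality
  factor enters through the Rayleigh range `z_R = π w₀²/(m λ)` — the
  shortest standard propagation law consistent with paraxial beam optics
  for a multimode (m = 8) beam. Top-hat: 1 inside `w(z)`, 0 outside.
  Defaults: w₀ = 1.5 mm, m = 8, z = 10 mm, λ = 750 nm.
- `F_i`: fraction of the pixel's emission accepted by the fiber,
  `A_core·cosθ/(4π d²)` inside the acceptance cone `θ ≤ arcsin(NA)`, zero
  outside, normalized to a unit maximum. The cosθ obliquity factor is a
  design choice (a pure solid-angle form differs by <2% inside the NA 0.22
  cone). Defaults: NA 0.22, core ⌀200 µm, standoff 1 mm, axis normal to
  the surface.
- `c_i`: nanothermometer concentration in [0, 1], uniform 1 by default.

Because emission interpolates linearly between database nodes, the pixel
sum collapses to per-node coefficients (one `bincount` plus a small
matrix–vector product), which keeps full-grid simulation at ~20 ms per
5×5 scan. An important structural property follows directly: for a
spatially uniform temperature the weights cancel in the band ratio, so the
simulated FIR equals the database FIR exactly — the basis of several
round-trip tests — and any mixture's FIR is bracketed by the FIRs of its
contributing pixels.

Detector noise rescales the spectrum to a peak count level (default 2000
counts), Poisson-samples each wavelength bin, adds Gaussian read noise
(σ = 5 counts) and clips at zero. At the default level this produces
~1.3 °C single-read temperature noise, a realistic figure for a compact
NIR spectrometer at 500 ms integration.

## Temperature fields and the training set

Laser-heated solder paste develops smooth bell-shaped temperature
profiles; the generator emulates them with rotated separable skew-normal
surfaces `s(u) = φ(u/σ)·Φ(a·u/σ)` per principal axis, peak-normalized on
the grid so the hottest pixel is exactly `T_max` and the far field relaxes
to `T_min`. The skew-normal form is a choice — "skewed Gaussian" fixes no
unique formula — and its parameters span: centers ±1 mm (step 0.5), widths
0.5–1.1 mm (step 0.2; width values printed as 5–11×10⁻⁴ mm elsewhere are
read as 10⁻⁴ m, the only physically plausible scale for mm-size fields),
x-skewness {−2, 2}, y-skewness 0, rotation 0–90° (step 15°), peak
temperature 40–90 °C (step 5), baseline drawn uniformly from
[20 °C, T_max − 1]. The full Cartesian grid has 61,600 combinations; the
default dataset is a T_max-stratified random subsample rendered until
5,000 samples survive filtering (the full grid is available by flag).

Each sample pairs a 5×5 "measured" image — the forward model evaluated at
25 fiber positions, 500 µm apart, with noise, FIR→temperature inverted per
position — with a 20×20 target, the block-mean of the true field over the
shared, centered 2.5 mm × 2.5 mm field of view (each fiber maps to a 4×4
target block). The simulation grid is 128×96 pixels over 4.0 mm × 3.0 mm
(31.25 µm pitch) — a desk-scale resolution choice; the 640×480 camera grid
remains available through `GridSpec`.

**SSIM filter.** Samples whose low-resolution observation carries too
little information about the target are discarded: SSIM between the
nearest-neighbor-upsampled input and the target (both affine-normalized
over a fixed 20–90 °C range, uniform 7×7 window — 20×20 images are too
small for the default window 11) must reach 0.7. Which two images enter
the published 0.7 cutoff is not specified anywhere; this comparand is the
package's recorded interpretation. Under the default noise level ~96% of
rendered samples pass, so filtered-count bookkeeping is exercised through
conservation and monotonicity properties rather than any particular count.

## The ×4 upscaling network

Fully convolutional: 3×3 'same' convolutions with channel widths
1→64→64→32→1, PReLU activations (one learnable slope per layer, init
0.25), nearest-neighbor ×2 upsampling between layers 2–3 and 3–4, linear
output head. Widths and optimizer are not dictated by the architecture
sketch this follows; (64, 64, 32) with Adam at the conventional 10⁻³
learning rate are the shipped choices, all configurable. The network is
implemented directly on numpy (im2col convolutions in channels-last
layout, float32), with every gradient — including the SSIM loss — verified
against central finite differences in the test suite.

**Loss.** `1 − SSIM` on normalized images, uniform 7×7 window, standard
constants (K₁ = 0.01, K₂ = 0.03, dynamic range 1), sample covariance,
interior windows only — numerically identical to
`skimage.metrics.structural_similarity`, which serves as the independent
oracle in tests and in evaluation. Normalization is the fixed affine map
(T − 20)/70 over 20–90 °C, not per-image, so the absolute temperature
scale survives reconstruction; outputs are clamped to 15–100 °C at
inference only.

Two optimization details matter and are documented because SSIM is an
unusual objective: (i) SSIM is blind to a joint sign flip — an
anti-correlated, mean-mirrored reconstruction scores like the true one
through the product of two negative terms — so training runs a 2-epoch MSE
warm-up and initializes the output bias at mid-range to anchor the
positive-correlation basin; (ii) the loss is evaluated on interior windows
(14×14 of them for 20×20 images), matching the oracle's edge cropping.

**Profiles.** Desk-scale default: 5,000 filtered samples, 100 epochs,
batch 256. The full-scale profile (300 epochs, batch 500, full grid) is a
constructor call away (`TrainingConfig.full_scale()`); validation-loss
curves there are reported to flatten around 250–300 epochs, and early
stopping is deliberately off by default. Splits: 25% test hold-out, then
80/20 train/validation, all drawn once from the seed; training is
bit-reproducible per seed. Evaluation reports SSIM and PSNR on normalized
images (whether published PSNR figures use normalized or °C images is
unstated; normalized is the recorded choice) and ΔT_max = |max(target) −
max(reconstruction)| in °C.

**What passing shows.** The held-out metrics (SSIM ≥ 0.85,
ΔT_max ≤ 2.6 °C at the defaults) are a synthetic analog of an experimental
validation: train and test samples come from the same generator, so they
demonstrate that the architecture and training recipe recover temperature
fields from 25-point observations under the stated noise — not that the
network transfers to real cameras, real pastes, or profile shapes outside
the skew-normal family.

## Closed-loop power control

The controller follows the soldering workflow: measure a background
spectrum (refreshed every 100 iterations), start at the minimum power
(default 20%), then each acquisition (default 500 ms, the loop period):
background-subtract, check the paste is present (peak background-subtracted
counts in 790–945 nm ≥ 150), convert FIR to temperature, and update a
discrete PID:

- derivative acts on the measurement, not the error (no setpoint kick),
  and its memory clears across off-paste gaps;
- anti-windup combines back-calculation (while the output saturates in the
  error's direction, the integrator is driven toward the value that would
  just produce the clamped output, time constant 2 s) with a hard clamp of
  the integrator to the output range — so integral action stored before a
  gap is dumped during the reentry transient instead of carried into
  overshoot;
- off paste, the power drops to the configured minimum/safe level and the
  integrator freezes. The 20% "minimum power" and the 15% "safe level"
  are modeled as one configurable parameter with two presets.

**Simulated plant.** The real loop closes on hardware, so a stand-in plant
is required and invented here: first-order lag
`dT/dt = (K(d)·u − (T − ambient))/τ` with inverse-square distance gain
`K(d) = K₀(d₀/d)²`, advanced by its exact discretization. Defaults:
K₀ = 80 °C at full power and d₀ = 10 mm, τ = 3 s, ambient 25 °C (37 °C
in-vivo preset), fluorescence peak counts 40,000·u·(d₀/d)² on paste (zero
off paste) over a flat 30-count background, with shot + read noise. At
the working point this yields ~0.5 °C measurement noise. Note K(15 mm) ≈
36 °C: setpoints above ~60 °C are physically unreachable at 15 mm, which
the distance-robustness tests respect by using lower setpoints.

**Gains.** No published gain values exist to compare against; the shipped
preset `reference-plant-v1` (kp = 0.04 /°C, ki = 0.03 /(°C·s), kd = 0) was
tuned heuristically on the reference plant against the stated requirements
— stability in all scenarios, overshoot < 5 °C, T90 < 20 s, setpoint
reached in < 10 s — and holds them across seeds and setpoints 60–80 °C
(worst observed: overshoot ≈ 3.8 °C, rise ≈ 4.5 s, T90 ≈ 4 s). The
derivative is left at zero because at the 2 Hz loop rate its
noise amplification outweighed its damping benefit on this plant.

**Moving scan.** The scan scenario moves the head at constant speed
(default 2 mm/min) over paste segments separated by gaps; each fresh
segment starts as a new cold plant, gaps emit background only (reduced
residual heating gain 0.1·K₀ models weak tissue absorption), and the trace
records position. Over gaps the commanded power equals the safe level at
every sample; on segments the setpoint band (±2 °C, a recorded choice) is
restored well before the segment ends at default lengths.

## Dual-channel ratiometric imaging

Processing chain for two-camera frames of the two peaks: background
subtraction (mean of a signal-free region or a scalar), integer-pixel
manual alignment of the 870-channel (no automatic registration, mirroring
manual alignment practice), counts → rates via `counts/(10^(gain_dB/20) ×
acquisition_time)` (the dB convention with linear factor 10^(dB/20) is an
assumption; only "gains set carefully" is stated), Gaussian blur of σ = 7
px on each channel *before* the ratio — blurring the ratio instead would
amplify division noise where the denominator is dim, and the published
order of operations is ambiguous — then `FIR = k·r₈₂₀/r₈₇₀` with a single
scalar system factor `k` absorbing filter inefficiencies and residual
1064 nm leakage (k = 1 for the synthetic fixture, which is built
inverse-consistent with the chain). Pixels with blurred 820-channel counts
≤ 15 (threshold evaluated post-blur, also a recorded choice) or zero
870-rate are masked to 0 ("dark"). FIR inverts to temperature per pixel;
inversions failing or landing outside the 20–80 °C display range
invalidate the pixel rather than raising. Composite soldering-path maps
average all valid in-range measurements per physical location, with
positions converted to integer pixel offsets via the shared pixel pitch.

## Numerical choices and degenerate inputs

- All randomness flows through explicitly passed `numpy` Generators; CLI
  commands derive per-stage seeds from one `--seed` via `SeedSequence`.
- Zero-weight forward sums produce a zero spectrum; the FIR then raises a
  dedicated undefined-ratio error rather than dividing by zero.
- `sample_tmin` requires T_max > 21 °C so [20, T_max − 1] is nonempty.
- Temperatures are kelvin internally; every user-facing surface is °C.
- Fields are validated finite; generated fields lie in [15, 95] °C by
  construction of the parameter grid.
- HDF5 archives carry a schema version; loading a truncated or mismatched
  file raises a schema error, never returns partial data.

## Known limitations

- The emission database, thermal plant, and camera frames are synthetic
  stand-ins; no claim is made about quantitative agreement with a specific
  instrument.
- Heat diffusion is not simulated: fields are prescribed, not evolved, and
  the plant is zero-dimensional.
- Photobleaching, excitation-dependent lineshape changes, tissue
  scattering, and fiber-bundle honeycomb artifacts beyond Gaussian blur
  are out of scope.
- The published dataset counts (38,947 rendered / 28,937 kept) are not
  reproducible from the stated parameter grid (its Cartesian product is
  61,600 and the filter comparand is unspecified); the package exercises
  the filter through conservation and monotonicity properties instead.
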