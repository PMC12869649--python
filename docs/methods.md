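# Methods

`qrai` models the physics of radiation-induced acoustics end to end: dose
deposition to initial pressure, wave propagation to a transducer array,
system-specific signal distortion (the digital twin), time-reversal
inversion, learned enhancement with an embedded physics operator, and
single-point calibration back to absolute dose. This note records the models,
their assumptions, the defaults that matter, and the numerical choices.

## Physical model

Under thermal confinement (radiation pulse much shorter than the acoustic
transit time across the heated region), a dose deposition D(r) creates an
initial pressure

    p0(r) = Γ · η_th · D(r) · ρ       [Gy · kg/m³ → Pa]

with Γ the Grüneisen parameter (water ≈ 0.11 at room temperature), η_th the
fraction of absorbed dose converted to heat (default 1), and ρ the density.
The pressure then obeys the lossless wave equation with spatially varying
sound speed c(r). Shear waves, nonlinearity and thermal diffusion are outside
the model; acoustic attenuation is assumed negligible by default, with a
crude frequency-independent absorption option (power-law coefficient
evaluated at a fixed reference frequency) for sensitivity studies only.

### Wave solver

`WaveSolver` integrates the first-order coupled pressure–velocity system with
a k-space pseudospectral scheme on a staggered grid: spectral derivatives
carry the temporal correction factor sinc(c_ref·|k|·dt/2) with
c_ref = max c, which makes propagation in a homogeneous medium
dispersion-free at any time step; heterogeneous media incur the usual
O(Δc/c) k-space error. The pressure field is split per axis and damped
inside a perfectly matched layer (default 10 voxels, quartic absorption
ramp, strength 2 in units of c_max/Δx). A plain damping sponge was measured
to reflect 15–40% of incident amplitude regardless of taper — the classic
sponge failure — which is why the split-field PML is used. Zero initial
particle velocity encodes the impulsive (thermal-confinement) source; the
first staggered velocity update uses dt/2 so the discrete initial condition
is exactly zero velocity at t = 0.

Defaults: CFL 0.3 (auto-derived dt; a user-pinned dt above the stability
bound raises with the maximum stable value printed). Sensors snap to the
nearest voxel centre. The radiation-pulse convolution is applied downstream
in the twin module, not inside the solver.

Verification: for any spherically symmetric p0 = φ(|x|) in a homogeneous
medium the detected signal at distance r is exactly
p(t) = (r − c t)·φ(|r − c t|)/(2r). For a uniform sphere this is the classic
bipolar N-wave (`analytic_sphere_signal`); for a Gaussian-regularized sphere
(ball ⊛ Gaussian, erf closed form) it is `analytic_smoothed_sphere_signal`.
The solver is gated at ≤ 2% relative L2 against the regularized closed form
for radii of 2–6 voxels. The comparison uses the regularized source because
a discontinuous sphere edge lies outside the band any grid can represent:
against the sharp N-wave the irreducible spectral-truncation error at those
radii is 25–40% (and still 4–12% after identical band-limiting of both
signals), none of which measures solver quality. The detector is kept ≥ 6
voxels clear of the PML; placing it 2 voxels away was measured to add ~3%
contamination.

### Adjoint

Every stage of the scheme (diagonal damping, spectral staggered derivatives,
sensor sampling) is linear, and `record_adjoint` applies the exact transpose
of the recording map by reversing the recursion; the transpose of the
forward staggered derivative is the negated backward one. The pairing is
verified by dot-product tests and elementwise against explicitly assembled
matrices on small grids. This exact adjoint is what propagates
sinogram-domain gradients to the image domain during training — no surrogate
or approximate backward model is involved.

## Synthetic beams

Parametric stand-ins for a Monte Carlo or treatment-planning dose engine;
only the features the acoustics and metrics are sensitive to are modeled.

- **Proton pencil beam**: depth dose = rising entrance plateau (0.35→0.51 of
  peak) + Gaussian peak at the range R = α·E^p (water defaults
  α = 0.0022 cm·MeV⁻ᵖ, p = 1.77), peak width from range straggling
  (1.2% of R, floored at 1.5 voxels), distal erfc cut of width
  `distal_sigma` (default 3 mm); lateral Gaussian (default σ 3 mm). The
  volume maximum equals `fluence_scale` (Gy per pulse). The Bragg-peak
  argmax lands within one voxel of R across the clinical energy range.
- **FLASH electron field**: smoothstep build-up from the surface-dose
  fraction, plateau, sigmoid distal falloff crossing 50% of the maximum at
  r50 (build-up ends at 0.4·r50 and the sigmoid width is 0.08·r50, so the
  50% crossing is exact to ~1%); lateral erf-smoothed top-hat of the
  collimator size. 1 Gy in 1 µs per pulse equals an instantaneous dose rate
  of 10⁶ Gy/s; with a 750 Hz proton pulse train and 10-pulse averaging the
  imaging frame rate is 75 fps.
- **Catalog**: the water-tank protocol enumerates energies × array positions
  (centre plus ±1 cm shifts on the two lateral axes for the 5-position
  layout), marks a seeded subset as excluded (emulating
  interference-corrupted acquisitions) and partitions the rest into
  train/val/test. 7 × 5 = 35 acquisitions, 2 excluded → 33 usable,
  split 20/5/8. The seven energies are not dictated by the protocol; the
  defaults span 70–130 MeV (ranges ≈ 4–12 cm in water).

## Digital twin

The measured signal is the acoustic point response distorted by three linear
system stages: convolution with the radiation pulse temporal profile
(unit-area kinds: box, Gaussian, double-Gaussian; delta = identity), a
finite-aperture sum over sub-elements (3 mm elements subdivided at 1 mm
pitch → 3×3 sub-elements, displacements symmetric about the element centre;
equal weights), and convolution with the element impulse response, modeled
as an energy-normalized damped sinusoid exp(−π f0 t/q)·sin(2π f0 t).
Defaults f0 = 1 MHz, q = 2 are placeholders for a measured response (a
user-supplied-samples kind is the escape hatch); energy normalization keeps
the overall signal scale stable under IR changes. Pulse and IR kernels
collapse into a single convolution kernel (they commute), applied per
channel with linear (truncated) convolution. Element directivity beyond the
aperture sum and electrical effects are not modeled. `TwinOperator` exposes
the composed forward map F and its exact adjoint.

## Time reversal

The sinogram is flipped in time and re-emitted from the element
(sub-element) positions through the same solver; the field at the final
reversed-time step is p_rec. Additive time-varying sources are the default
injection (a Dirichlet mode exists for comparison): with partial surface
data the exact reversed boundary-value problem is unattainable, so this
choice is explicit. No positivity clamp is applied — limited-view
reconstructions legitimately contain negative values and distorted
morphology, which is precisely what the enhancement network is trained to
remove. TR output scale is arbitrary (linear in the unknown acquisition
gain); quantitativeness is restored by calibration.

## Physics-informed enhancement

A U-Net N maps p_rec to p_pred; training minimizes
λ₁·mean|N(p_rec) − p0|² + λ₂·mean|F(N(p_rec)) − S_m|². The image term
requires a ground-truth p0 and so is available only for labeled samples;
the sinogram term is self-supervised (S_m is measured) and drives learning
on unlabeled acquisitions. Gradients of the physics term reach the network
through the exact adjoint of F: ∇ = (2/n)·Fᵀ(F(pred) − S_m), finite-
difference-verified to 1e-4 relative on 8³ grids.

Choices:
- λ₁ = 1; λ₂ auto-balanced once at the first epoch so both terms start at
  comparable magnitude (ratio gated to [0.5, 2] in tests).
- Per-sample max-normalization of p_rec, with p0 and S_m scaled by the same
  factor (all linear in it); the scale is re-applied after inference so
  predictions stay on the input's physical scale.
- Non-negative final activation (ReLU) by default — negative pressure has no
  dose interpretation; a linear mode is retained for ablation.
- The layer stack (N-dimensional convolutions, pooling, upsampling) carries
  explicit hand-written backward passes, finite-difference-verified; Adam
  (lr 1e-3) with all seeds pinned (init, batch order), so training is
  bit-reproducible given the seed.
- Network defaults: depth 3, base 8 channels, ~100k parameters in 2D.
  Input extents must divide by 2^(depth−1).

## Calibration and metrics

Single-point calibration: K = D_c/p_c at a voxel where the delivered dose is
known (the Bragg peak by default, `auto-peak`; optional 3³-neighbourhood
mean). Dose = K·p_pred in cGy, clamped at zero since negative dose is
unphysical. K is invariant to any global gain on the measurement chain.

Gamma index: global normalization to max of the reference, 3 mm / 3%
defaults, 10% low-dose threshold, exhaustive voxel search within 3×Δd, with
optional sub-voxel refinement by linear interpolation of the evaluated
volume (fine index f ↔ coarse coordinate f/refine, so reference voxels stay
exactly aligned). The fast path is tested equal to a brute-force
double-loop oracle on ≤16³ volumes; a boundary-exact voxel passes (γ ≤ 1
with 1e-9 relative slack for float roundoff). SSIM is computed from global
whole-volume statistics exactly as the single-window formula, with
c1 = (0.01·L)², c2 = (0.03·L)², L defaulting to the reference maximum
(a uniform-window local variant sits behind a flag). PSNR is
20·log₁₀(√n·max|ref|/‖test−ref‖₂), the standard peak-over-RMSE reading; a
"literal" mode uses the raw voxel count as prefactor for comparison.

## The synthetic benchmark

`qrai.benchmark` is the package's study harness: 2D water medium on a 64×64
grid of 1 mm voxels, a single 16-element linear array (3 mm pitch and
aperture, 1 mm sub-pitch) 12 voxels from the far edge, Gaussian 1 µs pulse,
1 MHz q = 2 impulse response, proton pencil beams entering opposite the
array with Bragg peaks 2.7–4.5 cm deep (55–74 MeV), peak dose 1.72 cGy per
pulse, and 2% Gaussian measurement noise on each sinogram.

The training protocol reproduces the data-scarcity regime the method
targets: 8 acquisitions of which only 4 are labeled — central-axis beams in
a narrow energy band, the acquisitions for which a reference dose
calculation would exist — while the unlabeled 4 span the full energy range
and off-centre positions. The supervised baseline can train only on the
labeled subset; the physics-informed model additionally uses the unlabeled
acquisitions through the sinogram term. Held-out beams (5) span the full
range with off-centre offsets. Both models share the architecture, seed,
learning rate and epoch budget (60 — the point where both training losses
plateau, changing by under 10% per ten epochs), so the only difference is
the physics term and the data it unlocks.

With abundant labeled in-distribution data the supervised baseline matches
the physics-informed model on this synthetic family (measured during
development); the advantage of embedding F is specific to the label-scarce,
distribution-shifted regime, which is the clinically relevant one (the
initial pressure inside a patient is never measurable). Passing the ordering
on this benchmark therefore shows the mechanism works where it is claimed
to; it does not show superiority when labels are plentiful.

The benchmark runs in 2D because the operators, network layers and metrics
are dimension-agnostic (the same code paths run in 3D and are
gradient/oracle-tested at 8³–16³); 2D keeps the full study to a few minutes
on one CPU. The end-to-end calibration check trains on the benchmark,
calibrates K at the predicted peak of one held-out beam, applies it to a
different held-out beam, and compares the recovered peak dose with the
simulated truth (gated at 15%).

What the synthetic data does not emulate: electromagnetic interference,
correlated noise, amplifier ringing, tissue heterogeneity of c/ρ/Γ,
secondary-particle dose, and 3D limited-view geometry at clinical scale.
Passing tests here demonstrates correctness of the mechanisms, not clinical
dosimetric accuracy.

## Known limitations

- Heterogeneous-medium propagation carries the standard k-space c_ref error;
  no staggered-grid density interpolation.
- The absorption option is frequency-independent (evaluated at a reference
  frequency), not a dispersive power law.
- Nearest-voxel sensor placement quantizes array geometry to the grid.
- Calibration clamps negative predictions to zero dose; with the default
  non-negative activation this is a no-op.
- The parametric impulse response is a placeholder; quantitative agreement
  with a physical system requires the measured response via the
  user-supplied-samples kind.
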