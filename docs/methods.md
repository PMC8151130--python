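# Methods

This note documents the models implemented in `fmmdsim`, the numerical
choices behind them, what the synthetic data emulates, and the known
limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physical setting

A dilute ensemble of single-domain iron-oxide nanoparticles (magnetite
constants: Ms = 476 kA/m, effective uniaxial anisotropy K = 11 kJ/m³,
density 5.2 g/cm³) with a lognormal core-diameter law — median
d0 = 7.81 nm, shape σ = 0.346, polydispersity index exp(σ²)−1 = 0.127 —
is driven by a two-tone field with static offset,
µ0H(t) = B0 + B1 sin(2πf1t) + B2 sin(2πf2t). The measurement protocol
uses B1 = 1.29 mT at f1 = 30,543 Hz, B2 = 16.4 mT at f2 = 62.95 Hz,
offsets 0–24 mT, and a sample temperature of ~318 K (coil heating); the
simulation protocol uses B1 = 1 mT at 40 kHz, B2 = 16 mT at 2 kHz at
300 K with water viscosity (8.9×10⁻⁴ Pa·s) and a 20 nm hydrodynamic
diameter. Internally every field is stored as µ0H in tesla, lengths in
meters, moments in A·m²; files quote offsets in mT/µ0.

## Equilibrium engine

The mixing component of order n for one core size is the synchronous
Fourier sum of the sampled Langevin response over exactly one
low-frequency period: reference cos(2π(f1+nf2)t) for odd n and
sin(2π(f1+nf2)t) for even n (the responses alternate between
point-symmetric and axisymmetric functions of the offset), prefactor
mp(dc)·2/k. Ensemble components integrate the per-size response over the
lognormal law; they are linear in Np.

Numerical choices:

* **Sampling grid.** 10 samples per 1/f1 with a numeric tone ratio
  f1 = 20·f2 (k = 200). The sum runs i = 0..k−1: one exact period keeps
  the tone basis orthogonal (closing the window with the duplicate
  sample t_k would bias components by up to ~0.5% at k = 200 and break
  exact orthogonality). The physical high frequency enters only through
  its amplitude; doubling the sampling density changes components by
  < 0.1% (tested), and raising the numeric ratio to the physical ~485
  leaves the signal-fraction cutoffs unchanged at the quoted precision.
* **Size quadrature.** Trapezoid in ln dc on log-spaced nodes covering
  d0·e^±6σ (801 nodes by default, > 99.9999% of the number mass; the
  signal-weighted mass decays even faster at the upper edge because the
  response saturates).
* **Langevin function.** coth ξ − 1/ξ with a 5th-order series below
  |ξ| < 10⁻² (relative error < 10⁻¹⁴ at the crossover); evaluation never
  divides by a small ξ.

## Signal-fraction analysis

`signal_fraction(dmin)` is the lognormal-restricted component integral
over [dmin, ∞) divided by the unrestricted integral, both evaluated at
the offset where |m_n| peaks on the 0–24 mT sweep (1 mT grid);
`threshold_for_signal_fraction` inverts it by bisection on the cumulative
tail profile. The published-scale analysis uses n = 1.

The evaluation offset and component order are genuinely open choices and
the result is mildly sensitive to them. Sensitivity, computed with this
package for the 90% cutoff (n = 1, peak offset 15 mT → 11.76 nm):
moving the evaluation offset across 13–20 mT shifts the cutoff between
11.81 and 10.97 nm; an RMS aggregate over the whole sweep gives
11.49 nm; pooling all four components at their peaks gives ~11.9 nm;
n = 2 at its own peak gives 12.48 nm. The peak-offset n = 1 definition
is retained as the most natural reading and the one that matches the
component whose peak position (15 mT) anchors the comparison between
engines. The 99% and 99.9% cutoffs (9.09 nm and 7.46 nm, the latter
spanning 55.2% of particles) vary by ±0.15 nm across the same
definitions.

## Stochastic Néel–Brown engine

Each particle carries a unit moment direction m (LLG dynamics,
dm/dt = γ/(1+α²)·[B_eff×m + α·m×(B_eff×m)], α = 1) and a unit easy axis
n rotating rigidly under the anisotropy torque and Brownian noise
(dn/dt = ω×n, ω = Θ/(6ηV_H)). The channels couple through
U = −mp·(m·B) − K·V_c·(m·n)²; dipole–dipole interaction is omitted —
at the data-sheet concentration (2.4 mg Fe/mL) the point-dipole pair
energy at the mean spacing is ≲ 10⁻³ kB·T (computed by
`dipole_thermal_ratio`), and the energy type keeps the term explicit as
identically zero.

* **Thermal noise.** White-noise spectral densities
  2kBT(1+α²)/(γ·mp·α) for the field term [T²·s] and 12kBT·η·V_H for the
  torque term [J²·s]; per-step Gaussians of variance density/dt.
  **Placement:** the thermal field drives the precession torque only.
  For this LLG form the fluctuation–dissipation balance requires
  S = 2kBTα(1+α²)/(γmp) for precession-only injection, which coincides
  with the density above exactly at α = 1 (the value used throughout);
  injecting the same noise into both LLG torques would instead thermalize
  the moments at an effective temperature (1+α²)/α²·T — a factor 2 too
  hot at α = 1. The static-field tests verify the implemented choice: the
  long-time Monte Carlo magnetization reproduces the Langevin curve at 2,
  5 and 20 mT within Monte Carlo error. With mobile easy axes this
  agreement is exact in distribution: the joint Boltzmann density
  factorizes and the moment marginal is Langevin for any K.
* **Integrator.** Stratonovich–Heun: Euler predictor with frozen noise,
  midpoint-averaged drift corrector with the same noise, then
  renormalization of m and n. Both unit norms are conserved to 10⁻⁹ over
  10⁴ deterministic steps (tested).
* **Time step.** The driven protocol's 10 ns output step under-resolves
  the precession/damping time 1/(γB) ≈ 0.1–1 ns; `n_substeps` subdivides
  each output step for the integrator. Convergence of the static-field
  magnetization against the Langevin curve sets the working resolution:
  biases are ≈ +18% of the signal at an integration step of 10⁻¹⁰ s,
  ≈ 1% at 2×10⁻¹¹ s, and below Monte Carlo error at 10⁻¹¹ s for the
  median core size (noise-rotation angle ∝ √dt; larger cores converge
  at proportionally larger steps). Defaults keep the reference protocol
  (n_substeps = 1) so that protocol-faithful runs are reproducible;
  quantitative tests state their substep choice.
* **Hydrodynamic sizes.** Only a single 20 nm hydrodynamic diameter is
  given for the 7.81 nm median core; polydisperse runs use a fixed
  nonmagnetic shell, dh = dc + (20 − 7.81) nm, an explicit modeling
  assumption.
* **Seeding.** One master seed; per-run generators derive from spawned
  seed sequences; traces are bit-reproducible for a fixed seed and
  thread count (single-threaded kernel).

## Hysteresis loops and their noise floor

`extract_loop` projects a trace onto one low-frequency period and
computes |∮M dH| (trapezoid on the closed cycle); by default all complete
periods are folded (point-wise averaged) first — the drive is periodic,
so folding suppresses Monte Carlo noise without touching the systematic
shape. The loop area is a two-bin functional of the trace (only the
quadrature components at exactly f1 and f2 contribute to ∮M dH), so its
statistical error scales as 1/√(particles × runs × periods) and cannot
be reduced by smoothing. Measured at 4000 particle-periods with a
2×10⁻¹⁰ s integration step, the zero-offset loop of the lognormal
ensemble encloses ≈ 4.3×10⁻⁵ T (per unit Ms) against a statistical floor
of ≈ 1×10⁻⁵ T, while the nominally closed 20 mT loop still encloses
≈ 3.0×10⁻⁵ T: at this step size a discretization-induced phase lag
creates spurious area wherever the magnetization swing is large, and it
masks the physical open-vs-closed contrast. Resolving a ≥10× contrast
therefore needs both integration steps ≲ 2×10⁻¹¹ s (where the
discretization lag falls below the physical Brownian lag) and
≳ 2×10⁴ particle-periods against the statistical floor — hours of
single-core compute; the in-suite check runs a documented
500-particle-period version per offset and is expected to sit at the
edge of resolvability. The relaxation-time analysis
(`relaxation_times`) independently quantifies the closure: at the median
size the effective time is Néel-dominated and of order 10⁻⁹ s, so
f·τ ≪ 1 and only the dc ≳ 20 nm tail (slower by 3–4 orders of magnitude,
Brownian-dominated) can lag the drive.

## Fitting

Pooled least squares on the real parts of all four components (imaginary
parts of measured sweeps are orders of magnitude weaker), residuals
scaled by the observed maximum (optionally per component), parameters
optimized in O(1) units (d0 in nm, σ, log10 Np) with scipy's damped
trust-region-reflective algorithm under bounds d0 ∈ [2, 30] nm,
σ ∈ [0.05, 1.5], Np log-parameterized. Np is exactly degenerate with any
multiplicative calibration, so normalized sweeps are fitted with Np
fixed. Noiseless self-generated sweeps are recovered to machine
precision (pooled R² = 1); at 1% noise on the 25-point sweep the (d0, σ)
estimator scatters by a few percent per realization with a
small-sample bias checked to stay below 2% over 20 seeded replicates.
Sparser offset grids visibly inflate the (d0, σ, Np) degeneracy and are
avoided in quantitative tests.

## Synthetic data

`generate_synthetic_sweep` emulates the measurement format: the
forward-model real components on the 0–24 mT offset grid plus additive
Gaussian noise scaled to each component's sweep maximum (a lock-in's
roughly uniform absolute noise floor), bit-reproducible per seed. It
does not emulate receive-coil transfer functions, frequency-dependent
phase shifts, background subtraction residues, or particle clustering;
passing recovery tests on it therefore validates the estimator under the
stated noise model, not the full instrument chain.

## Known limitations

* The dynamic simulations are quantitative only with refined substeps;
  at the reference protocol's raw 10 ns step the magnetization amplitude is
  systematically suppressed (the coarse-step dynamics run effectively
  hot), which is also a plausible reading of why fitting the equilibrium
  model to such simulations can return a strongly inflated width σ.
* Loop-area contrasts at realistic parameters sit close to the Monte
  Carlo noise floor at desktop scale (see above).
* Single-core, spherical, uniaxial particles; no interactions, clusters,
  surface (dead-layer) corrections, or multi-modal size laws.
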