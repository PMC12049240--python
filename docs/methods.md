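# Methods

## Model

A classical MD trajectory samples the vibrational motion of a molecule; the
Fourier transform of the autocorrelation of any observable along the
trajectory peaks at the classical frequencies that modulate it. For a
normal-mode momentum p_j(t) over total time T the time-averaged
autocorrelation is

    C_pp(t) = (1/T) ∫₀ᵀ p_j(t₀) p_j(t₀+t) dt₀ .

Because T is chosen long compared with the vibrational periods, the upper
limit of the t₀ integration can be extended to infinity with negligible
error, and the Fourier transform of C_pp collapses to the manifestly
nonnegative form

    I_j(ω) = |p̃_j(ω)|² / (2T) ,

which is what the package computes. Peak maxima of I_j locate the classical
vibrational frequencies; a mode coupled to others shows secondary peaks at
the partners' frequencies, slightly shifted because each single-mode
spectrum estimates the shared frequencies from its own projection of the
dynamics.

The normal-mode basis is built at the equilibrium geometry: the Hessian is
mass-weighted (element (i,j) divided by √(m_i m_j)), diagonalized, and the
eigenvectors with nonzero eigenvalues collected into the orthogonal matrix
C. A Cartesian trajectory is projected by P = Cᵀ m^{1/2} v. The extra
m^{1/2} weighting is applied by this package so that p_j is the momentum
conjugate to the mass-weighted normal coordinate; with it, Σ_j p_j²/2
equals the Cartesian kinetic energy Σ_i m_i v_i²/2 for motion inside the
retained subspace, and the summed normal-mode spectrum is bin-by-bin
identical to the summed spectrum of √m-weighted Cartesian velocity
components. (A velocity upload that is already mass-weighted would be
double-weighted; the convention is therefore stated here and in the
docstrings.)

The C matrix is defined at the equilibrium geometry but applied as-is along
the trajectory. Away from equilibrium this leaks a small amount of overall
rotation into the lowest-frequency modes; high-frequency bands are
unaffected. Optional Eckart alignment (mass-weighted Kabsch rotation onto
the reference geometry, fitted per frame on positions and applied to
velocities) reduces the leakage. It defaults to on when positions are
present and off for velocity-only input, and it is an optional refinement —
the unaligned projection is the baseline behavior.

## Discrete conventions

The continuous identities above fix nothing about the discretization, so
the package pins one convention and makes the textbook identities exact in
it:

* **Transform.** p̃(ω) = Δt Σₙ p(tₙ) e^{iωtₙ}, evaluated on a zero-padded
  FFT grid.
* **Normalization time.** T = NΔt — each of the N samples owns one
  sampling interval. (The `total_time` attribute of a trajectory remains
  the elapsed time (N−1)Δt; the spectral normalization uses NΔt, which is
  what makes the Parseval identity below exact rather than accurate to
  O(1/N).)
* **One-sided folding.** The reported spectrum folds the negative-frequency
  half onto positive frequencies: interior bins carry a factor 2, the ω=0
  and Nyquist bins a factor 1. Peak positions and relative intensities are
  unchanged; absolute normalization satisfies, exactly and for any padding,

      Σ_k I(ω_k) Δω / (2π) = ⟨p²⟩ / 2     (full window, no taper, no mean removal).

* **Autocorrelation estimator.** Biased and zero-extended:
  C(kΔt) = (1/N) Σ_{n=0}^{N−1−k} p(n)p(n+k). With this estimator the
  discrete Wiener–Khinchin identity is exact: the FFT route equals the
  explicit Fourier transform of the autocorrelation to rounding error,
  at every grid frequency, for any input. The half-line t₀ integration
  contributes a factor ½ in the discrete chain:
  I(ω) = (Δt/2) Σ_{k=−(N−1)}^{N−1} C(|k|Δt) e^{iωkΔt}. The
  autocorrelation route (`power_spectrum_direct`) exists as the built-in
  cross-check; it materializes an O(N·M) cosine table and is intended for
  validation-sized inputs (≲ a few thousand samples).
* **Zero padding.** Default 8×. The raw grid spacing of a 25,000 a.u.
  (≈0.6 ps) trajectory is ≈55 cm⁻¹; padding refines the evaluation grid so
  that isolated peaks localize to ≲7 cm⁻¹. Padding adds no information —
  it interpolates the underlying spectrum.
* **Taper.** Rectangular by default (a Hann window is available). No
  windowing is applied in the reproduction path; the Parseval identity is
  stated for the rectangular taper.
* **Mean removal.** On by default: a drifting signal otherwise produces an
  ω = 0 artifact that dominates low frequencies. It is switched off
  wherever the Parseval identity is asserted, since removing the mean
  changes ⟨p²⟩.
* **Frequency axis.** Wavenumbers, ν̃ = ω/(2πc); in atomic units an angular
  frequency of 1 a.u. is 219 474.63 cm⁻¹. The frequency window is applied
  by slicing the grid after the transform; an upper bound above Nyquist is
  an error that states the Nyquist value in cm⁻¹.

## Mode basis numerics

* **Zero-mode removal by count.** Exactly 6 eigenvalues (5 for a declared
  linear molecule) of smallest magnitude are discarded, rather than
  thresholding near zero — force-field Hessians put the external modes at
  small but nonzero values. If the discarded set is not well separated
  from the retained one (largest discarded |λ| above 10⁻⁴ of the smallest
  retained λ) a warning lists the smallest eigenvalues. Any retained
  non-positive eigenvalue raises: the geometry is not a minimum.
* **Sign convention.** Each eigenvector column is flipped so its
  largest-magnitude component is positive, making C reproducible across
  linear-algebra backends.
* **Degenerate eigenvalues.** The ordering and mixing inside a degenerate
  block is backend-dependent. Spectra are unaffected: they are computed per
  retained mode and summed over selections, and any orthogonal remixing
  inside a degenerate block leaves the summed spectrum invariant. Per-mode
  columns inside an exactly degenerate block are reproducible only up to
  that remixing; this is documented rather than "fixed".
* **Mode numbering.** 1-based, ascending harmonic frequency — mode 37 of a
  45-mode system is the 37th lowest.
* **Eckart degenerate case.** A collinear reference geometry leaves the
  alignment rotation undetermined about the molecular axis and raises.

## Synthetic generator

The generator stands in for ab initio / force-field MD runs and defines the
conditions under which the engine is validated.

* **Harmonic systems** are evolved analytically: the coupled quadratic form
  (diagonal ω_j² plus a symmetric bilinear coupling, supplied in cm⁻²) is
  diagonalized once and each eigenmode advanced as an exact
  cosine/sine — there is no integrator error anywhere in the validation
  chain. Initial conditions follow the quasi-classical scheme by default:
  each eigenmode carries total energy ω/2 (its harmonic zero-point energy,
  ħ = 1, momentum amplitude √ω) with a uniformly random phase drawn from
  the seed. A single trajectory is used throughout, matching how such
  spectra are computed in practice. Alternative schemes: thermal (energies
  exponentially distributed with mean k_BT) and explicit momentum
  amplitudes.
* **Coupling representation.** When a coupling is supplied, the returned
  `ModeBasis` spans the *local* (uncoupled) modes while the dynamics runs
  on the coupled eigenfrequencies. This reproduces the situation that makes
  single-mode spectra interesting: a projection basis built at equilibrium
  meeting dynamically mixed motion, so each mode's spectrum shows the
  shared eigen-peaks.
* **Cartesian embedding.** Local modes are embedded through a random
  orthonormal 3N×(3N−6) matrix over a fictitious atom set with real element
  masses (symbols drawn from H/C/N/O), which exercises the mass-weighting
  and projection code nontrivially. Unused vibrational slots become silent
  filler modes above the active band. `hessian_from_basis` reconstructs the
  Cartesian Hessian whose mass-weighted eigenmodes are exactly this basis,
  with an exact 6-dimensional null space.
* **Morse oscillator.** V(x) = D(1−e^{−ax})² with a set by the harmonic
  frequency of the well; classical oscillation frequency at energy E is
  ω₀√(1−E/D), the analytic target for the anharmonic red-shift checks.
  Integration is adaptive DOP853 at rtol 10⁻¹², audited to conserve energy
  to 10⁻¹⁰ relative over the run.
* **What the generator does not emulate.** Real anharmonic potentials
  (beyond the 1D Morse), thermostat noise, conformational change,
  sum-of-frequency combination bands, and the geometry-dependence of the
  true C matrix along a hot trajectory. Passing tests therefore demonstrate
  the correctness of the spectral estimator, the unit system and the
  projection algebra under controlled dynamics — not force-field accuracy
  or the assignment of any real molecule.

## Problem sizes and defaults

Validation trajectories use Δt = 10 a.u. and 2,500 steps (25,000 a.u.
≈ 0.6 ps) — the scale of a short ab initio MD run, and the scale at which
8× padding localizes isolated peaks to ≲7 cm⁻¹. The consistency and
counting checks use a 10-mode (6-atom) harmonic system and 17-/32-atom
random Hessians (45 and 90 vibrational modes). The default CLI frequency
window is 0–4,000 cm⁻¹, covering the full mid-IR fundamental region.

An optional test reproduces the published CH-stretch assignments
(modes 37–41, 3049–3153 cm⁻¹) of the aniline–water example trajectory; the
trajectory is an external download (several MB) and is not bundled — place
it under `data/external/aniline*` to activate the check.

## Known limitations

* Absolute IR absorption intensities are out of scope: no
  temperature/field prefactors and no quantum correction factors are
  applied; intensities are meaningful relatively, within one spectrum.
* The normal-mode route requires the momenta to be those of mass-weighted
  normal coordinates (the package's own projection produces exactly this).
* Exact intensity profiles depend on the padding/taper convention; peak
  positions are the convention-robust observable.
* `power_spectrum_direct` is quadratic in input size and exists for
  cross-checking, not production use.
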