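# modespec

Time-averaged vibrational power spectra from classical molecular-dynamics
trajectories, with normal-mode decomposition for peak assignment.

## The problem

Classical MD is the workhorse for computing vibrational spectra of systems
too large for quantum dynamics: the Fourier transform of the velocity
autocorrelation function locates the classical vibrational frequencies,
which approximate the quantum fundamentals while retaining (part of) the
anharmonicity of the potential. The catch is that for a molecule of N atoms
the Cartesian spectrum carries all 3N−6 modes at once and is as crowded as
the experimental one, so individual bands cannot be assigned.

`modespec` addresses this with a time-averaging formulation. For the
momentum p_j(t) of normal mode j along a trajectory of total time T,

    I_j(ω) = |p̃_j(ω)|² / (2T),    p̃_j(ω) = ∫ p_j(t) e^{iωt} dt,

which is the Fourier transform of the time-averaged autocorrelation
C_pp(t) = (1/T)∫ p_j(t₀) p_j(t₀+t) dt₀ rewritten as a manifestly
nonnegative quantity. Computed per mode, the spectrum shows only the peaks
of mode j and of the modes dynamically coupled to it — crowded bands become
assignable mode by mode. The mode basis is the orthogonal matrix C of
mass-weighted-Hessian eigenvectors with nonzero eigenvalues; trajectories
recorded in Cartesian space are projected by Q = Cᵀx, P = Cᵀ m^{1/2} v
(optionally after Eckart alignment onto the reference geometry).

The spectral engine accepts any scalar time series, so the same machinery
computes dipole-autocorrelation lineshapes or autocorrelation spectra from
entirely different fields.

## What is in the box

| module | contents |
| --- | --- |
| `modespec.trajectory_io` | block Cartesian / block normal-mode / Tinker velocity dialects, spectrum files, unit conversion to atomic units, element masses |
| `modespec.normal_modes` | mass-weighted Hessian, mode basis construction, Eckart alignment, velocity-to-momentum projection |
| `modespec.spectrum` | autocorrelation, FFT and autocorrelation-route power spectra, per-mode / summed / Cartesian spectra, peak extraction |
| `modespec.synthetic` | analytic harmonic (optionally bilinearly coupled) trajectory generator with quasi-classical initial conditions, classical Morse oscillator, random molecular Hessians |
| `modespec.cli` | `modespec run` and `modespec make-fixtures` |

## Worked example: a coupled CH-stretch-like pair

Two local modes at 3000 and 3100 cm⁻¹ with a bilinear coupling of
3×10⁵ cm⁻² mix into eigenmodes at 2979.5 and 3119.7 cm⁻¹ (the analytic 2×2
eigenfrequencies, recorded in the fixture manifest):

```bash
modespec make-fixtures --kind coupled --out-dir demo \
    --frequencies 3000,3100 --coupling 3e5 --seed 7
modespec run --input demo/mode_momenta.blk --time-step 10 \
    --mode normal --modes 1,2 --freq-min 2500 --freq-max 3600 \
    --vel-time-unit au --vel-space-unit au --output demo/ch_band.dat
```

Peak extraction on the two columns of `demo/ch_band.dat` prints:

```
mode_1: peak at   2978.6 cm^-1  intensity 79.94
mode_1: peak at   3054.5 cm^-1  intensity 5.35
mode_1: peak at   3116.5 cm^-1  intensity 21.23
mode_2: peak at   2964.8 cm^-1  intensity 6.59
mode_2: peak at   3123.4 cm^-1  intensity 68.60
mode_2: peak at   3199.3 cm^-1  intensity 3.58
```

Each single-mode spectrum shows its own dominant eigen-peak *and* a
secondary peak at the partner eigenfrequency — the spectral fingerprint of
mode coupling. Both main peaks sit within one padded grid spacing
(6.9 cm⁻¹ here: a 25,000 a.u. trajectory padded 8×) of the analytic
2979.5 / 3119.7 cm⁻¹ values; the small satellites are finite-trajectory
leakage. Hiding one column at a time is exactly how a crowded band is
assigned in practice.

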