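"""Synthetic trajectories with known spectral content.

This module is the test harness of the package: it generates harmonically
(and Morse-) evolving trajectories whose exact spectral content is known in
closed form, standing in for the ab initio / force-field MD runs the
spectral engine is meant to analyse.

The harmonic generator evolves a set of local modes of chosen frequencies,
optionally bilinearly coupled, by diagonalizing the coupled quadratic form
and propagating each eigenmode analytically — there is no integrator error.
Initial conditions follow a quasi-classical scheme by default: each
eigenmode carries a total energy of omega/2 (its harmonic zero-point
energy, hbar = 1) with a uniformly random phase, so a single trajectory
reproduces the zero-point-energy initialization used for real MD inputs.

With a nonzero coupling the returned :class:`~modespec.normal_modes.ModeBasis`
spans the *local* modes while the dynamics runs on the coupled
eigenfrequencies — exactly the situation in which a projection basis built
at the equilibrium geometry meets dynamically coupled motion, so
single-mode spectra show the shared-peak structure of coupled modes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.integrate

from . import units
from .normal_modes import ModeBasis, expand_masses
from .trajectory_io import (
    NormalModeTrajectory,
    Signal,
    Trajectory,
    resolve_masses,
)

_ELEMENT_POOL = ("H", "C", "N", "O")


@dataclasses.dataclass(frozen=True)
class OscillatorSpec:
    """Specification of a (possibly coupled) harmonic oscillator set.

    ``coupling`` is a symmetric, zero-diagonal matrix of bilinear couplings
    between the local modes, on the omega^2 scale and expressed in cm^-2
    (i.e. entry (i, j) adds ``coupling_ij * q_i q_j`` to the mass-weighted
    quadratic form after conversion to atomic units).
    """

    frequencies_cm1: tuple[float, ...]
    coupling_cm2: np.ndarray | None = None
    labels: tuple[str, ...] | None = None  # element labels of the embedding atoms
    energy_scheme: str = "quasiclassical"  # or "thermal", "explicit"
    temperature: float = 300.0  # K, thermal scheme only
    amplitudes: tuple[float, ...] | None = None  # momentum amplitudes, a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_cm1)
        object.__setattr__(self, "frequencies_cm1", freqs)
        if not freqs or any(f <= 0 for f in freqs):
            raise ValueError("mode frequencies must be positive")
        if self.coupling_cm2 is not None:
            c = np.asarray(self.coupling_cm2, dtype=float)
            if c.shape != (len(freqs), len(freqs)):
                raise ValueError("coupling matrix shape must match mode count")
            if not np.allclose(c, c.T):
                raise ValueError("coupling matrix must be symmetric")
            if np.any(np.diag(c) != 0):
                raise ValueError("coupling matrix must have a zero diagonal")
            object.__setattr__(self, "coupling_cm2", c)
        if self.energy_scheme not in ("quasiclassical", "thermal", "explicit"):
            raise ValueError(f"unknown energy scheme {self.energy_scheme!r}")
        if self.energy_scheme == "explicit":
            if self.amplitudes is None or len(self.amplitudes) != len(freqs):
                raise ValueError("explicit scheme needs one amplitude per mode")

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm1)


def coupled_eigenfrequencies(spec: OscillatorSpec) -> np.ndarray:
    """Analytic eigenfrequencies (cm^-1) of the coupled quadratic form."""
    omega = np.array(spec.frequencies_cm1) / units.HARTREE_CM1
    K = np.diag(omega**2)
    if spec.coupling_cm2 is not None:
        K = K + spec.coupling_cm2 / units.HARTREE_CM1**2
    eigvals = np.linalg.eigvalsh(K)
    if np.any(eigvals <= 0):
        raise ValueError("coupled quadratic form is not positive definite")
    return np.sqrt(eigvals) * units.HARTREE_CM1


def _random_orthonormal_columns(
    rng: np.random.Generator, n: int, k: int
) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    q = q * np.sign(np.diag(r))  # deterministic across backends
    return q[:, :k]


def generate_harmonic_trajectory(
    spec: OscillatorSpec,
    dt: float,
    n_steps: int,
) -> tuple[Trajectory, ModeBasis, NormalModeTrajectory]:
    """Analytically evolved harmonic trajectory plus its exact mode basis.

    Returns the Cartesian embedding (on a fictitious atom set large enough
    to host the requested modes among its 3N-6 vibrations), the exact
    :class:`ModeBasis` of the embedding, and the exact local-mode momenta.
    The active local modes occupy the lowest mode numbers; any remaining
    vibrational slots of the embedding are silent filler modes at higher
    frequencies with zero amplitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    rng = np.random.default_rng(spec.seed)

    order = np.argsort(spec.frequencies_cm1)
    if not np.all(order == np.arange(spec.n_modes)):
        raise ValueError("mode frequencies must be given in ascending order")

    # coupled quadratic form in local-mode coordinates (a.u. of omega^2)
    omega_local = np.array(spec.frequencies_cm1) / units.HARTREE_CM1
    K = np.diag(omega_local**2)
    if spec.coupling_cm2 is not None:
        K = K + spec.coupling_cm2 / units.HARTREE_CM1**2
    lam, U = np.linalg.eigh(K)
    if np.any(lam <= 0):
        raise ValueError("coupled quadratic form is not positive definite")
    Omega = np.sqrt(lam)

    # per-eigenmode energy
    if spec.energy_scheme == "quasiclassical":
        energies = Omega / 2.0
    elif spec.energy_scheme == "thermal":
        kT = spec.temperature * units.KBOLTZ_HARTREE_PER_K
        energies = rng.exponential(scale=kT, size=spec.n_modes)
    else:  # explicit momentum amplitudes map to E = a^2 / 2
        energies = np.array(spec.amplitudes, dtype=float) ** 2 / 2.0

    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_modes)
    amp_p = np.sqrt(2.0 * energies)

    t = np.arange(n_steps) * dt
    # eigenmode evolution: q_k = (a_k/Omega_k) sin(...), p_k = a_k cos(...)
    arg = np.outer(t, Omega) + phases
    P_eig = amp_p * np.cos(arg)
    Q_eig = (amp_p / Omega) * np.sin(arg)

    # back to local-mode coordinates
    p_local = P_eig @ U.T
    q_local = Q_eig @ U.T

    # Cartesian embedding over a fictitious atom set
    n_atoms = max(3, int(np.ceil((spec.n_modes + 6) / 3)))
    n_coords = 3 * n_atoms
    n_vib = n_coords - 6
    labels = spec.labels
    if labels is None:
        labels = tuple(rng.choice(_ELEMENT_POOL, size=n_atoms).tolist())
    elif len(labels) != n_atoms:
        raise ValueError(
            f"{len(labels)} labels given but the embedding needs {n_atoms} atoms"
        )
    masses = resolve_masses(labels)

    n_filler = n_vib - spec.n_modes
    top = max(spec.frequencies_cm1)
    filler_freqs = top * (1.2 + 0.1 * np.arange(n_filler))
    all_freqs = np.concatenate([spec.frequencies_cm1, filler_freqs])

    C = _random_orthonormal_columns(rng, n_coords, n_vib)
    basis = ModeBasis(
        masses=masses,
        reference_geometry=rng.standard_normal(n_coords) * 2.0,
        C=C,
        harmonic_frequencies=all_freqs,
    )

    q_all = np.zeros((n_steps, n_vib))
    p_all = np.zeros((n_steps, n_vib))
    q_all[:, : spec.n_modes] = q_local
    p_all[:, : spec.n_modes] = p_local

    inv_sqrt_m = 1.0 / np.sqrt(expand_masses(masses, n_coords))
    positions = basis.reference_geometry + (q_all @ C.T) * inv_sqrt_m
    velocities = (p_all @ C.T) * inv_sqrt_m

    traj = Trajectory(
        labels=labels,
        timestep=dt,
        positions=positions,
        velocities=velocities,
        source_units={"dialect": "synthetic", "time_unit": "au", "space_unit": "au"},
    )
    nm_traj = NormalModeTrajectory(timestep=dt, momenta=p_all)
    return traj, basis, nm_traj


def hessian_from_basis(basis: ModeBasis) -> np.ndarray:
    """Cartesian Hessian whose mass-weighted eigenmodes are ``basis``.

    The complement of the mode space is an exact null space, so
    :func:`~modespec.normal_modes.build_mode_basis` recovers the basis (up
    to degenerate-block rotations) with exactly 6 discarded zero modes.
    """
    omega = basis.harmonic_frequencies / units.HARTREE_CM1
    Hmw = (basis.C * omega**2) @ basis.C.T
    sqrt_m = np.sqrt(basis.coordinate_masses)
    return Hmw * np.outer(sqrt_m, sqrt_m)


def random_molecular_hessian(
    n_atoms: int,
    seed: int = 0,
    *,
    labels: Sequence[str] | None = None,
    freq_range_cm1: tuple[float, float] = (200.0, 3500.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random positive-definite Hessian with an exact trans/rot null space.

    Builds a random nonlinear geometry, projects the exact translational
    and rotational directions out of a random SPD form in mass-weighted
    coordinates, and returns ``(hessian, masses, geometry)`` in atomic
    units.  The vibrational eigenfrequencies are spread over
    ``freq_range_cm1``.
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms for a nonlinear geometry")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = tuple(rng.choice(_ELEMENT_POOL, size=n_atoms).tolist())
    masses = resolve_masses(labels)
    geometry = rng.standard_normal((n_atoms, 3)) * 2.0

    n_coords = 3 * n_atoms
    sqrt_m = np.sqrt(np.repeat(masses, 3))

    # mass-weighted translations and rotations
    ext = np.zeros((n_coords, 6))
    com = masses @ geometry / masses.sum()
    centered = geometry - com
    for axis in range(3):
        ext[axis::3, axis] = sqrt_m[axis::3]
    for a in range(n_atoms):
        for axis, (i, j) in enumerate(((1, 2), (2, 0), (0, 1))):
            ext[3 * a + i, 3 + axis] = sqrt_m[3 * a] * centered[a, j]
            ext[3 * a + j, 3 + axis] = -sqrt_m[3 * a] * centered[a, i]
    ext_basis, _ = np.linalg.qr(ext)
    proj = np.eye(n_coords) - ext_basis @ ext_basis.T

    lo = freq_range_cm1[0] / units.HARTREE_CM1
    hi = freq_range_cm1[1] / units.HARTREE_CM1
    g = rng.standard_normal((n_coords, n_coords))
    q, r = np.linalg.qr(proj @ g @ proj)
    # eigenvalues spread over [lo^2, hi^2] on the projected subspace
    vib = q[:, : n_coords - 6]
    vals = np.linspace(lo**2, hi**2, n_coords - 6)
    Hmw = (vib * vals) @ vib.T
    Hmw = proj @ Hmw @ proj  # exact null space on trans/rot
    Hmw = (Hmw + Hmw.T) / 2.0
    hessian = Hmw * np.outer(sqrt_m, sqrt_m)
    return hessian, masses, geometry.ravel()


def generate_morse_trajectory(
    omega0_cm1: float,
    dissociation_energy: float,
    mass: float,
    energy: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> Signal:
    """Velocity time series of a classical 1D Morse oscillator.

    The potential is ``V(x) = D (1 - exp(-a x))^2`` with ``a`` chosen so the
    harmonic frequency at the bottom equals ``omega0_cm1``; the classical
    oscillation frequency at total energy E is ``omega0 sqrt(1 - E/D)``.
    Integration is adaptive (DOP853) and energy-conserving to 1e-10
    relative; the seed sets the initial direction of motion.
    """
    if dissociation_energy <= 0:
        raise ValueError("dissociation energy must be positive")
    if not 0.0 < energy < dissociation_energy:
        raise ValueError(
            "energy must lie in (0, D_e); the trajectory is unbound otherwise"
        )
    if mass <= 0:
        raise ValueError("mass must be positive")
    omega0 = omega0_cm1 / units.HARTREE_CM1
    a = omega0 * np.sqrt(mass / (2.0 * dissociation_energy))

    def force(x: float) -> float:
        e = np.exp(-a * x)
        return -2.0 * a * dissociation_energy * (1.0 - e) * e

    def rhs(_t, y):
        x, v = y
        return [v, force(x) / mass]

    rng = np.random.default_rng(seed)
    v0 = np.sqrt(2.0 * energy / mass) * (1.0 if rng.random() < 0.5 else -1.0)
    t_eval = np.arange(n_steps) * dt
    sol = scipy.integrate.solve_ivp(
        rhs,
        (0.0, t_eval[-1]),
        [0.0, v0],
        t_eval=t_eval,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"Morse integration failed: {sol.message}")
    x, v = sol.y
    e_tot = 0.5 * mass * v**2 + dissociation_energy * (1.0 - np.exp(-a * x)) ** 2
    drift = np.max(np.abs(e_tot - energy)) / energy
    if drift > 1e-10:  # pragma: no cover
        raise RuntimeError(f"energy drift {drift:.2e} exceeds 1e-10 relative")
    return Signal(values=v, timestep=dt)


def morse_classical_frequency(omega0_cm1: float, energy_fraction: float) -> float:
    """Analytic classical Morse frequency omega0 * sqrt(1 - E/D), in cm^-1."""
    if not 0.0 <= energy_fraction < 1.0:
        raise ValueError("energy fraction must lie in [0, 1)")
    return omega0_cm1 * np.sqrt(1.0 - energy_fraction)


def write_tinker_velocities(
    traj: Trajectory, path: str | Path, *, title: str = "synthetic"
) -> None:
    """Write velocities in the Tinker dump dialect (Å/ps, D exponents).

    Exists here, beside the generators, because the package only ever reads
    real Tinker output; this writer produces test fixtures in that dialect.
    """
    factor = 1.0 / units.velocity_to_au(1.0, "angstrom", "ps")
    with open(path, "w") as fh:
        for frame in traj.velocities:
            fh.write(f"{traj.n_atoms}  {title}\n")
            for a, label in enumerate(traj.labels):
                v = frame[3 * a : 3 * a + 3] * factor
                comps = "  ".join(f"{x:.16E}".replace("E", "D") for x in v)
                fh.write(f"{a + 1:6d}  {label:<3s} {comps}\n")
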