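"""Normal-mode analysis: mass-weighted Hessian, mode basis, projection.

The mode basis is the orthogonal matrix ``C`` whose columns are the
eigenvectors of the mass-weighted Hessian with nonzero eigenvalues, ordered
by ascending eigenvalue.  Cartesian velocities are projected onto mode
momenta by mass-weighting each component with the square root of its atom's
mass and applying ``C^T``; this makes ``p_j`` the momentum conjugate to the
mass-weighted normal coordinate, so kinetic energy is preserved within the
retained subspace.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg

from . import units
from .trajectory_io import NormalModeTrajectory, Trajectory


@dataclasses.dataclass(frozen=True)
class ModeBasis:
    """Masses, reference geometry and orthonormal mode vectors.

    ``C`` has shape (3N, n_modes) with columns ordered by ascending
    harmonic frequency; ``harmonic_frequencies`` are in cm^-1.
    """

    masses: np.ndarray  # per atom, electron masses
    reference_geometry: np.ndarray  # 3N, bohr
    C: np.ndarray  # (3N, n_modes)
    harmonic_frequencies: np.ndarray  # cm^-1
    linear: bool = False

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        geom = np.asarray(self.reference_geometry, dtype=float).ravel()
        C = np.asarray(self.C, dtype=float)
        freqs = np.asarray(self.harmonic_frequencies, dtype=float)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "reference_geometry", geom)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "harmonic_frequencies", freqs)
        if np.any(masses <= 0):
            raise ValueError("masses must be positive")
        if C.ndim != 2 or C.shape[1] != freqs.size:
            raise ValueError("C and harmonic_frequencies disagree on mode count")
        gram = C.T @ C
        if not np.allclose(gram, np.eye(C.shape[1]), atol=1e-9):
            raise ValueError("mode vectors are not orthonormal (C^T C != I)")

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def n_modes(self) -> int:
        return self.C.shape[1]

    @property
    def coordinate_masses(self) -> np.ndarray:
        """Per-coordinate masses (each atom's mass repeated 3 times)."""
        return expand_masses(self.masses, self.C.shape[0])


def expand_masses(masses: np.ndarray, n_coords: int) -> np.ndarray:
    """Map per-atom masses onto coordinates.

    Accepts either one mass per coordinate (already expanded, as in
    low-dimensional toy models) or one mass per atom with three coordinates
    each.
    """
    masses = np.asarray(masses, dtype=float).ravel()
    if masses.size == n_coords:
        return masses
    if 3 * masses.size == n_coords:
        return np.repeat(masses, 3)
    raise ValueError(
        f"{masses.size} masses incompatible with {n_coords} coordinates"
    )


def mass_weight_hessian(hessian: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Divide each Hessian element by sqrt(m_i m_j) of the owning atoms."""
    H = np.asarray(hessian, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError(f"hessian must be square, got shape {H.shape}")
    scale = np.max(np.abs(H))
    if scale > 0 and np.max(np.abs(H - H.T)) > 1e-8 * scale:
        raise ValueError("hessian is not symmetric to 1e-8 relative")
    m = expand_masses(masses, H.shape[0])
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    inv_sqrt = 1.0 / np.sqrt(m)
    return H * np.outer(inv_sqrt, inv_sqrt)


def build_mode_basis(
    hessian: np.ndarray,
    masses: np.ndarray,
    reference_geometry: np.ndarray,
    *,
    linear: bool = False,
    n_discard: int | None = None,
) -> ModeBasis:
    """Diagonalize the mass-weighted Hessian and keep the vibrational modes.

    The ``n_discard`` eigenvalues of smallest magnitude (default 6, or 5 for
    a linear molecule) are treated as the translational/rotational null
    space and dropped — removal is by count, not by a numeric threshold,
    which is robust to the numerical noise of force-field Hessians.  Any
    retained negative eigenvalue means the geometry is not a minimum and
    raises.  Harmonic frequencies are sqrt(eigenvalue) converted to cm^-1.
    """
    Hmw = mass_weight_hessian(hessian, masses)
    n = Hmw.shape[0]
    if n_discard is None:
        n_discard = 5 if linear else 6
    if n_discard >= n:
        raise ValueError(f"cannot discard {n_discard} of {n} coordinates")
    try:
        eigvals, eigvecs = scipy.linalg.eigh(Hmw)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"eigendecomposition failed: {exc}") from exc

    order = np.argsort(np.abs(eigvals))
    discard = np.sort(order[:n_discard])
    keep = np.sort(order[n_discard:])
    kept_vals = eigvals[keep]
    if np.any(kept_vals <= 0):
        bad = int(np.argmax(kept_vals <= 0)) + 1
        raise ValueError(
            f"retained eigenvalue for mode {bad} is non-positive "
            f"({kept_vals[bad - 1]:.3e}); geometry is not a minimum"
        )
    if n_discard > 0:
        small = np.abs(eigvals[discard])
        if np.max(small) > 1e-4 * np.min(kept_vals):
            warnings.warn(
                "discarded eigenvalues are not clearly separated from the "
                f"vibrational ones; smallest |eigenvalues|: {sorted(small)}",
                stacklevel=2,
            )
    C = eigvecs[:, keep]
    # deterministic sign: largest-magnitude component of each column positive
    flip = np.sign(C[np.argmax(np.abs(C), axis=0), np.arange(C.shape[1])])
    flip[flip == 0] = 1.0
    C = C * flip
    freqs_cm1 = units.omega_au_to_wavenumber(np.sqrt(kept_vals))
    return ModeBasis(
        masses=np.asarray(masses, dtype=float),
        reference_geometry=np.asarray(reference_geometry, dtype=float).ravel(),
        C=C,
        harmonic_frequencies=freqs_cm1,
        linear=linear,
    )


def _eckart_rotation(
    positions: np.ndarray, reference: np.ndarray, masses: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mass-weighted Kabsch fit of ``positions`` onto ``reference``.

    Returns (R, com, com_ref) such that (x - com) @ R.T + com_ref is the
    aligned frame.
    """
    x = np.asarray(positions, dtype=float).reshape(-1, 3)
    r = np.asarray(reference, dtype=float).reshape(-1, 3)
    if x.shape != r.shape:
        raise ValueError("frame and reference atom counts differ")
    m = np.asarray(masses, dtype=float).ravel()
    if m.size != x.shape[0]:
        raise ValueError("one mass per atom is required")
    com = m @ x / m.sum()
    com_ref = m @ r / m.sum()
    xc = x - com
    rc = r - com_ref
    cov = (xc * m[:, None]).T @ rc
    U, sing, Vt = np.linalg.svd(cov)
    if sing[1] <= 1e-12 * max(sing[0], 1e-300):
        raise ValueError(
            "degenerate (collinear) geometry: Eckart rotation is undetermined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, com, com_ref


def eckart_align(
    frame_positions: np.ndarray,
    reference_geometry: np.ndarray,
    masses: np.ndarray,
) -> np.ndarray:
    """Align one frame onto the reference geometry (Eckart-like frame).

    Removes the mass-weighted center of mass and applies the mass-weighted
    least-squares rotation onto the reference.  Applying it to the reference
    itself returns the reference unchanged.
    """
    R, com, com_ref = _eckart_rotation(frame_positions, reference_geometry, masses)
    x = np.asarray(frame_positions, dtype=float).reshape(-1, 3)
    aligned = (x - com) @ R.T + com_ref
    return aligned.reshape(np.asarray(frame_positions).shape)


def project_to_modes(
    traj: Trajectory,
    basis: ModeBasis,
    *,
    align: bool | None = None,
) -> NormalModeTrajectory:
    """Project Cartesian velocities onto normal-mode momenta, p = C^T m^1/2 v.

    If ``align`` is true, the Eckart rotation fitted on each frame's
    positions is applied to the velocities before projection.  The default
    (``None``) enables alignment when positions are present and disables it
    for velocity-only input.
    """
    if traj.velocities is None:
        raise ValueError("trajectory has no velocities")
    n_coords = basis.C.shape[0]
    if traj.velocities.shape[1] != n_coords:
        raise ValueError(
            f"trajectory has {traj.velocities.shape[1]} coordinates but the "
            f"basis expects {n_coords}"
        )
    if align is None:
        align = traj.has_positions
    if align and not traj.has_positions:
        raise ValueError("alignment requested but trajectory has no positions")

    sqrt_m = np.sqrt(basis.coordinate_masses)
    if align:
        momenta = np.empty((traj.n_frames, basis.n_modes))
        for f in range(traj.n_frames):
            R, _, _ = _eckart_rotation(
                traj.positions[f], basis.reference_geometry, basis.masses
            )
            v = traj.velocities[f].reshape(-1, 3) @ R.T
            momenta[f] = basis.C.T @ (sqrt_m * v.ravel())
    else:
        momenta = (traj.velocities * sqrt_m) @ basis.C
    return NormalModeTrajectory(timestep=traj.timestep, momenta=momenta)
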