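"""Readers and writers for MD trajectory dialects and spectrum files.

Three plain-text trajectory dialects are supported:

* **Block Cartesian** — per MD step: a line with the atom count, then one
  line per atom ``label x y z vx vy vz``.
* **Block normal-mode** — per MD step: a line with the mode count, then the
  mode momenta, possibly wrapped over several lines.
* **Tinker velocity dump** — per MD step: a header ``natoms [title]``, then
  one line per atom ``index name vx vy vz`` with velocities in Å/ps and
  Fortran ``D`` exponents accepted.

All quantities are converted to Hartree atomic units on reading (see
:mod:`modespec.units`); writers emit atomic units unless told otherwise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from . import units


class FormatError(ValueError):
    """Structurally malformed trajectory or spectrum file."""


class ParseError(FormatError):
    """A field could not be parsed as the expected type."""


class InsufficientDataError(FormatError):
    """File parsed, but holds too few frames to define a dynamics."""


# ---------------------------------------------------------------------------
# atomic masses
# ---------------------------------------------------------------------------


def resolve_masses(labels: Sequence[str]) -> np.ndarray:
    """Resolve element labels to isotope-averaged masses in electron masses.

    Labels are matched case-insensitively against element symbols after
    stripping any trailing digits (``"H1"`` -> ``"H"``).  Unknown labels
    raise :class:`ValueError`; no silent default mass is ever applied,
    because masses enter the Hessian weighting and the kinetic-energy
    normalization of Cartesian spectra.
    """
    from mdtraj.core import element as _element

    masses = np.empty(len(labels))
    for i, raw in enumerate(labels):
        symbol = raw.rstrip("0123456789")
        symbol = symbol[:1].upper() + symbol[1:].lower()
        try:
            mass_amu = _element.get_by_symbol(symbol).mass
        except KeyError:
            raise ValueError(
                f"unknown element label {raw!r} (atom {i + 1}); "
                "provide standard element symbols"
            ) from None
        masses[i] = mass_amu * units.AMU_TO_ME
    return masses


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Time-ordered Cartesian positions/velocities in atomic units.

    ``positions`` may be ``None`` for velocity-only dialects (Tinker dump),
    which restricts use to velocity-based spectra.
    """

    labels: tuple[str, ...]
    timestep: float
    velocities: np.ndarray  # (n_frames, 3N), bohr / a.u. time
    positions: np.ndarray | None = None  # (n_frames, 3N), bohr
    source_units: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        vel = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "velocities", vel)
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if vel.ndim != 2 or vel.shape[1] != 3 * len(self.labels):
            raise ValueError(
                f"velocities shape {vel.shape} inconsistent with "
                f"{len(self.labels)} atoms"
            )
        if vel.shape[0] < 2:
            raise InsufficientDataError("a trajectory needs at least 2 frames")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            object.__setattr__(self, "positions", pos)
            if pos.shape != vel.shape:
                raise ValueError("positions and velocities shapes differ")

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]

    @property
    def has_positions(self) -> bool:
        return self.positions is not None

    @property
    def total_time(self) -> float:
        """T = timestep x (frames - 1), atomic units."""
        return self.timestep * (self.n_frames - 1)


@dataclasses.dataclass(frozen=True)
class NormalModeTrajectory:
    """Per-step normal-mode momenta p_j(t) in atomic units."""

    timestep: float
    momenta: np.ndarray  # (n_frames, n_modes)

    def __post_init__(self) -> None:
        mom = np.asarray(self.momenta, dtype=float)
        object.__setattr__(self, "momenta", mom)
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if mom.ndim != 2 or mom.shape[1] < 1:
            raise ValueError("momenta must be a (n_frames, n_modes) array")
        if mom.shape[0] < 2:
            raise InsufficientDataError(
                "a normal-mode trajectory needs at least 2 frames"
            )

    @property
    def n_modes(self) -> int:
        return self.momenta.shape[1]

    @property
    def n_frames(self) -> int:
        return self.momenta.shape[0]

    @property
    def total_time(self) -> float:
        return self.timestep * (self.n_frames - 1)


@dataclasses.dataclass(frozen=True)
class Signal:
    """A generic scalar time series (a velocity component, a dipole, ...)."""

    values: np.ndarray
    timestep: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", vals)
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if vals.size < 2:
            raise InsufficientDataError("a signal needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def total_time(self) -> float:
        return self.timestep * (self.n_samples - 1)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _numbered_lines(path: Path):
    """Yield (line_number, stripped_line) skipping blank lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped:
                yield lineno, stripped


def _parse_float(token: str, lineno: int) -> float:
    # Fortran-style D exponents appear in Tinker output.
    try:
        return float(token.replace("D", "E").replace("d", "e"))
    except ValueError:
        raise ParseError(
            f"line {lineno}: could not parse {token!r} as a number"
        ) from None


def _parse_int(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"line {lineno}: could not parse {token!r} as {what}"
        ) from None


# ---------------------------------------------------------------------------
# block Cartesian dialect
# ---------------------------------------------------------------------------


def read_block_trajectory(
    path: str | Path,
    timestep: float,
    *,
    timestep_unit: str = "au",
    time_unit: str = "au",
    space_unit: str = "au",
) -> Trajectory:
    """Read a block-format Cartesian trajectory.

    Parameters
    ----------
    timestep, timestep_unit
        MD integration step and its unit (``au`` or ``fs``); the timestep is
        always supplied by the caller, never inferred from the file.
    time_unit, space_unit
        Units of the velocities (and positions) stored in the file.
        Velocities are interpreted as ``space_unit/time_unit``.
    """
    path = Path(path)
    lines = _numbered_lines(path)
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    labels: tuple[str, ...] | None = None
    n_atoms: int | None = None
    block_index = 0

    while True:
        try:
            lineno, header = next(lines)
        except StopIteration:
            break
        block_index += 1
        tokens = header.split()
        count = _parse_int(tokens[0], lineno, "an atom count")
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise FormatError(
                f"block {block_index} (line {lineno}) declares {count} atoms, "
                f"expected {n_atoms}"
            )
        block_labels: list[str] = []
        pos = np.empty((count, 3))
        vel = np.empty((count, 3))
        for i in range(count):
            try:
                lineno, atom_line = next(lines)
            except StopIteration:
                raise FormatError(
                    f"block {block_index} ends after {i} of {count} atom lines"
                ) from None
            fields = atom_line.split()
            if len(fields) < 7:
                raise FormatError(
                    f"line {lineno}: expected 'label x y z vx vy vz', "
                    f"got {len(fields)} fields (block {block_index})"
                )
            block_labels.append(fields[0])
            values = [_parse_float(tok, lineno) for tok in fields[1:7]]
            pos[i] = values[:3]
            vel[i] = values[3:]
        if labels is None:
            labels = tuple(block_labels)
        elif tuple(block_labels) != labels:
            raise FormatError(
                f"block {block_index}: atom labels differ from block 1"
            )
        frames_pos.append(pos.ravel())
        frames_vel.append(vel.ravel())

    if block_index == 0:
        raise InsufficientDataError(f"{path}: no trajectory blocks found")
    if block_index < 2:
        raise InsufficientDataError(
            f"{path}: only {block_index} block(s); at least 2 are required"
        )

    space = units.SPACE_TO_BOHR[space_unit] if space_unit in units.SPACE_TO_BOHR else None
    if space is None:
        raise ValueError(f"unknown space unit {space_unit!r}")
    vel_factor = units.velocity_to_au(1.0, space_unit, time_unit)
    return Trajectory(
        labels=labels,
        timestep=units.time_to_au(timestep, timestep_unit),
        positions=np.asarray(frames_pos) * space,
        velocities=np.asarray(frames_vel) * vel_factor,
        source_units={
            "timestep_unit": timestep_unit,
            "time_unit": time_unit,
            "space_unit": space_unit,
            "dialect": "block",
        },
    )


def write_block_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the block Cartesian dialect, in atomic units."""
    if traj.positions is None:
        raise ValueError("trajectory has no positions; cannot write block dialect")
    with open(path, "w") as fh:
        for pos, vel in zip(traj.positions, traj.velocities):
            fh.write(f"{traj.n_atoms}\n")
            for a, label in enumerate(traj.labels):
                p = pos[3 * a : 3 * a + 3]
                v = vel[3 * a : 3 * a + 3]
                fh.write(
                    f"{label} "
                    + " ".join(f"{x:.17g}" for x in (*p, *v))
                    + "\n"
                )


# ---------------------------------------------------------------------------
# block normal-mode dialect
# ---------------------------------------------------------------------------


def read_normal_mode_trajectory(
    path: str | Path,
    timestep: float,
    *,
    timestep_unit: str = "au",
    time_unit: str = "au",
    space_unit: str = "au",
) -> NormalModeTrajectory:
    """Read a block-format normal-mode momentum trajectory.

    Each block starts with the mode count, followed by that many momenta,
    wrapped over as many lines as needed.  Momenta are scaled by the same
    ``space_unit/time_unit`` factor as velocities (with the mass factor
    assumed to be in atomic units already).
    """
    path = Path(path)
    lines = _numbered_lines(path)
    frames: list[np.ndarray] = []
    n_modes: int | None = None
    block_index = 0

    while True:
        try:
            lineno, header = next(lines)
        except StopIteration:
            break
        block_index += 1
        tokens = header.split()
        count = _parse_int(tokens[0], lineno, "a mode count")
        if count < 1:
            raise FormatError(f"line {lineno}: mode count must be positive")
        if n_modes is None:
            n_modes = count
        elif count != n_modes:
            raise FormatError(
                f"block {block_index} (line {lineno}) declares {count} modes, "
                f"expected {n_modes}"
            )
        values: list[float] = []
        while len(values) < count:
            try:
                lineno, data_line = next(lines)
            except StopIteration:
                raise FormatError(
                    f"block {block_index} ends after {len(values)} of "
                    f"{count} momenta"
                ) from None
            toks = data_line.split()
            if len(values) + len(toks) > count:
                raise FormatError(
                    f"block {block_index} (line {lineno}): more momenta than "
                    f"the declared {count}"
                )
            values.extend(_parse_float(t, lineno) for t in toks)
        frames.append(np.array(values))

    if block_index == 0:
        raise InsufficientDataError(f"{path}: no momentum blocks found")
    if block_index < 2:
        raise InsufficientDataError(
            f"{path}: only {block_index} block(s); at least 2 are required"
        )

    scale = units.velocity_to_au(1.0, space_unit, time_unit)
    return NormalModeTrajectory(
        timestep=units.time_to_au(timestep, timestep_unit),
        momenta=np.asarray(frames) * scale,
    )


def write_normal_mode_trajectory(
    nm_traj: NormalModeTrajectory, path: str | Path, *, per_line: int = 6
) -> None:
    """Write a normal-mode trajectory in the block dialect, in atomic units."""
    with open(path, "w") as fh:
        for frame in nm_traj.momenta:
            fh.write(f"{nm_traj.n_modes}\n")
            for start in range(0, nm_traj.n_modes, per_line):
                chunk = frame[start : start + per_line]
                fh.write(" ".join(f"{x:.17g}" for x in chunk) + "\n")


# ---------------------------------------------------------------------------
# Tinker velocity dump
# ---------------------------------------------------------------------------


def read_tinker_velocities(
    path: str | Path,
    timestep: float,
    *,
    timestep_unit: str = "au",
    time_unit: str = "ps",
    space_unit: str = "angstrom",
) -> Trajectory:
    """Read a Tinker velocity dump (velocities in Å/ps by default).

    Per frame: a header line ``natoms [title]``, then per atom a line
    ``index name vx vy vz`` (extra trailing columns are ignored; Fortran
    ``D`` exponents are accepted).  Positions are absent from this dialect,
    so the returned trajectory can only feed velocity-based spectra.
    """
    path = Path(path)
    lines = _numbered_lines(path)
    frames: list[np.ndarray] = []
    labels: tuple[str, ...] | None = None
    n_atoms: int | None = None
    frame_index = 0

    while True:
        try:
            lineno, header = next(lines)
        except StopIteration:
            break
        frame_index += 1
        count = _parse_int(header.split()[0], lineno, "an atom count")
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise FormatError(
                f"frame {frame_index} (line {lineno}) declares {count} atoms, "
                f"expected {n_atoms}"
            )
        frame_labels: list[str] = []
        vel = np.empty((count, 3))
        prev_index = 0
        for i in range(count):
            try:
                lineno, atom_line = next(lines)
            except StopIteration:
                raise FormatError(
                    f"frame {frame_index} ends after {i} of {count} atom lines"
                ) from None
            fields = atom_line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"line {lineno}: expected 'index name vx vy vz', got "
                    f"{len(fields)} fields (missing velocity column?)"
                )
            idx = _parse_int(fields[0], lineno, "an atom index")
            if idx <= prev_index:
                raise FormatError(
                    f"line {lineno}: non-monotonic atom index {idx} after "
                    f"{prev_index} (frame {frame_index})"
                )
            prev_index = idx
            frame_labels.append(fields[1])
            vel[i] = [_parse_float(tok, lineno) for tok in fields[2:5]]
        if labels is None:
            labels = tuple(frame_labels)
        elif tuple(frame_labels) != labels:
            raise FormatError(
                f"frame {frame_index}: atom names differ from frame 1"
            )
        frames.append(vel.ravel())

    if frame_index == 0:
        raise InsufficientDataError(f"{path}: no velocity frames found")
    if frame_index < 2:
        raise InsufficientDataError(
            f"{path}: only {frame_index} frame(s); at least 2 are required"
        )

    vel_factor = units.velocity_to_au(1.0, space_unit, time_unit)
    return Trajectory(
        labels=labels,
        timestep=units.time_to_au(timestep, timestep_unit),
        positions=None,
        velocities=np.asarray(frames) * vel_factor,
        source_units={
            "timestep_unit": timestep_unit,
            "time_unit": time_unit,
            "space_unit": space_unit,
            "dialect": "tinker",
        },
    )


# ---------------------------------------------------------------------------
# spectrum files
# ---------------------------------------------------------------------------


def write_spectrum(spectrum, path: str | Path, selection=None) -> None:
    """Write a power spectrum as whitespace-delimited text.

    The first column is the frequency in cm^-1; subsequent columns are the
    intensity columns named in the ``# freq_cm-1 ...`` header.  ``selection``
    may be ``None`` (all columns), a column label, or a list of labels /
    1-based mode numbers restricted to columns present in the spectrum.
    """
    labels = list(spectrum.labels)
    if selection is None:
        cols = list(range(len(labels)))
    else:
        if isinstance(selection, (str, int)):
            selection = [selection]
        if len(selection) == 0:
            raise ValueError("empty column selection")
        cols = []
        for item in selection:
            label = f"mode_{item}" if isinstance(item, int) else str(item)
            if label not in labels:
                raise ValueError(
                    f"column {label!r} not in spectrum columns {labels}"
                )
            cols.append(labels.index(label))
    with open(path, "w") as fh:
        fh.write("# freq_cm-1 " + " ".join(labels[c] for c in cols) + "\n")
        for k, freq in enumerate(spectrum.frequencies):
            row = " ".join(f"{spectrum.intensities[k, c]:.12e}" for c in cols)
            fh.write(f"{freq:.8f} {row}\n")


def read_spectrum(path: str | Path):
    """Read a spectrum file written by :func:`write_spectrum`."""
    from .spectrum import PowerSpectrum

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise FormatError(f"{path}: missing '# freq_cm-1 ...' header")
    labels = header.lstrip("#").split()[1:]
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != len(labels) + 1:
        raise FormatError(
            f"{path}: {data.shape[1]} columns but {len(labels)} labels"
        )
    return PowerSpectrum(
        frequencies=data[:, 0],
        intensities=data[:, 1:],
        labels=tuple(labels),
        total_time=float("nan"),
        meta={"source": str(path)},
    )
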