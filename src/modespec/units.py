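"""Unit conversions to and from the internal Hartree atomic-unit system.

Everything inside the package is expressed in Hartree atomic units:
lengths in bohr, time in atomic time units (:math:`\\hbar/E_h`), masses in
electron masses.  All conversions happen at the I/O boundary so that the
frequency axis of a Fourier transform has a single, unambiguous meaning.

Angular frequencies in atomic units map onto spectroscopic wavenumbers via
``omega_au_to_wavenumber``: an angular frequency equal to 1 a.u. corresponds
to a photon of 1 hartree, i.e. 219474.63 cm^-1.
"""

from __future__ import annotations

from scipy import constants as _const

#: Bohr radius in metres.
BOHR_M: float = _const.physical_constants["Bohr radius"][0]
#: Atomic unit of time in seconds.
AU_TIME_S: float = _const.physical_constants["atomic unit of time"][0]
#: Unified atomic mass unit in electron masses.
AMU_TO_ME: float = (
    _const.physical_constants["atomic mass constant"][0]
    / _const.physical_constants["electron mass"][0]
)
#: 1 hartree expressed as a wavenumber (cm^-1).
HARTREE_CM1: float = (
    _const.physical_constants["hartree-inverse meter relationship"][0] / 100.0
)
#: Boltzmann constant in hartree per kelvin.
KBOLTZ_HARTREE_PER_K: float = (
    _const.physical_constants["Boltzmann constant"][0]
    / _const.physical_constants["Hartree energy"][0]
)

ANGSTROM_PER_BOHR: float = BOHR_M * 1e10
FS_PER_AU_TIME: float = AU_TIME_S * 1e15

#: Multiply a time in the named unit by this factor to obtain atomic units.
TIME_TO_AU: dict[str, float] = {
    "au": 1.0,
    "fs": 1.0 / FS_PER_AU_TIME,
    "ps": 1e3 / FS_PER_AU_TIME,
}

#: Multiply a length in the named unit by this factor to obtain bohr.
SPACE_TO_BOHR: dict[str, float] = {
    "au": 1.0,
    "angstrom": 1.0 / ANGSTROM_PER_BOHR,
    "nm": 10.0 / ANGSTROM_PER_BOHR,
}


def time_to_au(value: float, unit: str) -> float:
    """Convert a time from ``unit`` (au, fs or ps) to atomic units."""
    try:
        return value * TIME_TO_AU[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_TO_AU)}"
        ) from None


def space_to_bohr(value: float, unit: str) -> float:
    """Convert a length from ``unit`` (au, angstrom or nm) to bohr."""
    try:
        return value * SPACE_TO_BOHR[unit]
    except KeyError:
        raise ValueError(
            f"unknown space unit {unit!r}; expected one of {sorted(SPACE_TO_BOHR)}"
        ) from None


def velocity_to_au(value: float, space_unit: str, time_unit: str) -> float:
    """Convert a velocity from ``space_unit/time_unit`` to bohr per a.u. time."""
    return space_to_bohr(value, space_unit) / TIME_TO_AU[_check_time(time_unit)]


def _check_time(unit: str) -> str:
    if unit not in TIME_TO_AU:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_TO_AU)}"
        )
    return unit


def omega_au_to_wavenumber(omega: float) -> float:
    """Angular frequency in a.u. -> wavenumber in cm^-1."""
    return omega * HARTREE_CM1


def wavenumber_to_omega_au(wavenumber: float) -> float:
    """Wavenumber in cm^-1 -> angular frequency in a.u."""
    return wavenumber / HARTREE_CM1
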