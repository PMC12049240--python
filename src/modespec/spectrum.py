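"""Time-averaged power spectra of autocorrelated MD data.

The central quantity is the time-averaged power spectrum of a real signal
``p(t)`` sampled at interval ``dt`` over a total time ``T``:

    I(omega) = |p~(omega)|^2 / (2 T),      p~(omega) = dt * sum_n p(t_n) e^{i omega t_n}

which is the Fourier transform of the time-averaged autocorrelation
``C(t) = (1/T) int p(t0) p(t0+t) dt0`` rewritten as a manifestly
nonnegative quantity.  In the discrete setting the two routes are exactly
equivalent when the autocorrelation is taken as the biased, zero-extended
estimator; :func:`power_spectrum_direct` implements the autocorrelation
route and serves as the built-in cross-check of the FFT route.

Conventions (documented in detail in ``docs/methods.md``):

* normalization time ``T = N dt`` (N samples, each owning one interval);
* the reported spectrum is one-sided: the negative-frequency half is folded
  onto positive frequencies (a factor 2 on every interior bin), so that the
  full-window integral ``int I(omega) d omega / (2 pi)`` equals the mean
  kinetic-energy-like quantity ``<p^2>/2`` exactly (no taper, no mean
  removal);
* frequencies are reported in cm^-1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from . import units
from .trajectory_io import NormalModeTrajectory, Signal, Trajectory, resolve_masses


@dataclasses.dataclass(frozen=True)
class Autocorrelation:
    """Biased (1/N), zero-extended autocorrelation estimate."""

    lags: np.ndarray  # atomic units, starting at 0, equally spaced
    values: np.ndarray
    normalization: str = "biased"

    @property
    def timestep(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclasses.dataclass(frozen=True)
class PowerSpectrum:
    """One or more nonnegative intensity columns on a common frequency grid."""

    frequencies: np.ndarray  # cm^-1, ascending, equally spaced
    intensities: np.ndarray  # (n_freq, n_columns)
    labels: tuple[str, ...]
    total_time: float  # atomic units
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if inten.ndim == 1:
            inten = inten[:, None]
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "intensities", inten)
        if inten.shape[0] != freqs.size:
            raise ValueError("frequency grid and intensities disagree")
        if inten.shape[1] != len(self.labels):
            raise ValueError("one label per intensity column is required")

    @property
    def n_columns(self) -> int:
        return self.intensities.shape[1]

    def column(self, key: int | str) -> np.ndarray:
        """Intensity column by integer index or label."""
        if isinstance(key, str):
            if key not in self.labels:
                raise KeyError(f"no column {key!r}; have {list(self.labels)}")
            key = self.labels.index(key)
        return self.intensities[:, key]


def autocorrelate(signal: Signal, max_lag_fraction: float = 1.0) -> Autocorrelation:
    """Biased, zero-extended autocorrelation of a scalar signal.

    ``C(k dt) = (1/N) sum_{n=0}^{N-1-k} s(n) s(n+k)`` — the estimator whose
    Fourier transform reproduces the periodogram exactly (discrete
    Wiener–Khinchin).  ``max_lag_fraction`` limits the lag range to that
    fraction of the signal duration.
    """
    if not 0.0 < max_lag_fraction <= 1.0:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    s = signal.values
    n = s.size
    full = scipy.signal.correlate(s, s, mode="full", method="auto")[n - 1 :]
    n_lags = int(np.floor(max_lag_fraction * (n - 1))) + 1
    values = full[:n_lags] / n
    lags = np.arange(n_lags) * signal.timestep
    return Autocorrelation(lags=lags, values=values)


def _preprocess(values: np.ndarray, remove_mean: bool, taper: str) -> np.ndarray:
    out = np.asarray(values, dtype=float)
    if remove_mean:
        out = out - out.mean()
    if taper == "rect":
        pass
    elif taper == "hann":
        out = out * scipy.signal.windows.hann(out.size, sym=False)
    else:
        raise ValueError(f"unknown taper {taper!r}; expected 'rect' or 'hann'")
    return out


def _grid(n: int, dt: float, pad_factor: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Padded one-sided frequency grid (cm^-1), folding factors and M."""
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    m = int(round(pad_factor * n))
    omega = 2.0 * np.pi * np.fft.rfftfreq(m, d=dt)  # rad / a.u. time
    freqs = units.omega_au_to_wavenumber(omega)
    fold = np.full(freqs.size, 2.0)
    fold[0] = 1.0
    if m % 2 == 0:
        fold[-1] = 1.0
    return freqs, fold, m

def _window_mask(
    freqs: np.ndarray, freq_window, dt: float
) -> np.ndarray:
    nyquist = units.omega_au_to_wavenumber(np.pi / dt)
    if freq_window is None:
        freq_window = (0.0, nyquist)
    lo, hi = float(freq_window[0]), float(freq_window[1])
    if hi > nyquist * (1 + 1e-12):
        raise ValueError(
            f"upper frequency {hi:g} cm^-1 exceeds the Nyquist frequency "
            f"{nyquist:.2f} cm^-1 for this timestep"
        )
    if lo >= hi:
        raise ValueError("freq_window lower bound must be below the upper bound")
    mask = (freqs >= lo) & (freqs <= hi * (1 + 1e-12))
    if not np.any(mask):
        raise ValueError("frequency window contains no grid points")
    return mask


def power_spectrum_tavg(
    signal: Signal,
    freq_window=None,
    *,
    pad_factor: int = 8,
    taper: str = "rect",
    remove_mean: bool = True,
) -> PowerSpectrum:
    """Time-averaged power spectrum I(omega) = |p~(omega)|^2 / (2T), via FFT.

    Zero padding (default 8x) refines the frequency grid, which is what
    localizes peaks well below the raw ``2 pi / T`` resolution on the short
    trajectories typical of ab initio MD.  Mean removal (default on)
    suppresses the omega = 0 artifact from drifting signals.
    """
    s = _preprocess(signal.values, remove_mean, taper)
    n = s.size
    dt = signal.timestep
    freqs, fold, m = _grid(n, dt, pad_factor)
    ptilde = dt * np.fft.rfft(s, n=m)
    t_norm = n * dt
    intensities = fold * np.abs(ptilde) ** 2 / (2.0 * t_norm)
    mask = _window_mask(freqs, freq_window, dt)
    return PowerSpectrum(
        frequencies=freqs[mask],
        intensities=intensities[mask],
        labels=("signal",),
        total_time=signal.total_time,
        meta={
            "pad_factor": pad_factor,
            "taper": taper,
            "remove_mean": remove_mean,
            "route": "fft",
        },
    )


def power_spectrum_direct(
    signal: Signal,
    freq_window=None,
    *,
    pad_factor: int = 8,
    taper: str = "rect",
    remove_mean: bool = True,
) -> PowerSpectrum:
    """Power spectrum via explicit Fourier transform of the autocorrelation.

    Same conventions and grid as :func:`power_spectrum_tavg`; exists as the
    independent autocorrelation-route cross-check of the FFT route (the two
    agree to rounding error for any input).
    """
    s = _preprocess(signal.values, remove_mean, taper)
    n = s.size
    dt = signal.timestep
    acf = autocorrelate(Signal(values=s, timestep=dt) if n >= 2 else signal, 1.0)
    freqs, fold, m = _grid(n, dt, pad_factor)
    omega = units.wavenumber_to_omega_au(freqs)
    k = np.arange(n)
    # I(w) = (dt/2) * sum_{k=-(n-1)}^{n-1} C(|k|) e^{i w k dt}; the factor
    # 1/2 is the discrete footprint of the half-line t0 integration that
    # turns the FT of C(t) into |p~|^2/(2T).
    cos_table = np.cos(np.outer(omega * dt, k))
    weights = acf.values.copy()
    weights[1:] *= 2.0
    weights[0] *= 1.0
    intensities = fold * (dt / 2.0) * (cos_table @ weights)
    mask = _window_mask(freqs, freq_window, dt)
    return PowerSpectrum(
        frequencies=freqs[mask],
        intensities=intensities[mask],
        labels=("signal",),
        total_time=signal.total_time,
        meta={
            "pad_factor": pad_factor,
            "taper": taper,
            "remove_mean": remove_mean,
            "route": "autocorrelation",
        },
    )


def _parse_selection(selection, n_modes: int) -> list[int] | str:
    if isinstance(selection, str):
        sel = selection.strip().lower()
        if sel in ("sum", "all"):
            return sel
        try:
            indices = [int(tok) for tok in sel.replace(",", " ").split()]
        except ValueError:
            raise ValueError(
                f"selection {selection!r} is not 'sum', 'all' or mode numbers"
            ) from None
    else:
        indices = [int(i) for i in selection]
    if not indices:
        raise ValueError("empty mode selection")
    for i in indices:
        if not 1 <= i <= n_modes:
            raise ValueError(
                f"mode {i} out of range; valid modes are 1..{n_modes}"
            )
    return indices


def compute_mode_spectra(
    nm_traj: NormalModeTrajectory,
    selection="sum",
    freq_window=None,
    *,
    pad_factor: int = 8,
    taper: str = "rect",
    remove_mean: bool = True,
) -> PowerSpectrum:
    """Per-mode power spectra I_j(omega) of normal-mode momenta.

    ``selection`` is ``"sum"`` (one column, the sum of all I_j), ``"all"``
    (one column per mode) or an explicit list of 1-based mode numbers in
    ascending-frequency order of the basis.
    """
    sel = _parse_selection(selection, nm_traj.n_modes)
    if sel == "sum":
        modes = range(1, nm_traj.n_modes + 1)
    elif sel == "all":
        modes = range(1, nm_traj.n_modes + 1)
    else:
        modes = sel

    columns = []
    freqs = None
    for j in modes:
        spec = power_spectrum_tavg(
            Signal(values=nm_traj.momenta[:, j - 1], timestep=nm_traj.timestep),
            freq_window,
            pad_factor=pad_factor,
            taper=taper,
            remove_mean=remove_mean,
        )
        freqs = spec.frequencies
        columns.append(spec.intensities[:, 0])

    if sel == "sum":
        intensities = np.sum(columns, axis=0)[:, None]
        labels = ("sum",)
    else:
        intensities = np.stack(columns, axis=1)
        labels = tuple(f"mode_{j}" for j in modes)
    return PowerSpectrum(
        frequencies=freqs,
        intensities=intensities,
        labels=labels,
        total_time=nm_traj.total_time,
        meta={
            "pad_factor": pad_factor,
            "taper": taper,
            "remove_mean": remove_mean,
            "selection": selection if isinstance(selection, str) else list(selection),
        },
    )


def compute_cartesian_spectrum(
    traj: Trajectory,
    freq_window=None,
    *,
    masses: np.ndarray | None = None,
    pad_factor: int = 8,
    taper: str = "rect",
    remove_mean: bool = True,
) -> PowerSpectrum:
    """Summed power spectrum of mass-weighted Cartesian velocities.

    Each velocity component is weighted by the square root of its atom's
    mass before transforming, so the summed Cartesian spectrum carries the
    same kinetic-energy normalization as the normal-mode route and the two
    are bin-by-bin identical for motion confined to the vibrational
    subspace.  Masses default to the element labels of the trajectory.
    """
    if masses is None:
        masses = resolve_masses(traj.labels)
    m_coord = np.repeat(np.asarray(masses, dtype=float).ravel(), 3)
    if m_coord.size != traj.velocities.shape[1]:
        raise ValueError("mass array inconsistent with trajectory coordinates")
    sqrt_m = np.sqrt(m_coord)

    total = None
    freqs = None
    for i in range(traj.velocities.shape[1]):
        spec = power_spectrum_tavg(
            Signal(values=sqrt_m[i] * traj.velocities[:, i], timestep=traj.timestep),
            freq_window,
            pad_factor=pad_factor,
            taper=taper,
            remove_mean=remove_mean,
        )
        freqs = spec.frequencies
        col = spec.intensities[:, 0]
        total = col if total is None else total + col
    return PowerSpectrum(
        frequencies=freqs,
        intensities=total[:, None],
        labels=("sum",),
        total_time=traj.total_time,
        meta={
            "pad_factor": pad_factor,
            "taper": taper,
            "remove_mean": remove_mean,
            "route": "cartesian",
        },
    )


def find_peaks(
    spectrum: PowerSpectrum,
    column: int | str = 0,
    min_relative_height: float = 0.05,
) -> list[tuple[float, float]]:
    """Locate spectral peaks: strict local maxima above a relative threshold.

    Returns ``(frequency_cm1, intensity)`` pairs sorted by frequency for all
    strict local maxima with intensity at least ``min_relative_height``
    times the global maximum; the global maximum itself is always included.
    A flat spectrum has no peaks and yields an empty list.  Exact intensity
    ties are all reported.
    """
    if not 0.0 < min_relative_height <= 1.0:
        raise ValueError("min_relative_height must lie in (0, 1]")
    y = spectrum.column(column)
    if y.size < 3 or np.allclose(y, y[0]):
        return []
    top = float(np.max(y))
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
    idx = set((np.nonzero(interior)[0] + 1).tolist())
    idx.add(int(np.argmax(y)))  # global max, even at a boundary/plateau
    peaks = [
        (float(spectrum.frequencies[k]), float(y[k]))
        for k in sorted(idx)
        if y[k] >= min_relative_height * top
    ]
    return peaks


def dominant_peak(
    spectrum: PowerSpectrum, column: int | str = 0
) -> tuple[float, float]:
    """Frequency and intensity of the highest peak (lower frequency on tie)."""
    peaks = find_peaks(spectrum, column, min_relative_height=1e-12)
    if not peaks:
        raise ValueError("spectrum is flat; no dominant peak")
    best = max(peaks, key=lambda p: (p[1], -p[0]))
    return best
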