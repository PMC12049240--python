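"""Autocorrelation and power-spectrum engine: oracles, invariants, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modespec as ms
from modespec import units


def brute_force_acf(values):
    """Biased, zero-extended autocorrelation by double loop."""
    n = len(values)
    return np.array(
        [sum(values[i] * values[i + k] for i in range(n - k)) / n for k in range(n)]
    )


def brute_force_spectrum(values, dt, freqs_cm1):
    """One-sided |p~|^2/(2T) by explicit DFT sum, T = N dt, interior bins folded."""
    n = len(values)
    t = np.arange(n) * dt
    omega = np.asarray(freqs_cm1) / units.HARTREE_CM1
    ptilde = dt * np.exp(1j * np.outer(omega, t)) @ values
    intensity = np.abs(ptilde) ** 2 / (2.0 * n * dt)
    nyq = units.omega_au_to_wavenumber(np.pi / dt)
    fold = np.where(
        (np.asarray(freqs_cm1) == 0.0)
        | np.isclose(freqs_cm1, nyq, rtol=1e-12, atol=0.0),
        1.0,
        2.0,
    )
    return fold * intensity


def cosine_signal(freq_cm1, dt, n, amplitude=1.0, phase=0.0):
    omega = freq_cm1 / units.HARTREE_CM1
    t = np.arange(n) * dt
    return ms.Signal(values=amplitude * np.cos(omega * t + phase), timestep=dt)


class TestAutocorrelate:
    def test_constant_ones_hand_computed(self):
        acf = ms.autocorrelate(ms.Signal(values=[1.0, 1.0, 1.0, 1.0], timestep=1.0))
        assert acf.values[0] == pytest.approx(1.0)
        assert acf.values[1] == pytest.approx(0.75)
        assert acf.values[3] == pytest.approx(0.25)

    def test_zero_signal_gives_zeros(self):
        acf = ms.autocorrelate(ms.Signal(values=np.zeros(16), timestep=1.0))
        assert np.all(acf.values == 0)

    def test_matches_double_loop_oracle(self, rng):
        values = rng.standard_normal(65)
        acf = ms.autocorrelate(ms.Signal(values=values, timestep=2.0))
        np.testing.assert_allclose(acf.values, brute_force_acf(values), atol=1e-12)

    def test_cosine_acf_oscillates_with_signal_period(self):
        sig = cosine_signal(units.HARTREE_CM1 * 2 * np.pi / 8, 1.0, 64)  # period 8
        acf = ms.autocorrelate(sig)
        # maxima of C(t) recur every 8 samples
        assert acf.values[8] > acf.values[4]
        assert acf.values[16] > acf.values[12]
        assert np.argmax(acf.values[1:12]) + 1 == 8

    def test_max_lag_fraction_limits_range(self, rng):
        sig = ms.Signal(values=rng.standard_normal(100), timestep=1.0)
        acf = ms.autocorrelate(sig, max_lag_fraction=0.5)
        assert acf.lags[-1] <= 0.5 * sig.total_time

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_max_lag_fraction_raises(self, bad):
        sig = ms.Signal(values=[1.0, 2.0], timestep=1.0)
        with pytest.raises(ValueError):
            ms.autocorrelate(sig, max_lag_fraction=bad)


class TestPowerSpectrum:
    def test_pure_cosine_peak_within_padded_grid_spacing(self):
        sig = cosine_signal(1500.0, 10.0, 2500)
        spec = ms.power_spectrum_tavg(sig, (0.0, 4000.0), pad_factor=8)
        spacing = spec.frequencies[1] - spec.frequencies[0]
        peak, _ = ms.dominant_peak(spec)
        assert abs(peak - 1500.0) <= spacing

    def test_zero_signal_gives_zero_spectrum(self):
        spec = ms.power_spectrum_tavg(
            ms.Signal(values=np.zeros(64), timestep=1.0), remove_mean=False
        )
        assert np.all(spec.intensities == 0)

    def test_matches_brute_force_dft_oracle(self, rng):
        values = rng.standard_normal(48)
        dt = 7.0
        spec = ms.power_spectrum_tavg(
            ms.Signal(values=values, timestep=dt), pad_factor=4, remove_mean=False
        )
        oracle = brute_force_spectrum(values, dt, spec.frequencies)
        np.testing.assert_allclose(
            spec.intensities[:, 0], oracle, rtol=1e-9, atol=1e-12 * oracle.max()
        )

    def test_upper_frequency_above_nyquist_reports_nyquist(self):
        sig = ms.Signal(values=np.ones(32), timestep=10.0)
        nyq = units.omega_au_to_wavenumber(np.pi / 10.0)
        with pytest.raises(ValueError, match=f"{nyq:.2f}"):
            ms.power_spectrum_tavg(sig, (0.0, nyq * 1.5))

    def test_inverted_window_raises(self):
        sig = ms.Signal(values=np.ones(32), timestep=10.0)
        with pytest.raises(ValueError, match="lower bound"):
            ms.power_spectrum_tavg(sig, (2000.0, 1000.0))

    @pytest.mark.parametrize("taper,remove_mean", [
        ("rect", False), ("rect", True), ("hann", False), ("hann", True),
    ])
    def test_wiener_khinchin_equivalence(self, rng, taper, remove_mean):
        """FFT route and autocorrelation-FT route agree to 1e-10 relative."""
        values = rng.standard_normal(300)
        sig = ms.Signal(values=values, timestep=4.0)
        kwargs = dict(pad_factor=4, taper=taper, remove_mean=remove_mean)
        fft_route = ms.power_spectrum_tavg(sig, **kwargs)
        acf_route = ms.power_spectrum_direct(sig, **kwargs)
        np.testing.assert_allclose(acf_route.frequencies, fft_route.frequencies)
        scale = fft_route.intensities.max()
        assert (
            np.max(np.abs(fft_route.intensities - acf_route.intensities)) <= 1e-10 * scale
        )

    def test_parseval_normalization(self, rng):
        """Full-window integral of I/(2 pi) equals <p^2>/2 exactly."""
        for _ in range(5):
            values = rng.standard_normal(rng.integers(30, 200))
            dt = float(rng.uniform(0.5, 20.0))
            sig = ms.Signal(values=values, timestep=dt)
            spec = ms.power_spectrum_tavg(
                sig, pad_factor=int(rng.integers(1, 9)), remove_mean=False
            )
            domega = (spec.frequencies[1] - spec.frequencies[0]) / units.HARTREE_CM1
            integral = spec.intensities.sum() * domega / (2 * np.pi)
            assert integral == pytest.approx(np.mean(values**2) / 2, rel=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=4,
            max_size=128,
        ),
        st.booleans(),
    )
    def test_positivity_everywhere(self, values, remove_mean):
        """|p~|^2 form: every reported intensity is nonnegative."""
        sig = ms.Signal(values=np.array(values), timestep=3.0)
        spec = ms.power_spectrum_tavg(sig, remove_mean=remove_mean)
        assert np.all(spec.intensities >= 0)


class TestModeAndCartesianSpectra:
    @pytest.fixture
    def two_mode_system(self):
        spec = ms.OscillatorSpec(frequencies_cm1=(1200.0, 2600.0), seed=9)
        return ms.generate_harmonic_trajectory(spec, 10.0, 2000)

    def test_uncoupled_modes_peak_only_at_own_frequency(self, two_mode_system):
        _, _, nm = two_mode_system
        spec = ms.compute_mode_spectra(nm, "all", (500.0, 3500.0))
        peaks1 = ms.find_peaks(spec, "mode_1", 0.1)
        peaks2 = ms.find_peaks(spec, "mode_2", 0.1)
        spacing = spec.frequencies[1] - spec.frequencies[0]
        assert len(peaks1) == 1 and abs(peaks1[0][0] - 1200.0) <= spacing
        assert len(peaks2) == 1 and abs(peaks2[0][0] - 2600.0) <= spacing

    def test_sum_is_elementwise_sum_of_all(self, two_mode_system):
        _, _, nm = two_mode_system
        all_spec = ms.compute_mode_spectra(nm, "all")
        sum_spec = ms.compute_mode_spectra(nm, "sum")
        np.testing.assert_array_equal(
            sum_spec.intensities[:, 0], all_spec.intensities.sum(axis=1)
        )

    def test_explicit_selection_orders_columns(self, two_mode_system):
        _, _, nm = two_mode_system
        spec = ms.compute_mode_spectra(nm, [2, 1])
        assert spec.labels == ("mode_2", "mode_1")

    def test_selection_out_of_range_names_valid_range(self, two_mode_system):
        _, _, nm = two_mode_system
        with pytest.raises(ValueError, match=f"1..{nm.n_modes}"):
            ms.compute_mode_spectra(nm, [0])

    def test_cartesian_equals_mode_sum_for_harmonic_system(self, two_mode_system):
        traj, _, nm = two_mode_system
        opts = dict(pad_factor=8, taper="rect", remove_mean=True)
        cart = ms.compute_cartesian_spectrum(traj, (0.0, 4000.0), **opts)
        mode_sum = ms.compute_mode_spectra(nm, "sum", (0.0, 4000.0), **opts)
        scale = mode_sum.intensities.max()
        assert (
            np.max(np.abs(cart.intensities - mode_sum.intensities)) <= 1e-8 * scale
        )

    def test_constant_velocity_with_mean_removal_is_silent(self):
        traj = ms.Trajectory(
            labels=("H",),
            timestep=1.0,
            velocities=np.full((64, 3), 0.3),
        )
        spec = ms.compute_cartesian_spectrum(traj, remove_mean=True)
        assert np.all(spec.intensities == 0)

    def test_zero_velocities_give_zero_spectrum(self):
        traj = ms.Trajectory(
            labels=("H",), timestep=1.0, velocities=np.zeros((16, 3))
        )
        spec = ms.compute_cartesian_spectrum(traj, remove_mean=False)
        assert np.all(spec.intensities == 0)


class TestFindPeaks:
    def test_single_cosine_yields_one_peak(self):
        spec = ms.power_spectrum_tavg(cosine_signal(1500.0, 10.0, 2500))
        assert len(ms.find_peaks(spec, 0, 0.1)) == 1

    def test_two_equal_cosines_yield_two_peaks(self):
        dt, n = 10.0, 2500
        omega1 = 1000.0 / units.HARTREE_CM1
        omega2 = 2000.0 / units.HARTREE_CM1
        t = np.arange(n) * dt
        sig = ms.Signal(values=np.cos(omega1 * t) + np.cos(omega2 * t + 0.7), timestep=dt)
        spec = ms.power_spectrum_tavg(sig, (500.0, 2500.0))
        peaks = ms.find_peaks(spec, 0, 0.3)
        spacing = spec.frequencies[1] - spec.frequencies[0]
        assert len(peaks) == 2
        assert abs(peaks[0][0] - 1000.0) <= spacing
        assert abs(peaks[1][0] - 2000.0) <= spacing

    def test_flat_spectrum_has_no_peaks(self):
        spec = ms.PowerSpectrum(
            frequencies=np.linspace(0, 100, 11),
            intensities=np.ones(11),
            labels=("signal",),
            total_time=1.0,
        )
        assert ms.find_peaks(spec) == []

    def test_threshold_bounds(self):
        spec = ms.power_spectrum_tavg(cosine_signal(1500.0, 10.0, 500))
        with pytest.raises(ValueError):
            ms.find_peaks(spec, 0, 0.0)
        with pytest.raises(ValueError):
            ms.find_peaks(spec, 0, 1.5)
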