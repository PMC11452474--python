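"""Parzen-tapered spectra, WPLI estimation and band averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phaseconn as pc
from phaseconn.spectral import BandScheme

from conftest import wpli_literal


def _tone_epochs(freq, n_trials=3, fs=500.0, dur=10.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t + phase)
    data = np.tile(x, (n_trials, 1, 1))
    return pc.EpochSet(data, fs, 0.0, "rep1", "s", ("Cz",))


class TestComputeSpectra:
    def test_default_grid_is_83_half_hz_bins(self):
        sp = pc.compute_spectra(_tone_epochs(10.0))
        assert len(sp.freqs) == 83
        np.testing.assert_allclose(sp.freqs, np.arange(4.0, 45.01, 0.5))

    def test_tone_peaks_at_its_bin(self):
        sp = pc.compute_spectra(_tone_epochs(10.0))
        mag = np.abs(sp.coef[0, 0])
        peak = int(np.argmax(mag))
        assert sp.freqs[peak] == 10.0
        far = np.abs(sp.freqs - 10.0) >= 1.0
        assert mag[peak] >= 10 * mag[far].max()

    def test_zero_epoch_gives_zero_coefficients(self):
        ep = pc.EpochSet(np.zeros((2, 1, 5000)), 500.0, 0.0, "rep1", "s", ("Cz",))
        sp = pc.compute_spectra(ep)
        assert np.all(sp.coef == 0)

    def test_incompatible_resolution_rejected(self):
        ep = pc.EpochSet(np.zeros((2, 1, 4999)), 500.0, 0.0, "rep1", "s", ("Cz",))
        with pytest.raises(ValueError, match="resolution"):
            pc.compute_spectra(ep)


class TestWPLI:
    def test_printed_formula_hand_case(self):
        # trial-wise Im(S) = {+2, -1, +3} -> |4| / 6
        coef = np.zeros((3, 2, 1), dtype=complex)
        coef[:, 0, 0] = 1.0
        coef[:, 1, 0] = [-2j, 1j, -3j]
        conn = pc.wpli_from_spectra(pc.SpectralTensor(coef, np.array([10.0]),
                                                      ("a", "b")))
        assert conn.values[0, 1, 0] == pytest.approx(4.0 / 6.0, abs=1e-12)

    def test_quarter_cycle_lagged_copy_gives_one(self, rng):
        z = rng.normal(size=(6, 1, 5)) + 1j * rng.normal(size=(6, 1, 5))
        coef = np.concatenate([z, z * np.exp(-1j * np.pi / 2)], axis=1)
        conn = pc.wpli_from_spectra(pc.SpectralTensor(coef, np.arange(5.0),
                                                      ("a", "b")))
        np.testing.assert_allclose(conn.values[0, 1], 1.0, atol=1e-12)

    def test_zero_lag_copy_gives_zero_with_flag(self, rng):
        z = rng.normal(size=(6, 1, 5)) + 1j * rng.normal(size=(6, 1, 5))
        coef = np.concatenate([z, z], axis=1)
        conn = pc.wpli_from_spectra(pc.SpectralTensor(coef, np.arange(5.0),
                                                      ("a", "b")))
        np.testing.assert_array_equal(conn.values[0, 1], 0.0)
        assert conn.degenerate[0, 1].all()

    def test_single_trial_rejected(self):
        coef = np.ones((1, 2, 3), dtype=complex)
        with pytest.raises(ValueError):
            pc.wpli_from_spectra(pc.SpectralTensor(coef, np.arange(3.0),
                                                   ("a", "b")))

    def test_vectorized_equals_literal_formula_on_random_spectra(self, rng):
        """The vectorized estimator and a literal per-trial loop over the
        definition agree to 1e-12 on 100 random spectral tensors."""
        for _ in range(100):
            coef = rng.normal(size=(5, 4, 6)) + 1j * rng.normal(size=(5, 4, 6))
            conn = pc.wpli_from_spectra(
                pc.SpectralTensor(coef, np.arange(6.0), ("a", "b", "c", "d")))
            oracle = wpli_literal(coef)
            np.testing.assert_allclose(conn.values, oracle, atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_magnitude_bounded_and_symmetric(self, seed):
        r = np.random.default_rng(seed)
        coef = r.normal(size=(4, 3, 4)) + 1j * r.normal(size=(4, 3, 4))
        conn = pc.wpli_from_spectra(
            pc.SpectralTensor(coef, np.arange(4.0), ("a", "b", "c")))
        assert np.all(conn.values <= 1.0 + 1e-12)
        assert np.all(conn.values >= 0.0)
        np.testing.assert_allclose(conn.values,
                                   conn.values.transpose(1, 0, 2), atol=1e-12)
        assert np.all(conn.values[np.arange(3), np.arange(3), :] == 0)

    def test_constant_imaginary_sign_saturates_at_one(self, rng):
        """WPLI = 1 iff Im(S) keeps one sign across trials."""
        phases = rng.uniform(0.1, np.pi - 0.1, size=(7, 1))  # all positive lags
        z = rng.lognormal(size=(7, 1)) * np.exp(1j * rng.uniform(0, 2 * np.pi, (7, 1)))
        coef = np.concatenate([z[:, None, :], (z * np.exp(-1j * phases))[:, None, :]],
                              axis=1)
        conn = pc.wpli_from_spectra(pc.SpectralTensor(coef, np.array([8.0]),
                                                      ("a", "b")))
        assert conn.values[0, 1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_lag_mixture_wpli_vanishes_with_trials(self):
        """Channels that are instantaneous mixtures of shared sources plus
        independent noise show near-zero WPLI at high trial counts."""
        rng = np.random.default_rng(3)
        n_tr, n_samp, fs = 200, 5000, 500.0
        shared = rng.standard_normal((n_tr, 1, n_samp))
        mix = np.array([[1.0], [0.6]])  # instantaneous mixing into 2 channels
        data = mix[None, :, :] * shared + 0.5 * rng.standard_normal((n_tr, 2, n_samp))
        ep = pc.EpochSet(data, fs, 0.0, "rep1", "s", ("a", "b"))
        conn = pc.epochs_to_band_wpli(ep)
        assert conn.values[0, 1].mean() < 0.1


class TestBandAverage:
    def test_theta_members_are_exactly_six_bins(self):
        scheme = BandScheme()
        freqs = np.arange(4.0, 45.01, 0.5)
        members = freqs[scheme.members("theta", freqs)]
        np.testing.assert_allclose(members, [5.0, 5.5, 6.0, 6.5, 7.0, 7.5])

    def test_no_bin_in_two_bands_and_gap_bins_excluded(self):
        scheme = BandScheme()
        freqs = np.arange(4.0, 45.01, 0.5)
        counts = np.zeros(len(freqs))
        for name in scheme.names:
            counts[scheme.members(name, freqs)] += 1
        assert counts.max() == 1
        gap = [np.flatnonzero(freqs == f)[0] for f in (4.0, 4.5, 22.0, 22.5)]
        assert all(counts[g] == 0 for g in gap)

    def test_hand_mean(self):
        freqs = np.arange(4.0, 45.01, 0.5)
        values = np.zeros((2, 2, 83))
        theta = BandScheme().members("theta", freqs)
        values[0, 1, theta[-1]] = values[1, 0, theta[-1]] = 0.6
        conn = pc.ConnectivityMatrix(values, ("a", "b"), "freq", tuple(freqs))
        out = pc.band_average(conn)
        assert out.values[0, 1, 0] == pytest.approx(0.1)

    def test_constant_bins_average_to_constant(self):
        freqs = np.arange(4.0, 45.01, 0.5)
        values = np.full((2, 2, 83), 0.4)
        conn = pc.ConnectivityMatrix(values, ("a", "b"), "freq", tuple(freqs))
        out = pc.band_average(conn)
        np.testing.assert_allclose(out.values, 0.4)

    def test_empty_band_rejected_by_name(self):
        freqs = np.arange(4.0, 45.01, 0.5)
        conn = pc.ConnectivityMatrix(np.zeros((2, 2, 83)), ("a", "b"),
                                     "freq", tuple(freqs))
        scheme = BandScheme(bands=(("theta", (5.0, 8.0)),
                                   ("nothing", (45.5, 46.0))))
        with pytest.raises(ValueError, match="nothing"):
            pc.band_average(conn, scheme)
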