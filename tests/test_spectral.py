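"""Amplitude spectra and the neighbourhood SNR statistic."""

import numpy as np
import pytest

from freqtag import spectral

FS = 1000.0
N = 20_000  # 20 s -> 0.05 Hz bins


def _sinusoid(f, amp=1.0, phase=0.3, n_ch=2):
    t = np.arange(N) / FS
    x = amp * np.sin(2 * np.pi * f * t + phase)
    return np.tile(x, (n_ch, 1))


def _flat_spectrum(value=1.0, n_ch=3, n_bins=801):
    freqs = np.arange(n_bins) * 0.05
    return spectral.AmplitudeSpectrum(
        amplitudes=np.full((n_ch, n_bins), value), freqs=freqs
    )


# --- amplitude spectrum -------------------------------------------------------


def test_bin_exact_frequencies():
    spec = spectral.amplitude_spectrum(_sinusoid(6.0), fs=FS)
    assert spec.df == pytest.approx(0.05)
    assert spec.bin_of(6.0) == 120
    assert spec.bin_of(3.0) == 60


def test_off_bin_frequency_rejected():
    spec = spectral.amplitude_spectrum(_sinusoid(6.0), fs=FS)
    with pytest.raises(ValueError):
        spec.bin_of(6.013)
    with pytest.raises(ValueError):
        spec.bin_of(1e6)


def test_pure_sinusoid_concentrates_in_one_bin():
    spec = spectral.amplitude_spectrum(_sinusoid(6.0, amp=2.0), fs=FS)
    k = spec.bin_of(6.0)
    peak = spec.amplitudes[0, k]
    others = np.delete(spec.amplitudes[0], k)
    assert peak == pytest.approx(2.0 * N / 2, rel=1e-9)  # rFFT magnitude N*amp/2
    assert others.max() < 1e-9 * peak


def test_amplitude_scales_linearly():
    a = spectral.amplitude_spectrum(_sinusoid(6.0, amp=1.0), fs=FS)
    b = spectral.amplitude_spectrum(_sinusoid(6.0, amp=3.0), fs=FS)
    np.testing.assert_allclose(b.amplitudes, 3.0 * a.amplitudes, atol=1e-9)


def test_direct_summation_dft_oracle():
    """rFFT amplitude equals the textbook DFT sum to 1e-9 relative."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(N)
    spec = spectral.amplitude_spectrum(x[None, :], fs=FS)
    n = np.arange(N)
    for f in (3.0, 6.0, 9.0, 24.0):
        k = spec.bin_of(f)
        oracle = abs(np.sum(x * np.exp(-2j * np.pi * k * n / N)))
        assert spec.amplitudes[0, k] == pytest.approx(oracle, rel=1e-9)


def test_raw_array_requires_fs():
    with pytest.raises(ValueError):
        spectral.amplitude_spectrum(np.zeros((2, 100)))


# --- SNR ----------------------------------------------------------------------


def test_snr_on_flat_spectrum_is_one():
    spec = _flat_spectrum(value=7.5)
    np.testing.assert_allclose(spectral.snr_at(spec, 6.0), 1.0)


def test_snr_is_scale_invariant():
    rng = np.random.default_rng(1)
    amps = rng.random((4, 801)) + 0.1
    freqs = np.arange(801) * 0.05
    a = spectral.AmplitudeSpectrum(amps, freqs)
    b = spectral.AmplitudeSpectrum(1234.5 * amps, freqs)
    np.testing.assert_allclose(
        spectral.snr_at(a, 6.0), spectral.snr_at(b, 6.0), rtol=1e-12
    )


def test_snr_ratio_three_to_one():
    spec = _flat_spectrum(value=2.0)
    k = spec.bin_of(6.0)
    spec.amplitudes[:, k] = 6.0
    np.testing.assert_allclose(spectral.snr_at(spec, 6.0), 3.0)


def test_snr_neighbourhood_skips_adjacent_bins():
    spec = _flat_spectrum(value=1.0)
    k = spec.bin_of(6.0)
    # contaminate only the immediately adjacent bins: SNR must not change
    spec.amplitudes[:, [k - 1, k + 1]] = 50.0
    np.testing.assert_allclose(spectral.snr_at(spec, 6.0), 1.0)


def test_snr_requires_neighbourhood_margin():
    spec = _flat_spectrum()
    with pytest.raises(ValueError):
        spectral.snr_at(spec, 0.1)  # bin 2, needs bins down to -4


def test_neighborhood_slice_consistent_with_snr_at():
    rng = np.random.default_rng(2)
    amps = rng.random((5, 801)) + 0.05
    spec = spectral.AmplitudeSpectrum(amps, np.arange(801) * 0.05)
    for f in (3.0, 6.0, 9.0):
        nb = spectral.neighborhood_amplitudes(spec, f)
        assert nb.shape == (5, 11)
        np.testing.assert_allclose(
            spectral.snr_from_neighborhood(nb), spectral.snr_at(spec, f), rtol=1e-12
        )


def test_snr_of_averaged_neighbourhoods_matches_averaged_spectrum():
    rng = np.random.default_rng(3)
    specs = [
        spectral.AmplitudeSpectrum(rng.random((3, 801)) + 0.1, np.arange(801) * 0.05)
        for _ in range(4)
    ]
    nbs = np.mean([spectral.neighborhood_amplitudes(s, 6.0) for s in specs], axis=0)
    mean_amps = np.mean([s.amplitudes for s in specs], axis=0)
    mean_spec = spectral.AmplitudeSpectrum(mean_amps, specs[0].freqs)
    np.testing.assert_allclose(
        spectral.snr_from_neighborhood(nbs), spectral.snr_at(mean_spec, 6.0), rtol=1e-12
    )


def test_white_noise_snr_near_one_on_average():
    rng = np.random.default_rng(4)
    spec = spectral.amplitude_spectrum(rng.standard_normal((8, N)), fs=FS)
    snr = spectral.snr_spectrum(spec)
    mean = np.nanmean(snr)
    assert 0.95 < mean < 1.1  # ratio statistic has a small positive bias


def test_snr_spectrum_nan_guard_at_edges():
    spec = _flat_spectrum()
    out = spectral.snr_spectrum(spec)
    assert np.isnan(out[:, :6]).all()
    assert np.isnan(out[:, -6:]).all()
    np.testing.assert_allclose(out[:, 6:-6], 1.0)


def test_noiseless_peak_snr_is_finite_and_large():
    spec = spectral.amplitude_spectrum(_sinusoid(6.0), fs=FS)
    snr = spectral.snr_at(spec, 6.0)
    assert np.all(np.isfinite(snr))
    assert np.all(snr > 1e6)


def test_power_at_is_squared_amplitude():
    spec = _flat_spectrum(value=3.0)
    np.testing.assert_allclose(spectral.power_at(spec, 6.0), 9.0)


# --- harmonic families --------------------------------------------------------


def test_candidate_families_are_disjoint_and_cover_range():
    base = spectral.base_candidates(2.0, 36.0)
    doublet = spectral.doublet_candidates(2.0, 36.0)
    assert base == (6.0, 12.0, 18.0, 24.0, 30.0, 36.0)
    assert doublet == (3.0, 9.0, 15.0, 21.0, 27.0, 33.0)
    assert not set(base) & set(doublet)


def test_harmonic_set_validation():
    spectral.HarmonicSet("base", (6.0, 12.0))
    spectral.HarmonicSet("doublet", (3.0, 9.0))
    with pytest.raises(ValueError):
        spectral.HarmonicSet("base", (9.0,))
    with pytest.raises(ValueError):
        spectral.HarmonicSet("doublet", (12.0,))


def test_aggregate_harmonics_mean_and_missing_key():
    hs = spectral.HarmonicSet("base", (6.0, 12.0))
    vals = {6.0: np.array([2.0, 4.0]), 12.0: np.array([4.0, 0.0])}
    np.testing.assert_allclose(spectral.aggregate_harmonics(vals, hs), [3.0, 2.0])
    with pytest.raises(KeyError):
        spectral.aggregate_harmonics({6.0: np.ones(2)}, hs)


def test_dominant_frequency_tie_prefers_lower():
    hs = spectral.HarmonicSet("base", (6.0, 12.0))
    assert spectral.dominant_frequency({6.0: 2.0, 12.0: 2.0}, hs) == 6.0
    assert spectral.dominant_frequency({6.0: 1.0, 12.0: 2.0}, hs) == 12.0
    with pytest.raises(ValueError):
        spectral.dominant_frequency({}, spectral.HarmonicSet("base", ()))
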