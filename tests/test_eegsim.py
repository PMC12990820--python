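"""Synthetic EEG: spectral purity, triggers, looking gates, noise, cohorts."""

import numpy as np
import pandas as pd
import pytest

from freqtag import eegsim, preprocess, spectral, stimgen

STIM_FREQS = (3.0, 6.0, 9.0, 12.0, 18.0, 24.0)


def test_noiseless_spectrum_is_pure(noiseless_recording):
    """With zero noise and full looking, energy sits only in stimulation bins."""
    segs = preprocess.segment_trials(noiseless_recording)
    spec = spectral.amplitude_spectrum(segs[0])
    stim_bins = [spec.bin_of(f) for f in STIM_FREQS]
    mask = np.ones(spec.freqs.size, dtype=bool)
    mask[stim_bins] = False
    peak = spec.amplitudes.max()
    assert peak > 0
    assert spec.amplitudes[:, mask].max() < 1e-9 * peak


def test_noiseless_peak_amplitude_ordering(noiseless_recording):
    """Base-harmonic amplitudes fall off with harmonic order at the ROI."""
    segs = preprocess.segment_trials(noiseless_recording)
    spec = spectral.amplitude_spectrum(segs[0])
    ch = noiseless_recording.montage.index([75])[0]
    amps = [spec.amplitudes[ch, spec.bin_of(f)] for f in (6.0, 12.0, 18.0, 24.0)]
    assert amps == sorted(amps, reverse=True)


def test_trigger_count_and_spacing(noiseless_recording):
    rec = noiseless_recording
    assert len(rec.events) == 2 * 120
    for k in (0, 1):
        ev = rec.events[rec.events["trial"] == k]
        assert len(ev) == 120
        start = rec.trials.loc[rec.trials["trial"] == k, "core_start"].iloc[0]
        expected = start + np.round(np.arange(120) * 1000 / 6).astype(int)
        np.testing.assert_array_equal(ev["sample"].to_numpy(), expected)


def test_simulation_deterministic_under_seed(montage):
    kw = dict(
        condition="control",
        n_trials=2,
        profile=eegsim.default_profiles()["control"],
        noise=eegsim.NoiseSpec(scale=2.0),
        montage=montage,
    )
    a = eegsim.simulate_subject(rng=np.random.default_rng(5), **kw)
    b = eegsim.simulate_subject(rng=np.random.default_rng(5), **kw)
    np.testing.assert_array_equal(a.signal, b.signal)
    pd.testing.assert_frame_equal(a.events, b.events)


def test_random_condition_rejects_doublet_response(montage):
    with pytest.raises(ValueError):
        eegsim.simulate_subject(
            "random",
            n_trials=1,
            profile=eegsim.ResponseProfile(base_amps={6.0: 1.0}, doublet_amps={3.0: 0.5}),
            noise=eegsim.NoiseSpec(scale=0.0),
            montage=montage,
        )


def test_zero_looking_trial_has_no_response(montage):
    rec = eegsim.simulate_subject(
        "doublet",
        n_trials=2,
        profile=eegsim.default_profiles()["doublet"],
        noise=eegsim.NoiseSpec(scale=0.0, channel_jitter_sd=0.0),
        montage=montage,
        rng=np.random.default_rng(6),
        looking=np.array([0.0, 20.0]),
    )
    segs = preprocess.segment_trials(rec)
    assert np.abs(segs[0].signal).max() == 0.0
    assert np.abs(segs[1].signal).max() > 0.0


def test_partial_looking_gates_response(montage):
    rec = eegsim.simulate_subject(
        "doublet",
        n_trials=1,
        profile=eegsim.default_profiles()["doublet"],
        noise=eegsim.NoiseSpec(scale=0.0, channel_jitter_sd=0.0),
        montage=montage,
        rng=np.random.default_rng(7),
        looking=np.array([8.0]),
    )
    seg = preprocess.segment_trials(rec)[0]
    assert np.abs(seg.signal[:, :8000]).max() > 0.0
    assert np.abs(seg.signal[:, 8000:]).max() == 0.0


def test_occipital_gain_peaks_over_occipital_cluster(montage):
    gain = eegsim.occipital_gain(montage, eegsim.default_profiles()["doublet"])
    occ = montage.index(montage.occipital_10)
    rest = np.setdiff1d(np.arange(montage.n_channels), occ)
    assert gain[occ].mean() > 3 * gain[rest].mean()
    assert gain.min() >= 0.05


def test_one_over_f_noise_scale_and_slope():
    noise = eegsim.NoiseSpec(exponent=1.0, scale=4.0, channel_jitter_sd=0.0)
    x = eegsim.one_over_f_noise(4, 20_000, noise, np.random.default_rng(8))
    np.testing.assert_allclose(x.std(axis=1), 4.0, rtol=1e-6)
    spec = np.abs(np.fft.rfft(x, axis=1)).mean(axis=0)
    low = spec[20:200].mean()
    high = spec[5000:9000].mean()
    assert low > 3 * high  # power falls with frequency


def test_zero_noise_scale_returns_silence():
    x = eegsim.one_over_f_noise(3, 1000, eegsim.NoiseSpec(scale=0.0), np.random.default_rng(9))
    assert np.all(x == 0.0)


def test_negative_noise_scale_rejected():
    with pytest.raises(ValueError):
        eegsim.NoiseSpec(scale=-1.0)


def test_looking_spec_samples_within_core():
    looks = eegsim.LookingSpec().sample_seconds(500, 20.0, np.random.default_rng(10))
    assert looks.min() >= 0.0 and looks.max() <= 20.0


def test_corrupt_channels_ground_truth(noisy_recording):
    noise = eegsim.NoiseSpec(scale=6.0, n_bad=18, bad_gain=20.0)
    rec = eegsim.corrupt_channels(noisy_recording, noise, np.random.default_rng(12))
    assert len(rec.bad_channels) == 18
    assert all(1 <= c <= 128 for c in rec.bad_channels)
    bad_idx = np.asarray(rec.bad_channels) - 1
    good_idx = np.setdiff1d(np.arange(128), bad_idx)
    assert rec.signal[bad_idx].std(axis=1).min() > 10 * np.median(
        rec.signal[good_idx].std(axis=1)
    )
    # original recording untouched
    assert noisy_recording.bad_channels == ()


def test_corrupt_channels_noop_without_bad():
    rec = object()  # never touched when n_bad == 0
    assert eegsim.corrupt_channels(rec, eegsim.NoiseSpec(n_bad=0), np.random.default_rng(0)) is rec


def test_plan_cohort_design():
    design = eegsim.CohortDesign()
    plan = eegsim.plan_cohort(design, np.random.default_rng(13))
    assert len(plan) == 30
    assert plan["condition"].value_counts().to_dict() == {c: 10 for c in stimgen.CONDITIONS}
    assert plan["subject_id"].is_unique
    assert plan["n_trials"].between(4, 18).all()
    assert plan["age_days"].between(120, 195).all()


def test_default_profiles_conditions():
    profiles = eegsim.default_profiles()
    assert set(profiles) == set(stimgen.CONDITIONS)
    assert profiles["random"].doublet_amps == {}
    assert profiles["doublet"].doublet_amps[9.0] > profiles["control"].doublet_amps[9.0]
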