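"""Shared fixtures: montage and small seeded synthetic recordings."""

from __future__ import annotations

import numpy as np
import pytest

from freqtag import eegsim
from freqtag.montage import MontageSpec, hydrocel_128


@pytest.fixture(scope="session")
def montage() -> MontageSpec:
    return hydrocel_128()


@pytest.fixture(scope="session")
def noiseless_recording(montage) -> eegsim.SyntheticRecording:
    """Two doublet-condition trials, zero noise, full looking.

    With no noise and 20 s of looking per trial the core segments contain
    pure bin-exact sinusoids, so spectra are analytically predictable.
    """
    profile = eegsim.default_profiles()["doublet"]
    noise = eegsim.NoiseSpec(scale=0.0, channel_jitter_sd=0.0)
    return eegsim.simulate_subject(
        "doublet",
        n_trials=2,
        profile=profile,
        noise=noise,
        montage=montage,
        rng=np.random.default_rng(11),
        looking=np.full(2, 20.0),
    )


@pytest.fixture(scope="session")
def noisy_recording(montage) -> eegsim.SyntheticRecording:
    """Four doublet-condition trials at the default noise calibration."""
    profile = eegsim.default_profiles()["doublet"]
    return eegsim.simulate_subject(
        "doublet",
        n_trials=4,
        profile=profile,
        noise=eegsim.DEFAULT_NOISE,
        montage=montage,
        rng=np.random.default_rng(21),
        looking=np.full(4, 20.0),
    )
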