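"""Amplitude spectra and the local signal-to-noise ratio (SNR) statistic.

The response strength at a tagged frequency is quantified per trial and
channel as the ratio between the Fourier amplitude at that frequency and the
mean amplitude of the 10 surrounding bins — 5 per side, skipping the bin
immediately adjacent on each side (offsets ±2..±6).  An SNR of 1 is the
noise level.  With 20-s segments the bin spacing is 0.05 Hz, so 6 Hz sits
exactly on bin 120 and all stimulation frequencies are bin-exact.

No taper, detrending or zero-padding is applied before the FFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TrialSegment

#: neighbourhood of the SNR statistic: bin offsets averaged as "noise"
NEIGHBOR_OFFSETS = (-6, -5, -4, -3, -2, 2, 3, 4, 5, 6)


@dataclass
class AmplitudeSpectrum:
    """Per-channel Fourier amplitude on the segment's frequency grid."""

    amplitudes: np.ndarray  # (n_channels, n_bins), >= 0
    freqs: np.ndarray       # (n_bins,), 0 .. Nyquist

    @property
    def df(self) -> float:
        """Bin spacing in Hz (1 / segment duration)."""
        return float(self.freqs[1] - self.freqs[0])

    def bin_of(self, f: float) -> int:
        """Index of an on-bin frequency; off-bin frequencies are rejected."""
        k = f / self.df
        if abs(k - round(k)) > 1e-6:
            raise ValueError(f"{f} Hz is not on the {self.df} Hz frequency grid")
        k = int(round(k))
        if not 0 <= k < self.freqs.size:
            raise ValueError(f"{f} Hz outside the spectrum")
        return k


@dataclass(frozen=True)
class HarmonicSet:
    """A family of analyzed frequencies with its dominant member."""

    family: str                    # "base" or "doublet"
    frequencies: tuple[float, ...]
    dominant: float | None = None

    def __post_init__(self) -> None:
        for f in self.frequencies:
            if self.family == "base":
                ok = f % 6 == 0
            else:
                # odd multiples of 3: doublet rate and harmonics that do not
                # coincide with the 6 Hz base-rate harmonics
                ok = f % 3 == 0 and f % 6 != 0
            if not ok:
                raise ValueError(f"{f} Hz is not a valid {self.family} family member")


def base_candidates(fmin: float = 2.0, fmax: float = 36.0) -> tuple[float, ...]:
    """Multiples of 6 Hz inside the analysis range."""
    return tuple(f for f in np.arange(6.0, fmax + 1e-9, 6.0) if f >= fmin)


def doublet_candidates(fmin: float = 2.0, fmax: float = 36.0) -> tuple[float, ...]:
    """Odd multiples of 3 Hz (never multiples of 6) inside the range."""
    return tuple(
        f for f in np.arange(3.0, fmax + 1e-9, 6.0) if fmin <= f <= fmax
    )


def amplitude_spectrum(
    seg: TrialSegment | np.ndarray, fs: float | None = None
) -> AmplitudeSpectrum:
    """FFT amplitude of a trial segment (no taper, no detrend).

    Accepts a :class:`TrialSegment` or a raw (channels x samples) array with
    ``fs``.  Amplitude is the rFFT magnitude; any constant scaling cancels in
    the SNR ratio.
    """
    if isinstance(seg, TrialSegment):
        signal, fs = seg.signal, seg.fs
    else:
        signal = np.atleast_2d(np.asarray(seg, dtype=float))
        if fs is None:
            raise ValueError("fs required for raw arrays")
    n = signal.shape[1]
    amps = np.abs(np.fft.rfft(signal, axis=1))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return AmplitudeSpectrum(amplitudes=amps, freqs=freqs)


def snr_at(spec: AmplitudeSpectrum, f: float) -> np.ndarray:
    """Per-channel SNR at an on-bin frequency.

    SNR = amplitude(f) / mean(amplitude at bin offsets ±2..±6).  The
    neighbour mean is floored at machine epsilon times the spectrum scale so
    noiseless synthetic input yields large finite values rather than inf.
    """
    k = spec.bin_of(f)
    lo, hi = k + min(NEIGHBOR_OFFSETS), k + max(NEIGHBOR_OFFSETS)
    if lo < 0 or hi >= spec.freqs.size:
        raise ValueError(f"{f} Hz lacks the ±6-bin neighbourhood margin")
    neighbors = spec.amplitudes[:, [k + o for o in NEIGHBOR_OFFSETS]]
    denom = neighbors.mean(axis=1)
    floor = np.finfo(float).eps * max(float(spec.amplitudes.max()), 1.0)
    return spec.amplitudes[:, k] / np.maximum(denom, floor)


def neighborhood_amplitudes(spec: AmplitudeSpectrum, f: float) -> np.ndarray:
    """Center-bin and neighbour amplitudes at ``f``: (n_channels, 11).

    Column 0 is the tagged bin; columns 1..10 the SNR neighbourhood.  These
    compact slices are sufficient to compute the SNR either per trial or on
    trial-averaged spectra (average the slices over trials, then take the
    ratio) without retaining full spectra.
    """
    k = spec.bin_of(f)
    lo, hi = k + min(NEIGHBOR_OFFSETS), k + max(NEIGHBOR_OFFSETS)
    if lo < 0 or hi >= spec.freqs.size:
        raise ValueError(f"{f} Hz lacks the ±6-bin neighbourhood margin")
    cols = [k] + [k + o for o in NEIGHBOR_OFFSETS]
    return spec.amplitudes[:, cols]


def snr_from_neighborhood(nb: np.ndarray) -> np.ndarray:
    """SNR from a neighbourhood slice (last axis: center + 10 neighbours)."""
    nb = np.asarray(nb, dtype=float)
    denom = nb[..., 1:].mean(axis=-1)
    floor = np.finfo(float).eps * max(float(nb.max()), 1.0)
    return nb[..., 0] / np.maximum(denom, floor)


def snr_spectrum(spec: AmplitudeSpectrum) -> np.ndarray:
    """SNR at every bin with a full neighbourhood (NaN in the edge guard)."""
    n_ch, n_bins = spec.amplitudes.shape
    out = np.full((n_ch, n_bins), np.nan)
    margin = max(abs(o) for o in NEIGHBOR_OFFSETS)
    offs = np.array(NEIGHBOR_OFFSETS)
    for k in range(margin, n_bins - margin):
        denom = spec.amplitudes[:, k + offs].mean(axis=1)
        floor = np.finfo(float).eps * max(float(spec.amplitudes.max()), 1.0)
        out[:, k] = spec.amplitudes[:, k] / np.maximum(denom, floor)
    return out


def power_at(spec: AmplitudeSpectrum, f: float) -> np.ndarray:
    """Raw spectral power (amplitude squared) at an on-bin frequency.

    Exposed as the power-based variant of the response measure; the SNR is
    the primary statistic everywhere in this package.
    """
    return spec.amplitudes[:, spec.bin_of(f)] ** 2


def aggregate_harmonics(
    snr_values: dict[float, np.ndarray], hs: HarmonicSet
) -> np.ndarray:
    """Arithmetic mean of per-channel SNR across the set's frequencies."""
    missing = [f for f in hs.frequencies if f not in snr_values]
    if missing:
        raise KeyError(f"missing SNR values at {missing} Hz")
    return np.mean([snr_values[f] for f in hs.frequencies], axis=0)


def dominant_frequency(group_mean_snr: dict[float, float], hs: HarmonicSet) -> float:
    """Family member with the highest group-mean response (ties -> lower f)."""
    if not hs.frequencies:
        raise ValueError("empty harmonic set")
    best = None
    for f in sorted(hs.frequencies):
        v = group_mean_snr[f]
        if best is None or v > best[1]:
            best = (f, v)
    return best[0]
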