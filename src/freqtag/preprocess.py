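"""Simplified preprocessing: average reference, channel repair, segmentation.

This is deliberately lighter than a full robust-preprocessing pipeline: the
downstream statistics depend only on gross channel health, so noisy channels
are flagged by a robust variance z-score and repaired by neighbour-mean
interpolation, iterating up to three times.  No filtering, detrending or
tapering is applied; stimulation frequencies are bin-exact in the 20-s
segments so spectral leakage is structural rather than windowing-dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .eegsim import SyntheticRecording

logger = logging.getLogger(__name__)

MAX_INTERPOLATION_PASSES = 3


@dataclass
class TrialSegment:
    """One 20-s trial core: channels x 20,000 samples, fades excluded."""

    signal: np.ndarray
    trial: int                  # acquisition order, 0-based
    condition: str
    subject_id: str
    looking_s: float
    age_days: float
    fs: float

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def rereference_average(rec: SyntheticRecording) -> SyntheticRecording:
    """Re-reference to the average of all channels (column means become 0)."""
    if rec.signal.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    signal = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return replace(rec, signal=signal)


def _robust_variance_z(signal: np.ndarray) -> np.ndarray:
    """Robust z-score of per-channel log variance (median/MAD based)."""
    logvar = np.log(signal.var(axis=1) + np.finfo(float).tiny)
    med = np.median(logvar)
    mad = np.median(np.abs(logvar - med))
    scale = 1.4826 * mad
    if scale <= 0:
        return np.zeros_like(logvar)
    return (logvar - med) / scale


def detect_and_interpolate(
    rec: SyntheticRecording,
    z_threshold: float = 3.0,
    max_passes: int = MAX_INTERPOLATION_PASSES,
) -> tuple[SyntheticRecording, list[int]]:
    """Detect high-variance channels and repair them from their neighbours.

    Channels whose robust log-variance z exceeds ``z_threshold`` are replaced
    by the mean of their non-bad neighbours; detection is re-run on the
    repaired signal, up to ``max_passes`` times.  Returns the repaired
    recording and the sorted 1-based numbers of repaired channels.
    """
    signal = rec.signal.copy()
    adjacency = rec.montage.adjacency
    repaired: set[int] = set()

    for _ in range(max_passes):
        z = _robust_variance_z(signal)
        bad = np.flatnonzero(z > z_threshold)
        if bad.size == 0:
            break
        if bad.size >= signal.shape[0] - 1:
            raise RuntimeError(
                f"channel repair aborted: {bad.size}/{signal.shape[0]} channels "
                f"flagged bad at z>{z_threshold}"
            )
        bad_set = set(bad.tolist())
        for ch in bad:
            donors = [n for n in np.flatnonzero(adjacency[ch]) if n not in bad_set]
            if not donors:  # fall back to all neighbours
                donors = list(np.flatnonzero(adjacency[ch]))
            signal[ch] = signal[donors].mean(axis=0)
            repaired.add(int(ch) + 1)

    return replace(rec, signal=signal), sorted(repaired)


def segment_trials(rec: SyntheticRecording) -> list[TrialSegment]:
    """Cut the continuous signal into per-trial 20-s cores.

    Each segment starts at the trial's first non-fade trigger and spans
    ``core_s`` seconds (20,000 samples at 1000 Hz); segmentation is pure
    slicing.  Trials whose triggers are missing are dropped with a warning.
    """
    if rec.events.empty:
        raise ValueError("recording has no trigger events")
    n_core = round(rec.timing.core_s * rec.fs)
    segments: list[TrialSegment] = []
    for _, trow in rec.trials.iterrows():
        ev = rec.events[rec.events["trial"] == trow["trial"]]
        if ev.empty:
            logger.warning(
                "subject %s trial %s has no triggers; dropped",
                rec.subject_id,
                trow["trial"],
            )
            continue
        start = int(ev["sample"].min())
        if start + n_core > rec.signal.shape[1]:
            logger.warning(
                "subject %s trial %s truncated at end of recording; dropped",
                rec.subject_id,
                trow["trial"],
            )
            continue
        segments.append(
            TrialSegment(
                signal=rec.signal[:, start : start + n_core],
                trial=int(trow["trial"]),
                condition=str(trow["condition"]),
                subject_id=rec.subject_id,
                looking_s=float(trow["looking_s"]),
                age_days=rec.age_days,
                fs=rec.fs,
            )
        )
    return segments


def preprocess_recording(
    rec: SyntheticRecording, z_threshold: float = 3.0
) -> tuple[list[TrialSegment], list[int]]:
    """Repair noisy channels, average reference, and segment; one call.

    Repair precedes referencing so corrupted channels cannot leak into the
    common average (the robust-reference idea, simplified).
    """
    rec, repaired = detect_and_interpolate(rec, z_threshold=z_threshold)
    rec = rereference_average(rec)
    return segment_trials(rec), repaired
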