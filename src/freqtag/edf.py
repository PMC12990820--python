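"""EDF export/import of synthetic recordings, with CSV/JSON sidecars.

Recordings are written as plain EDF (16-bit) — one file per subject — with
channel labels E1..E128 in microvolts.  Trigger events, per-trial metadata
(condition, looking seconds) and subject attributes that EDF cannot carry
travel in sidecar files next to the EDF:

    <stem>.edf            signal
    <stem>_events.csv     trigger sample indices with trial/shape labels
    <stem>_trials.csv     per-trial condition / looking / core-start table
    <stem>_subject.json   subject id, condition, age, timing

Reading goes through :func:`mne.io.read_raw_edf`; the writer is a minimal
EDF encoder (the round trip is exact up to 16-bit quantization of the
per-channel physical range).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .eegsim import SyntheticRecording, Timing
from .montage import MontageSpec, hydrocel_128

DIG_MIN, DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: SyntheticRecording, path: str | Path) -> Path:
    """Write the recording's signal to ``path`` as 16-bit EDF (uV)."""
    path = Path(path)
    signal = np.asarray(rec.signal, dtype=float)
    n_ch, n_samples = signal.shape
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # one-second data records
    n_rec = int(np.ceil(n_samples / spr))

    # symmetric physical range per channel, headroom against clipping
    phys_max = np.maximum(np.abs(signal).max(axis=1) * 1.01, 1e-6)
    pmax_str = [f"{v:.6g}"[:8] for v in phys_max]
    pmin_str = [f"{-v:.6g}"[:8] for v in phys_max]
    pmax_used = np.array([float(s) for s in pmax_str])

    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii(rec.subject_id, 80))
        f.write(_ascii("freqtag synthetic", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(256 * (n_ch + 1), 8))
        f.write(_ascii("", 44))
        f.write(_ascii(n_rec, 8))
        f.write(_ascii(1, 8))
        f.write(_ascii(n_ch, 4))

        labels = [f"E{i}" for i in range(1, n_ch + 1)]
        for lab in labels:
            f.write(_ascii(lab, 16))
        for _ in labels:
            f.write(_ascii("AgAgCl electrode", 80))
        for _ in labels:
            f.write(_ascii("uV", 8))
        for s in pmin_str:
            f.write(_ascii(s, 8))
        for s in pmax_str:
            f.write(_ascii(s, 8))
        for _ in labels:
            f.write(_ascii(DIG_MIN, 8))
        for _ in labels:
            f.write(_ascii(DIG_MAX, 8))
        for _ in labels:
            f.write(_ascii("", 80))
        for _ in labels:
            f.write(_ascii(spr, 8))
        for _ in labels:
            f.write(_ascii("", 32))

        scale = (DIG_MAX - DIG_MIN) / (2.0 * pmax_used)
        padded = np.zeros((n_ch, n_rec * spr))
        padded[:, :n_samples] = signal
        digital = np.clip(
            np.rint(padded * scale[:, None]), DIG_MIN, DIG_MAX
        ).astype("<i2")
        for r in range(n_rec):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def write_sidecar(rec: SyntheticRecording, edf_path: str | Path) -> dict[str, Path]:
    """Write the events/trials/subject sidecars next to ``edf_path``."""
    edf_path = Path(edf_path)
    stem = edf_path.with_suffix("")
    paths = {
        "events": Path(f"{stem}_events.csv"),
        "trials": Path(f"{stem}_trials.csv"),
        "subject": Path(f"{stem}_subject.json"),
    }
    rec.events.to_csv(paths["events"], index=False)
    rec.trials.to_csv(paths["trials"], index=False)
    t = rec.timing
    meta = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "age_days": rec.age_days,
        "fs": rec.fs,
        "n_samples": int(rec.signal.shape[1]),
        "bad_channels": list(rec.bad_channels),
        "timing": {
            "fs": t.fs,
            "rate_hz": t.rate_hz,
            "core_s": t.core_s,
            "fade_s": t.fade_s,
            "gap_s": t.gap_s,
        },
    }
    paths["subject"].write_text(json.dumps(meta, indent=1))
    return paths


def save_recording(rec: SyntheticRecording, edf_path: str | Path) -> Path:
    """Write EDF plus all sidecars; returns the EDF path."""
    edf_path = Path(edf_path)
    write_edf(rec, edf_path)
    write_sidecar(rec, edf_path)
    return edf_path


def load_recording(
    edf_path: str | Path, montage: MontageSpec | None = None
) -> SyntheticRecording:
    """Round-trip reader: EDF signal (via MNE) + sidecar metadata."""
    import mne

    edf_path = Path(edf_path)
    stem = edf_path.with_suffix("")
    meta = json.loads(Path(f"{stem}_subject.json").read_text())
    events = pd.read_csv(f"{stem}_events.csv")
    trials = pd.read_csv(f"{stem}_trials.csv")

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE returns volts for uV-dim channels
    signal = signal[:, : meta["n_samples"]]  # drop final-record padding

    return SyntheticRecording(
        signal=signal,
        fs=float(meta["fs"]),
        events=events,
        trials=trials,
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        age_days=float(meta["age_days"]),
        montage=montage or hydrocel_128(),
        timing=Timing(**meta["timing"]),
        bad_channels=tuple(meta["bad_channels"]),
    )
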