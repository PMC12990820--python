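"""Pipeline configuration: one object, YAML-loadable, hashable for manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import stimgen


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with the design defaults.

    Thresholds: ``snr_valid`` (occipital 6 Hz SNR a trial must exceed),
    ``min_look_s`` (seconds of looking a trial must exceed), ``alpha``
    (harmonic selection, maximum statistics and LRT steps), ``n_perm``
    (permutations for maximum statistics), ``min_order_fraction`` (per-order
    subject retention for the analyzable-order prefix), and the 2-36 Hz
    harmonic search range.
    """

    # design
    n_per_condition: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in stimgen.CONDITIONS}
    )
    trials_mean: float = 10.83
    trials_sd: float = 3.36
    trials_range: tuple[int, int] = (4, 18)
    age_range_days: tuple[float, float] = (120.0, 195.0)

    # synthesis
    noise_scale: float = 6.0
    noise_exponent: float = 1.0
    n_bad_channels: int = 18
    bad_channel_gain: float = 20.0
    write_edf: bool = False

    # thresholds
    snr_valid: float = 2.0
    min_look_s: float = 7.0
    min_valid_trials: int = 2
    alpha: float = 0.05
    n_perm: int = 10_000
    min_order_fraction: float = 0.40
    harmonic_range: tuple[float, float] = (2.0, 36.0)
    roi: str = "occipital_3"
    max_order: int | None = None  # None -> derived via min_order_fraction

    # reproducibility / output
    seed: int = 0
    out_dir: str = "freqtag_out"

    def __post_init__(self) -> None:
        for name in ("snr_valid", "min_look_s", "alpha", "n_perm", "min_order_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha >= 1:
            raise ValueError("alpha must be < 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trials_range", "age_range_days", "harmonic_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
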