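"""128-channel sensor-net geometry and named occipital subsets.

Positions come from the standard 128-channel HydroCel geodesic net layout
bundled with MNE.  Channels are addressed by their net number (1..128).
Adjacency between sensors is defined by k-nearest neighbours (k=6) in 3-D
sensor space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

N_CHANNELS = 128

#: medial occipital cluster used a priori for valid-trial selection
OCCIPITAL_10 = (69, 70, 73, 74, 75, 81, 82, 83, 88, 89)
#: smaller medial occipital ROI used for the trial-level SNR summaries
OCCIPITAL_3 = (74, 75, 82)


@dataclass(frozen=True)
class MontageSpec:
    """Sensor positions and neighbourhood structure for the 128-channel net."""

    positions: np.ndarray  # (128, 3) in head coordinates (m)
    adjacency: np.ndarray  # (128, 128) boolean, symmetric, zero diagonal
    occipital_10: tuple[int, ...] = OCCIPITAL_10
    occipital_3: tuple[int, ...] = OCCIPITAL_3

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def channels(self) -> np.ndarray:
        """Channel numbers, 1-based as printed on the net."""
        return np.arange(1, self.n_channels + 1)

    def index(self, channels) -> np.ndarray:
        """0-based array indices for 1-based channel numbers."""
        return np.asarray(channels, dtype=int) - 1

    def neighbors(self, channel: int) -> np.ndarray:
        """1-based numbers of the sensors adjacent to ``channel``."""
        return np.flatnonzero(self.adjacency[channel - 1]) + 1


def _knn_adjacency(positions: np.ndarray, k: int) -> np.ndarray:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros(d.shape, dtype=bool)
    nearest = np.argsort(d, axis=1)[:, :k]
    rows = np.repeat(np.arange(d.shape[0]), k)
    adj[rows, nearest.ravel()] = True
    adj |= adj.T  # symmetrize: neighbourhood is mutual
    return adj


@lru_cache(maxsize=1)
def hydrocel_128(k_neighbors: int = 6) -> MontageSpec:
    """Build the default 128-channel montage (cached)."""
    import mne

    m = mne.channels.make_standard_montage("GSN-HydroCel-128")
    ch_pos = m.get_positions()["ch_pos"]
    positions = np.array([ch_pos[f"E{i}"] for i in range(1, N_CHANNELS + 1)])
    return MontageSpec(positions=positions, adjacency=_knn_adjacency(positions, k_neighbors))
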