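"""Stimulus-sequence generation for the three exposure conditions.

Eight abstract shapes (integers 1..8) are presented in a continuous 6 Hz
stream.  Three between-subject conditions define the transitional-probability
(TP) structure of the stream:

``doublet``
    The eight shapes are partitioned into four fixed ordered pairs
    ("doublets").  Within a doublet the TP is 1; successive doublets are
    drawn uniformly among the other three (no immediate repetition of the
    same doublet), so the between-doublet TP is 1/3.

``control``
    Four shapes may occupy the first position of a unit and the other four
    the second position, yielding 16 possible doublets.  Units are drawn
    uniformly among the 15 doublets differing from the previous one, so the
    TP from a first-position shape to a specific second-position shape is
    1/4 on average.

``random``
    Shapes are drawn uniformly among the 7 shapes differing from the
    previous one (TP = 1/7 per specific successor).

Pairing schemes are randomized once per subject and kept fixed over trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_SHAPES = 8
CONDITIONS = ("doublet", "control", "random")

#: shapes per trial that carry EEG triggers (20 s at 6 Hz)
DEFAULT_N_CORE = 120
#: untriggered fade shapes on each side of the core (2 s at 6 Hz)
DEFAULT_N_FADE = 12


def _check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return condition


@dataclass(frozen=True)
class PairingScheme:
    """Per-subject assignment of shapes to doublet structure.

    For the doublet condition ``pairs`` holds 4 disjoint ordered pairs
    covering shapes 1..8.  For the control condition ``first_set`` /
    ``second_set`` are the 4 first-position and 4 second-position shapes.
    The random condition carries no pairing.
    """

    condition: str
    pairs: tuple[tuple[int, int], ...] = ()
    first_set: tuple[int, ...] = ()
    second_set: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if self.condition == "doublet":
            flat = [s for p in self.pairs for s in p]
            if sorted(flat) != list(range(1, N_SHAPES + 1)):
                raise ValueError("doublet pairs must partition shapes 1..8")
        elif self.condition == "control":
            if sorted(self.first_set + self.second_set) != list(range(1, N_SHAPES + 1)):
                raise ValueError("control position sets must partition shapes 1..8")
        else:
            if self.pairs or self.first_set or self.second_set:
                raise ValueError("random condition takes no pairing")

    @property
    def doublets(self) -> tuple[tuple[int, int], ...]:
        """All admissible (first, second) units under this scheme."""
        if self.condition == "doublet":
            return self.pairs
        if self.condition == "control":
            return tuple((f, s) for f in self.first_set for s in self.second_set)
        return ()


@dataclass
class TrialSequence:
    """Ordered shape identities for one trial, fades included.

    ``triggered`` flags the core (non-fade) positions; under the default
    configuration the core holds 120 shapes and the full sequence 144.
    """

    shapes: np.ndarray
    triggered: np.ndarray
    condition: str
    scheme: PairingScheme

    @property
    def n_core(self) -> int:
        return int(self.triggered.sum())

    @property
    def n_total(self) -> int:
        return int(self.shapes.size)

    def core_shapes(self) -> np.ndarray:
        return self.shapes[self.triggered]

    def to_frame(self, trial: int = 0) -> pd.DataFrame:
        """Long-format export: one row per presented shape."""
        return pd.DataFrame(
            {
                "trial": trial,
                "position": np.arange(self.n_total),
                "shape_id": self.shapes,
                "triggered": self.triggered,
            }
        )


@dataclass
class TPTable:
    """Empirical transitional probabilities of a set of sequences.

    ``matrix`` is the 8x8 shape-to-shape conditional probability matrix
    (rows: current shape, columns: next shape; rows sum to 1 over observed
    successors).  ``tp_within`` and ``tp_between`` summarize the unit
    structure; see :func:`empirical_tp`.
    """

    matrix: pd.DataFrame
    tp_within: float
    tp_between: float
    condition: str
    counts: pd.DataFrame = field(repr=False, default=None)


def make_pairing(condition: str, rng: np.random.Generator) -> PairingScheme:
    """Draw a uniformly random admissible pairing scheme for a subject."""
    _check_condition(condition)
    perm = rng.permutation(np.arange(1, N_SHAPES + 1))
    if condition == "doublet":
        pairs = tuple((int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(4))
        return PairingScheme("doublet", pairs=pairs)
    if condition == "control":
        return PairingScheme(
            "control",
            first_set=tuple(int(s) for s in sorted(perm[:4])),
            second_set=tuple(int(s) for s in sorted(perm[4:])),
        )
    return PairingScheme("random")


def _sample_units(
    units: tuple[tuple[int, int], ...],
    n_units: int,
    rng: np.random.Generator,
    prev: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    # uniform among units differing from the immediately preceding one
    out: list[tuple[int, int]] = []
    for _ in range(n_units):
        admissible = [u for u in units if u != prev]
        prev = admissible[rng.integers(len(admissible))]
        out.append(prev)
    return out


def _sample_random_shapes(
    n: int, rng: np.random.Generator, prev: int | None = None
) -> list[int]:
    out: list[int] = []
    for _ in range(n):
        admissible = [s for s in range(1, N_SHAPES + 1) if s != prev]
        prev = admissible[rng.integers(len(admissible))]
        out.append(prev)
    return out


def generate_trial_sequence(
    scheme: PairingScheme,
    n_core: int = DEFAULT_N_CORE,
    n_fade: int = DEFAULT_N_FADE,
    rng: np.random.Generator | None = None,
) -> TrialSequence:
    """Generate one trial's shape stream under the scheme's condition.

    Fade shapes (``n_fade`` per side) follow the same sequential rules as
    the core but carry no triggers.  For the paired conditions ``n_core``
    and ``n_fade`` must be even so units are never split.
    """
    if rng is None:
        rng = np.random.default_rng()
    cond = scheme.condition
    if n_core <= 0 or n_fade < 0:
        raise ValueError("counts must be positive")

    n_total = n_core + 2 * n_fade
    if cond == "random":
        shapes = np.array(_sample_random_shapes(n_total, rng))
    else:
        if n_core % 2 or n_fade % 2:
            raise ValueError(
                f"{cond} condition requires even core/fade shape counts, "
                f"got n_core={n_core}, n_fade={n_fade}"
            )
        units = _sample_units(scheme.doublets, n_total // 2, rng)
        shapes = np.array([s for u in units for s in u])

    triggered = np.zeros(n_total, dtype=bool)
    triggered[n_fade : n_fade + n_core] = True
    return TrialSequence(shapes=shapes, triggered=triggered, condition=cond, scheme=scheme)


def _unit_stream(seq: TrialSequence) -> list[tuple[int, int]]:
    s = seq.shapes
    return [(int(s[i]), int(s[i + 1])) for i in range(0, s.size - 1, 2)]


def empirical_tp(sequences: list[TrialSequence]) -> TPTable:
    """Tabulate observed transitional probabilities.

    All sequences must share one condition (and scheme).  Summary scalars:

    - ``tp_within``: mean over first-position shapes of P(observed successor
      shape | first-position shape) averaged over observed successors within
      units — equals 1 exactly in the doublet condition and ~1/4 in control.
    - ``tp_between``: mean conditional probability of each specific observed
      successor unit given the current unit (doublet/control), or of each
      specific successor shape (random, where it is the shape-level TP ~1/7).

    Probabilities are conditional frequencies over *observed* successors, so
    structurally impossible transitions never dilute the summaries.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    cond = sequences[0].condition
    if any(s.condition != cond for s in sequences):
        raise ValueError("sequences mix conditions")

    counts = np.zeros((N_SHAPES, N_SHAPES), dtype=np.int64)
    for seq in sequences:
        a = seq.shapes
        np.add.at(counts, (a[:-1] - 1, a[1:] - 1), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        matrix = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    idx = pd.Index(range(1, N_SHAPES + 1), name="shape")
    matrix_df = pd.DataFrame(matrix, index=idx, columns=idx.rename("next_shape"))
    counts_df = pd.DataFrame(counts, index=idx, columns=idx.rename("next_shape"))

    if cond == "random":
        tp_between = _mean_observed_conditional(counts)
        tp_within = float("nan")
    else:
        # within-unit transitions: first -> second position
        win = np.zeros((N_SHAPES, N_SHAPES), dtype=np.int64)
        unit_index: dict[tuple[int, int], int] = {}
        unit_counts: np.ndarray | None = None
        units_all: list[list[int]] = []
        for seq in sequences:
            units = _unit_stream(seq)
            for f, s in units:
                win[f - 1, s - 1] += 1
            ids = []
            for u in units:
                if u not in unit_index:
                    unit_index[u] = len(unit_index)
                ids.append(unit_index[u])
            units_all.append(ids)
        n_units = len(unit_index)
        unit_counts = np.zeros((n_units, n_units), dtype=np.int64)
        for ids in units_all:
            a = np.asarray(ids)
            np.add.at(unit_counts, (a[:-1], a[1:]), 1)
        tp_within = _mean_observed_conditional(win)
        tp_between = _mean_observed_conditional(unit_counts)

    return TPTable(
        matrix=matrix_df,
        tp_within=float(tp_within),
        tp_between=float(tp_between),
        condition=cond,
        counts=counts_df,
    )


def _mean_observed_conditional(counts: np.ndarray) -> float:
    """Mean conditional probability over transitions observed at least once."""
    row_sums = counts.sum(axis=1, keepdims=True)
    mask = counts > 0
    if not mask.any():
        raise ValueError("no transitions observed")
    probs = counts[mask] / np.broadcast_to(row_sums, counts.shape)[mask]
    return float(probs.mean())


def sequences_to_frame(sequences: list[TrialSequence]) -> pd.DataFrame:
    """Concatenate trials into one long-format table (CSV-ready)."""
    return pd.concat(
        [seq.to_frame(trial=i) for i, seq in enumerate(sequences)], ignore_index=True
    )
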