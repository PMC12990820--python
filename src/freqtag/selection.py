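"""Valid-trial selection, trial-order bookkeeping, and harmonic selection.

A trial is valid when (a) its SNR at the 6 Hz base frequency exceeds 2 in at
least one of the 10 pre-defined occipital channels, and (b) the infant
looked at the screen for more than 7 s (both strict inequalities).  Subjects
need at least two valid trials to stay in the sample.  Valid trials are
renumbered 1..n per subject ("trial order"); analyses are restricted to the
prefix of orders at which every condition retains at least 40% of its
subjects.

Harmonic selection tests, per candidate frequency in the 2-36 Hz range,
whether trial-level SNR differs from 1 with a two-sided one-sample Wilcoxon
signed-rank test.  Base-family candidates are tested on all conditions;
doublet-family candidates on the doublet and control conditions only, since
no doublet-rate response can exist in the random stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .montage import OCCIPITAL_3, OCCIPITAL_10, MontageSpec
from .spectral import HarmonicSet, base_candidates, doublet_candidates

SNR_VALID_THRESHOLD = 2.0
MIN_LOOKING_S = 7.0
MIN_VALID_TRIALS = 2
MIN_ORDER_FRACTION = 0.40


@dataclass
class HarmonicTestResult:
    """Wilcoxon signed-rank test of SNR != 1 at one candidate frequency."""

    frequency: float
    statistic: float
    p_value: float
    selected: bool
    n: int


def trial_is_valid(
    snr_topo_6hz: np.ndarray,
    looking_s: float,
    montage: MontageSpec,
    snr_threshold: float = SNR_VALID_THRESHOLD,
    min_look_s: float = MIN_LOOKING_S,
) -> bool:
    """Apply the joint electrophysiological + behavioural validity criterion."""
    occ = snr_topo_6hz[montage.index(montage.occipital_10)]
    return bool(occ.max() > snr_threshold and looking_s > min_look_s)


def renumber_and_filter(
    records: pd.DataFrame, min_valid: int = MIN_VALID_TRIALS
) -> pd.DataFrame:
    """Drop invalid trials, renumber orders 1..n, drop sparse subjects.

    ``records`` needs columns ``subject_id``, ``trial`` (acquisition index)
    and ``valid``.  Output rows keep acquisition order within subject and
    gain an ``order`` column; subjects with fewer than ``min_valid`` valid
    trials are removed entirely.  Idempotent on its own output.
    """
    out = records[records["valid"]].copy()
    out = out.sort_values(["subject_id", "trial"], kind="stable")
    out["order"] = out.groupby("subject_id").cumcount() + 1
    n_valid = out.groupby("subject_id")["order"].transform("max")
    return out[n_valid >= min_valid].reset_index(drop=True)


def restrict_orders(
    table: pd.DataFrame, min_fraction: float = MIN_ORDER_FRACTION
) -> tuple[pd.DataFrame, int]:
    """Keep the prefix of orders 1..K that every condition supports.

    An order k is supported by a condition when at least ``min_fraction`` of
    that condition's subjects contribute a trial at order k; K is the last
    order before the first unsupported one.  Returns the restricted table
    and K.
    """
    if table.empty:
        raise ValueError("empty analysis table")
    n_subjects = table.groupby("condition")["subject_id"].nunique()
    max_order = int(table["order"].max())
    K = 0
    for k in range(1, max_order + 1):
        contrib = (
            table[table["order"] >= k].groupby("condition")["subject_id"].nunique()
        )
        frac = (contrib.reindex(n_subjects.index).fillna(0) / n_subjects).min()
        if frac >= min_fraction:
            K = k
        else:
            break
    return table[table["order"] <= K].reset_index(drop=True), K


def select_harmonics(
    trial_snr: pd.DataFrame,
    family: str,
    fmin: float = 2.0,
    fmax: float = 36.0,
    alpha: float = 0.05,
) -> tuple[HarmonicSet, list[HarmonicTestResult]]:
    """Wilcoxon-select the significant members of a harmonic family.

    ``trial_snr`` is long format with columns ``frequency`` and ``snr``; the
    unit of observation is the trial (pooled across subjects).  Callers are
    responsible for restricting doublet-family input to the doublet+control
    conditions.  A candidate is selected when the two-sided signed-rank p
    (SNR vs 1, zero differences dropped) is below ``alpha``.
    """
    if family == "base":
        candidates = base_candidates(fmin, fmax)
    elif family == "doublet":
        candidates = doublet_candidates(fmin, fmax)
    else:
        raise ValueError(f"unknown family {family!r}")

    results: list[HarmonicTestResult] = []
    for f in candidates:
        vals = trial_snr.loc[trial_snr["frequency"] == f, "snr"].to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"need >= 2 trials at {f} Hz, got {vals.size}")
        diffs = vals - 1.0
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(
                diffs, zero_method="wilcox", alternative="two-sided"
            )
        results.append(
            HarmonicTestResult(
                frequency=float(f),
                statistic=float(stat),
                p_value=float(p),
                selected=bool(p < alpha),
                n=int(vals.size),
            )
        )

    selected = tuple(r.frequency for r in results if r.selected)
    hs = HarmonicSet(family=family, frequencies=selected)
    return hs, results


def subject_mean_snr(trial_snr: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean SNR per frequency (config alternative to pooling)."""
    return (
        trial_snr.groupby(["subject_id", "frequency"], as_index=False)["snr"].mean()
    )


def roi_channels(montage: MontageSpec, roi: str = "occipital_3") -> tuple[int, ...]:
    """Resolve a named ROI to channel numbers."""
    if roi == "occipital_3":
        return OCCIPITAL_3
    if roi == "occipital_10":
        return OCCIPITAL_10
    raise ValueError(f"unknown ROI {roi!r}")
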