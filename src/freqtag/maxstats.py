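"""Permutation maximum statistics over whole-scalp SNR topographies.

The observed statistic is the per-channel mean SNR over units (trials for
individual analysis, subjects for group analysis).  The null hypothesis is
SNR = 1 everywhere — the unit topography.  Surrogates randomize each unit's
topography against the unit topography with an independent binary mask and
record the maximum of the surrogate mean over channels; thresholding the
observed mean at the (1 - alpha) quantile of the null maxima controls the
family-wise error across channels.  Channels exceeding the threshold form
the ROI.

Two surrogate schemes are provided.  ``reflect`` (default) mirrors masked
topographies around the unit topography (1 + (1 - snr), the one-sample
sign-randomization of the deviation from the null value), which leaves the
surrogate mean's dispersion equal to the observed one and is calibrated
under symmetric deviations.  ``replace`` substitutes masked topographies by
the all-ones map itself; it is anti-conservative (masked units lose their
noise, shrinking the surrogate dispersion) and is kept only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import MontageSpec

DEFAULT_N_PERM = 10_000


@dataclass
class MaxStatResult:
    """Observed topography, permutation null, threshold, and ROI."""

    frequency: float
    observed: np.ndarray        # (n_channels,) mean SNR over units
    null_maxima: np.ndarray     # (n_perm,)
    threshold: float            # empirical (1 - alpha) quantile of the null
    significant: tuple[int, ...]  # 1-based channel numbers, observed > threshold
    alpha: float
    n_units: int


def max_stat_test(
    topographies: np.ndarray,
    frequency: float = np.nan,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    mask_prob: float = 0.5,
    surrogate: str = "reflect",
) -> MaxStatResult:
    """Maximum-statistics permutation test on a stack of SNR topographies.

    ``topographies`` is (n_units, n_channels); all units must share one
    montage.  Each permutation masks each unit independently with
    probability ``mask_prob`` and randomizes the masked topographies against
    the unit topography (see module docstring for the two schemes), averages
    over units, and records the channel-wise maximum.  The threshold is the
    'higher' empirical order statistic at 1 - alpha, so results are exactly
    reproducible under a fixed seed; significance is strict (> threshold).
    """
    topos = np.asarray(topographies, dtype=float)
    if topos.ndim != 2 or topos.shape[0] < 2:
        raise ValueError("need a (n_units >= 2, n_channels) topography stack")
    if surrogate not in ("reflect", "replace"):
        raise ValueError(f"unknown surrogate scheme {surrogate!r}")
    rng = rng or np.random.default_rng()
    n_units, n_ch = topos.shape

    observed = topos.mean(axis=0)

    # surrogate mean per channel via masked-sum identities (no surrogate
    # stacks materialized):
    #   reflect: mean + (2/n) * sum_masked(1 - topo)
    #   replace: (sum_kept(topo) + n_masked) / n
    dev = 1.0 - topos
    null_maxima = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7) // max(n_units * n_ch, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        masks = (rng.random((b, n_units)) < mask_prob).astype(float)
        if surrogate == "reflect":
            means = observed[None, :] + 2.0 * (masks @ dev) / n_units
        else:
            n_ones = masks.sum(axis=1, keepdims=True)
            means = ((1.0 - masks) @ topos + n_ones) / n_units
        null_maxima[done : done + b] = means.max(axis=1)
        done += b

    threshold = float(np.quantile(null_maxima, 1.0 - alpha, method="higher"))
    significant = tuple(int(c) + 1 for c in np.flatnonzero(observed > threshold))
    return MaxStatResult(
        frequency=float(frequency),
        observed=observed,
        null_maxima=null_maxima,
        threshold=threshold,
        significant=significant,
        alpha=alpha,
        n_units=n_units,
    )


def individual_roi(
    trial_topographies: dict[float, np.ndarray],
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    surrogate: str = "reflect",
) -> dict[float, MaxStatResult]:
    """Per-subject significance: units are the subject's valid trials.

    ``trial_topographies`` maps frequency -> (n_trials, n_channels).
    """
    rng = rng or np.random.default_rng()
    out = {}
    for f, topos in trial_topographies.items():
        if np.asarray(topos).shape[0] < 2:
            raise ValueError(f"subject has < 2 valid trials at {f} Hz")
        out[f] = max_stat_test(
            topos, frequency=f, n_perm=n_perm, alpha=alpha, rng=rng, surrogate=surrogate
        )
    return out


def group_roi(
    subject_topographies: dict[float, np.ndarray],
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    surrogate: str = "reflect",
) -> dict[float, MaxStatResult]:
    """Group-level ROIs: units are subject topographies.

    ``subject_topographies`` maps frequency -> (n_subjects, n_channels); the
    per-frequency significant-channel sets are the ROIs used downstream.
    """
    rng = rng or np.random.default_rng()
    out = {}
    for f, topos in subject_topographies.items():
        if np.asarray(topos).shape[0] < 2:
            raise ValueError(f"group analysis needs >= 2 subjects at {f} Hz")
        out[f] = max_stat_test(
            topos, frequency=f, n_perm=n_perm, alpha=alpha, rng=rng, surrogate=surrogate
        )
    return out


def result_to_dict(res: MaxStatResult) -> dict:
    """JSON-serializable summary (frequency, threshold, channel list)."""
    return {
        "frequency": res.frequency,
        "alpha": res.alpha,
        "n_units": res.n_units,
        "threshold": res.threshold,
        "significant_channels": list(res.significant),
    }
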