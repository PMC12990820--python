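"""End-to-end orchestration: simulate -> preprocess -> SNR -> selection ->
maximum statistics -> mixed models.

Every stage is also callable on its own; this module wires them together
with one seed, structured logging, and a manifest (config hash + seeds) so
any output can be regenerated bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf as edfio
from . import eegsim, maxstats, preprocess, selection, spectral, stats_models
from .config import PipelineConfig
from .montage import MontageSpec, hydrocel_128

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline produced."""

    config: PipelineConfig
    plan: pd.DataFrame
    trial_table: pd.DataFrame          # all trials with validity flags
    analysis_table: pd.DataFrame       # valid, renumbered, order-restricted
    max_order: int
    harmonic_tests: pd.DataFrame
    base_set: spectral.HarmonicSet
    doublet_set: spectral.HarmonicSet
    dominant: dict[str, float | None]
    group_rois: dict[float, maxstats.MaxStatResult]
    individual_significance: pd.DataFrame
    ladders: dict[str, stats_models.LadderResult] = field(default_factory=dict)
    contrasts: dict[str, stats_models.ContrastResult] = field(default_factory=dict)
    valid_fraction: float = float("nan")


def _candidate_frequencies(cfg: PipelineConfig) -> tuple[float, ...]:
    return spectral.base_candidates(*cfg.harmonic_range) + spectral.doublet_candidates(
        *cfg.harmonic_range
    )


def _spectral_stage(
    rec: eegsim.SyntheticRecording,
    cfg: PipelineConfig,
    montage: MontageSpec,
) -> tuple[pd.DataFrame, dict[int, dict[float, np.ndarray]]]:
    """Preprocess one subject and extract per-trial spectral neighbourhoods.

    Returns (trial rows with validity, {trial: {freq: (n_ch, 11) amplitude
    slice}}).  The compact slices support both per-trial SNR and SNR of
    trial-averaged spectra downstream.
    """
    segs, repaired = preprocess.preprocess_recording(rec)
    if repaired:
        logger.info("subject %s: repaired channels %s", rec.subject_id, repaired)

    freqs = _candidate_frequencies(cfg)
    rows, nbs = [], {}
    for seg in segs:
        spec = spectral.amplitude_spectrum(seg)
        nb = {f: spectral.neighborhood_amplitudes(spec, f) for f in freqs}
        snr6 = spectral.snr_from_neighborhood(nb[6.0])
        valid = selection.trial_is_valid(
            snr6, seg.looking_s, montage, cfg.snr_valid, cfg.min_look_s
        )
        nbs[seg.trial] = nb
        rows.append(
            {
                "subject_id": seg.subject_id,
                "condition": seg.condition,
                "age_days": seg.age_days,
                "trial": seg.trial,
                "looking_s": seg.looking_s,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows), nbs


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis on a synthetic cohort defined by ``cfg``.

    When ``out_dir`` (or ``cfg.out_dir``) exists or can be created, artifacts
    are written there: the trial table and analysis table (CSV), the
    harmonic-selection report (CSV), group ROIs (JSON), model summaries
    (JSON), and a manifest recording the config hash and seed.
    """
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    montage = hydrocel_128()
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate + per-subject spectral stage (sequential, memory-bounded)
    design = eegsim.CohortDesign(
        n_per_condition=dict(cfg.n_per_condition),
        trials_mean=cfg.trials_mean,
        trials_sd=cfg.trials_sd,
        trials_range=tuple(cfg.trials_range),
        age_range_days=tuple(cfg.age_range_days),
    )
    noise = eegsim.NoiseSpec(
        exponent=cfg.noise_exponent,
        scale=cfg.noise_scale,
        n_bad=cfg.n_bad_channels,
        bad_gain=cfg.bad_channel_gain,
    )
    plan = eegsim.plan_cohort(design, rng)
    profiles = eegsim.default_profiles()

    trial_frames, topos = [], {}
    for _, row in plan.iterrows():
        rec = eegsim.simulate_from_plan_row(row, profiles, noise, montage)
        if cfg.n_bad_channels:
            rec = eegsim.corrupt_channels(
                rec, noise, np.random.default_rng(int(row["seed"]) + 1)
            )
        if cfg.write_edf:
            edfio.save_recording(rec, out / f"{rec.subject_id}.edf")
        rows, nb = _spectral_stage(rec, cfg, montage)
        trial_frames.append(rows)
        topos[rec.subject_id] = nb
        logger.info(
            "subject %s (%s): %d trials, %d valid",
            rec.subject_id,
            rec.condition,
            len(rows),
            int(rows["valid"].sum()),
        )

    trial_table = pd.concat(trial_frames, ignore_index=True)
    valid_fraction = float(trial_table["valid"].mean())
    logger.info(
        "%d/%d trials valid (%.1f%%)",
        int(trial_table["valid"].sum()),
        len(trial_table),
        100 * valid_fraction,
    )

    # --- valid-trial bookkeeping
    valid = selection.renumber_and_filter(trial_table, cfg.min_valid_trials)

    # --- harmonic selection: per-trial SNR of the occipital-10-averaged
    # amplitude spectrum (channel-averaging the spectrum before the ratio
    # keeps the null statistic centered on 1)
    occ10 = montage.index(montage.occipital_10)
    freqs = _candidate_frequencies(cfg)
    snr_rows = []
    for _, r in valid.iterrows():
        tr = topos[r["subject_id"]][r["trial"]]
        for f in freqs:
            roi_nb = tr[f][occ10].mean(axis=0)
            snr_rows.append(
                {
                    "subject_id": r["subject_id"],
                    "trial": r["trial"],
                    "condition": r["condition"],
                    "frequency": f,
                    "snr": float(spectral.snr_from_neighborhood(roi_nb)),
                }
            )
    snr_long = pd.DataFrame(snr_rows)

    base_set, base_tests = selection.select_harmonics(
        snr_long, "base", *cfg.harmonic_range, alpha=cfg.alpha
    )
    doublet_set, doublet_tests = selection.select_harmonics(
        snr_long[snr_long["condition"].isin(["doublet", "control"])],
        "doublet",
        *cfg.harmonic_range,
        alpha=cfg.alpha,
    )
    harmonic_tests = pd.DataFrame(
        [
            {"family": fam, "frequency": t.frequency, "W": t.statistic, "p": t.p_value,
             "selected": t.selected, "n": t.n}
            for fam, tests in (("base", base_tests), ("doublet", doublet_tests))
            for t in tests
        ]
    )

    dominant = {
        "base": _dominant(snr_long, base_set),
        "doublet": _dominant(
            snr_long[snr_long["condition"].isin(["doublet", "control"])], doublet_set
        ),
    }

    # --- group-level maximum statistics at the selected frequencies
    # (subject topography = SNR of the subject's trial-averaged spectrum)
    selected_freqs = base_set.frequencies + doublet_set.frequencies
    subj_topos: dict[float, np.ndarray] = {}
    for f in selected_freqs:
        per_subject = []
        for sid, trials in topos.items():
            idx = valid.loc[valid["subject_id"] == sid, "trial"]
            if len(idx) == 0:
                continue
            if f in spectral.doublet_candidates(*cfg.harmonic_range):
                cond = trial_table.loc[trial_table["subject_id"] == sid, "condition"].iloc[0]
                if cond == "random":
                    continue
            mean_nb = np.mean([trials[t][f] for t in idx], axis=0)
            per_subject.append(spectral.snr_from_neighborhood(mean_nb))
        subj_topos[f] = np.asarray(per_subject)
    group_rois = maxstats.group_roi(
        subj_topos, n_perm=cfg.n_perm, alpha=cfg.alpha, rng=np.random.default_rng(cfg.seed + 1)
    )

    # --- individual-level maximum statistics (count of responding subjects)
    ind_rows = []
    ind_rng = np.random.default_rng(cfg.seed + 2)
    for sid, trials in topos.items():
        idx = valid.loc[valid["subject_id"] == sid, "trial"]
        if len(idx) < 2:
            continue
        per_freq = {
            f: spectral.snr_from_neighborhood(np.asarray([trials[t][f] for t in idx]))
            for f in selected_freqs
        }
        res = maxstats.individual_roi(per_freq, n_perm=cfg.n_perm, alpha=cfg.alpha, rng=ind_rng)
        for f, r in res.items():
            ind_rows.append(
                {"subject_id": sid, "frequency": f, "n_significant": len(r.significant),
                 "significant": bool(r.significant)}
            )
    individual_significance = pd.DataFrame(ind_rows)

    # --- trial-level ROI summaries and the analysis table
    roi_idx = montage.index(selection.roi_channels(montage, cfg.roi))
    rec_rows = []
    for _, r in valid.iterrows():
        tr = topos[r["subject_id"]][r["trial"]]

        def _roi_snr(f: float) -> float:
            # average the SNR spectrum over the ROI channels
            return float(spectral.snr_from_neighborhood(tr[f][roi_idx]).mean())

        snr_base = float(
            np.mean([_roi_snr(f) for f in base_set.frequencies])
        ) if base_set.frequencies else np.nan
        snr_doublet = float(
            np.mean([_roi_snr(f) for f in doublet_set.frequencies])
        ) if doublet_set.frequencies else np.nan
        rec_rows.append({**r[["subject_id", "condition", "age_days", "trial", "order"]],
                         "snr_base": snr_base, "snr_doublet": snr_doublet})
    records = pd.DataFrame(rec_rows)

    ladders: dict[str, stats_models.LadderResult] = {}
    contrasts: dict[str, stats_models.ContrastResult] = {}
    if doublet_set.frequencies and base_set.frequencies:
        restricted, K = selection.restrict_orders(records, cfg.min_order_fraction)
        if cfg.max_order is not None:
            K = cfg.max_order
        analysis = stats_models.build_table(restricted, max_order=K)
        for dv in ("log_snr_base", "log_snr_doublet", "learning_index"):
            ladders[dv] = stats_models.fit_ladder(analysis, dv, alpha=cfg.alpha)
            contrasts[dv] = stats_models.post_hoc(ladders[dv], orders=(1, 5, K))
    else:
        logger.warning("empty harmonic set (base or doublet); skipping mixed models")
        restricted, K = selection.restrict_orders(records, cfg.min_order_fraction) if not records.empty else (records, 0)
        analysis = records

    result = PipelineResult(
        config=cfg,
        plan=plan,
        trial_table=trial_table,
        analysis_table=analysis,
        max_order=K,
        harmonic_tests=harmonic_tests,
        base_set=base_set,
        doublet_set=doublet_set,
        dominant=dominant,
        group_rois=group_rois,
        individual_significance=individual_significance,
        ladders=ladders,
        contrasts=contrasts,
        valid_fraction=valid_fraction,
    )
    _write_artifacts(result, out)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return result


def _dominant(snr_long: pd.DataFrame, hs: spectral.HarmonicSet) -> float | None:
    if not hs.frequencies:
        return None
    means = snr_long.groupby("frequency")["snr"].mean().to_dict()
    return spectral.dominant_frequency({f: means[f] for f in hs.frequencies}, hs)


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    cfg = result.config
    result.trial_table.to_csv(out / "trial_table.csv", index=False)
    result.analysis_table.to_csv(out / "analysis_table.csv", index=False)
    result.harmonic_tests.to_csv(out / "harmonic_selection.csv", index=False)
    result.plan.to_csv(out / "cohort_plan.csv", index=False)

    rois = {str(f): maxstats.result_to_dict(r) for f, r in result.group_rois.items()}
    (out / "group_rois.json").write_text(json.dumps(rois, indent=1))

    models = {}
    for dv, ladder in result.ladders.items():
        sel = ladder.selected
        models[dv] = {
            "selected": sel.name,
            "terms": list(sel.terms),
            "aic_ml": min(s.aic for s in ladder.steps if s.accepted),
            "loglik_reml": sel.loglik,
            "icc": sel.icc,
            "singular": sel.singular,
            "fixed_effects": {
                name: {
                    "estimate": float(sel.params[name]),
                    "se": float(sel.bse[name]),
                    "t": float(sel.tvalues[name]),
                    "p": float(sel.pvalues[name]),
                    "ci": [float(sel.conf_int.loc[name, "ci_lo"]),
                           float(sel.conf_int.loc[name, "ci_hi"])],
                }
                for name in sel.params.index
            },
            "ladder": ladder.summary_frame().to_dict(orient="records"),
        }
        ct = result.contrasts[dv]
        models[dv]["contrasts"] = {
            "df": ct.df,
            "means": ct.means.to_dict(orient="records"),
            "pairwise": ct.pairwise.to_dict(orient="records"),
            "slopes": None if ct.slopes is None else ct.slopes.to_dict(orient="records"),
            "by_order": None if ct.by_order is None else ct.by_order.to_dict(orient="records"),
        }
    (out / "model_summaries.json").write_text(json.dumps(models, indent=1, default=float))

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "max_order": result.max_order,
        "valid_fraction": result.valid_fraction,
        "base_frequencies": list(result.base_set.frequencies),
        "doublet_frequencies": list(result.doublet_set.frequencies),
        "dominant": result.dominant,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
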