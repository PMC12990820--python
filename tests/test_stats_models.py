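"""Mixed-model ladder, simple coding, contrasts, ICC, back-transform."""

import numpy as np
import pandas as pd
import pytest

from freqtag import stats_models as sm


def _table(**kw):
    defaults = dict(rng=np.random.default_rng(kw.pop("seed", 0)))
    defaults.update(kw)
    return sm.simulate_analysis_table(**defaults)


# --- build_table ---------------------------------------------------------------


def _records():
    rng = np.random.default_rng(1)
    rows = []
    for sid in ("A", "B", "C"):
        for order in range(1, 13):
            rows.append(
                {
                    "subject_id": sid,
                    "condition": "doublet",
                    "age_days": 150.0,
                    "order": order,
                    "snr_base": 10.0,
                    "snr_doublet": float(rng.uniform(1, 3)),
                }
            )
    return pd.DataFrame(rows)


def test_build_table_log_transform():
    t = sm.build_table(_records())
    assert np.allclose(t["log_snr_base"], 1.0)  # log10(10) = 1
    assert np.allclose(t["log_snr_doublet"], np.log10(t["snr_doublet"]))


def test_build_table_learning_index_ratio_identity():
    rec = _records()
    rec["snr_doublet"] = rec["snr_base"]
    t = sm.build_table(rec)
    assert np.allclose(t["learning_index"], 1.0)


def test_build_table_order_restriction():
    t = sm.build_table(_records(), max_order=9)
    assert t["order"].max() == 9
    with pytest.raises(ValueError):
        sm.build_table(_records(), max_order=0)


def test_build_table_centers_age():
    t = sm.build_table(_records())
    assert abs(t["age_c"].mean()) < 1e-9


# --- simple coding ---------------------------------------------------------------


def test_simple_coding_columns_sum_to_zero_when_balanced():
    cond = pd.Series(["doublet", "control", "random"] * 4)
    code = sm.simple_code(cond)
    assert np.allclose(code.sum(axis=0), 0.0)
    assert set(code.columns) == {"c_control", "c_random"}


def test_intercept_is_grand_mean_of_condition_means():
    """On balanced data the condition-only model's intercept equals the
    unweighted mean of the three condition means (tolerance 1e-6)."""
    t = _table(
        n_per_condition=6,
        n_orders=6,
        condition_effects={"doublet": 0.2, "control": 0.05, "random": -0.1},
        subject_sd=0.0,
        residual_sd=0.1,
        seed=2,
    )
    res, X = sm._fit_mixedlm(t, "log_snr_doublet", ("condition",), reml=True)
    grand = t.groupby("condition")["log_snr_doublet"].mean().mean()
    assert res.fe_params[0] == pytest.approx(grand, abs=1e-6)


# --- ladder ----------------------------------------------------------------------


def test_lrt_chi2_nonnegative_all_steps():
    t = _table(seed=3, condition_effects={"doublet": 0.15, "control": 0.0, "random": -0.1})
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    for step in ladder.steps[1:]:
        assert step.lrt_chi2 >= 0.0
        assert step.lrt_df >= 1


def test_ladder_recovers_condition_effect():
    t = _table(
        seed=4,
        condition_effects={"doublet": 0.25, "control": 0.1, "random": 0.0},
        subject_sd=0.08,
        residual_sd=0.15,
    )
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    assert "condition" in ladder.selected_terms
    assert "age" not in ladder.selected_terms


def test_ladder_recovers_negative_order_slope():
    t = _table(seed=5, dv="log_snr_base", order_slope=-0.03, residual_sd=0.15)
    ladder = sm.fit_ladder(t, "log_snr_base")
    assert "order" in ladder.selected_terms
    assert ladder.selected.params["order"] < 0


def test_ladder_null_data_mostly_keeps_intercept_model():
    """Under the null each LRT step fires at ~alpha, so the intercept-only
    model survives in roughly (1 - alpha)^4 ~ 81% of cohorts."""
    rng = np.random.default_rng(6)
    kept = sum(
        sm.fit_ladder(
            sm.simulate_analysis_table(n_per_condition=6, n_orders=6, rng=rng),
            "log_snr_doublet",
        ).selected_terms
        == ()
        for _ in range(60)
    )
    assert kept >= 39  # >= 65% of 60


def test_ladder_requires_multiple_subjects_and_conditions():
    t = _table(seed=7)
    with pytest.raises(ValueError):
        sm.fit_ladder(t[t["subject_id"] == "S00"], "log_snr_doublet")
    with pytest.raises(ValueError):
        sm.fit_ladder(t[t["condition"] == "doublet"], "log_snr_doublet")


def test_aic_identity():
    t = _table(seed=8)
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    base = ladder.steps[0]
    k = len(base.params) + 2
    assert base.aic == pytest.approx(2 * k - 2 * base.loglik)


# --- contrasts -------------------------------------------------------------------


def test_post_hoc_detects_strong_contrast():
    t = _table(
        seed=9,
        condition_effects={"doublet": 0.3, "control": 0.12, "random": 0.0},
        subject_sd=0.05,
        residual_sd=0.15,
    )
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    ct = sm.post_hoc(ladder)
    pw = ct.pairwise.set_index("contrast")
    assert pw.loc["doublet - random", "p_tukey"] < 0.001
    assert pw.loc["doublet - random", "estimate"] > 0
    assert ((ct.pairwise["p_tukey"] >= 0) & (ct.pairwise["p_tukey"] <= 1)).all()


def test_post_hoc_back_transforms_log_dvs():
    t = _table(seed=10, condition_effects={"doublet": 0.25, "control": 0.1, "random": 0.0})
    ct = sm.post_hoc(sm.fit_ladder(t, "log_snr_doublet"))
    means = ct.means.set_index("condition")
    for lev in ("doublet", "control", "random"):
        assert means.loc[lev, "back_mean"] == pytest.approx(
            10 ** means.loc[lev, "estimate"]
        )


def test_post_hoc_null_contrasts_not_significant():
    t = _table(seed=11)
    ct = sm.post_hoc(sm.fit_ladder(t, "log_snr_doublet"))
    assert (ct.pairwise["p_tukey"] > 0.05).all()


def test_post_hoc_slopes_when_interaction_present():
    t = _table(
        seed=12,
        condition_effects={"doublet": 0.2, "control": 0.0, "random": 0.0},
        order_slope=-0.02,
    )
    # inject a condition-specific slope so the interaction is detectable
    mask = t["condition"] == "doublet"
    t.loc[mask, "log_snr_doublet"] += 0.06 * t.loc[mask, "order"]
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    if "condition:order" in ladder.selected_terms:
        ct = sm.post_hoc(ladder)
        assert ct.slopes is not None
        assert ct.by_order is not None


# --- ICC and back-transform -------------------------------------------------------


def test_icc_zero_between_subject_variance():
    t = _table(seed=13, subject_sd=0.0, residual_sd=0.2)
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    assert ladder.selected.icc < 0.05


def test_icc_near_one_when_residual_tiny():
    t = _table(seed=14, subject_sd=0.3, residual_sd=0.01)
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    assert ladder.selected.icc > 0.95


def test_icc_bounds():
    t = _table(seed=15, subject_sd=0.1, residual_sd=0.2)
    ladder = sm.fit_ladder(t, "log_snr_doublet")
    for step in ladder.steps:
        assert 0.0 <= step.icc <= 1.0


def test_back_transform_matches_reported_convention():
    assert round(sm.back_transform(0.272), 2) == 1.87
    assert sm.back_transform(0.0) == 1.0
    assert np.isinf(sm.back_transform(1e4))  # saturates instead of overflowing
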