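"""Trial-level linear mixed models for SNR and the doublet learning index.

Three dependent variables are modelled over valid trials: log10 base-level
SNR, log10 doublet-level SNR, and the learning index (doublet SNR / base
SNR, untransformed).  Every model carries a by-subject random intercept.
Condition uses *simple coding*: the intercept estimates the grand mean
across the three condition means, and each condition coefficient is that
condition's offset from the reference condition.

Model selection follows a stepwise ladder — intercept-only, + trial order,
+ condition, + age, + condition-by-order interaction — comparing nested fits
by likelihood-ratio test (ML fits) and retaining the lowest-AIC model among
the steps that improved significantly.  Reported estimates come from a REML
refit of the retained model.  Tukey-adjusted pairwise contrasts (condition
means, and order slopes when the interaction is present) use the studentized
range over the three comparisons with residual degrees of freedom
(nobs - n_fixed, a Satterthwaite-style stand-in recorded with the results).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

CONDITIONS = ("doublet", "control", "random")
LOG_DVS = ("log_snr_base", "log_snr_doublet")
DEFAULT_MAX_ORDER = 9

#: simple-coding values per condition (reference = doublet):
#: column c_<level> takes 1 - 1/3 for that level, -1/3 otherwise
_SIMPLE_LEVELS = ("control", "random")


def simple_code(condition: pd.Series) -> pd.DataFrame:
    """Simple-coded condition columns (each column sums to 0 when balanced)."""
    out = {}
    for lev in _SIMPLE_LEVELS:
        out[f"c_{lev}"] = (condition == lev).astype(float) - 1.0 / 3.0
    return pd.DataFrame(out, index=condition.index)


def build_table(records: pd.DataFrame, max_order: int = DEFAULT_MAX_ORDER) -> pd.DataFrame:
    """Assemble the modelling table from valid-trial records.

    Requires columns ``subject_id, condition, age_days, order, snr_base,
    snr_doublet``.  Adds log10-transformed SNR outcomes and the learning
    index, drops orders beyond ``max_order``, and centers age.
    """
    t = records[records["order"] <= max_order].copy()
    if t.empty:
        raise ValueError("no trials at or below the requested order")
    t["log_snr_base"] = np.log10(t["snr_base"])
    t["log_snr_doublet"] = np.log10(t["snr_doublet"])
    t["learning_index"] = t["snr_doublet"] / t["snr_base"]
    t["age_c"] = t["age_days"] - t["age_days"].mean()
    return t.reset_index(drop=True)


# --- design construction ----------------------------------------------------

TERMS = ("order", "condition", "age", "condition:order")


def _design(table: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    if "order" in terms:
        X["order"] = table["order"].astype(float)
    if "condition" in terms:
        X = pd.concat([X, simple_code(table["condition"])], axis=1)
    if "age" in terms:
        age = table["age_c"] if "age_c" in table else table["age_days"] - table["age_days"].mean()
        X["age_c"] = age.astype(float)
    if "condition:order" in terms:
        cc = simple_code(table["condition"])
        for col in cc:
            X[f"order:{col}"] = table["order"].astype(float) * cc[col]
    return X


@dataclass
class ModelResult:
    """One rung of the ladder: fit statistics and fixed-effect estimates."""

    name: str
    terms: tuple[str, ...]
    loglik: float
    aic: float
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame          # Wald 95% CI
    icc: float
    n_obs: int
    df_resid: int
    converged: bool
    singular: bool
    lrt_chi2: float | None = None   # vs the previous accepted model
    lrt_df: int | None = None
    lrt_p: float | None = None
    accepted: bool = False
    _fit: object = field(default=None, repr=False)
    _table: pd.DataFrame = field(default=None, repr=False)
    _dv: str = field(default="", repr=False)


def _fit_mixedlm(table: pd.DataFrame, dv: str, terms: tuple[str, ...], reml: bool):
    X = _design(table, terms)
    model = MixedLM(table[dv].to_numpy(float), X.to_numpy(), groups=table["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = None
        # lbfgs can hit a singular Hessian when the intercept variance sits
        # on the zero boundary, or silently return a degenerate fit with
        # infinite log-likelihood; derivative-free optimizers get past both
        for method in ("lbfgs", "powell", "nm", "cg"):
            try:
                cand = model.fit(reml=reml, method=method)
            except np.linalg.LinAlgError:
                continue
            ok = (
                np.isfinite(cand.llf)
                and np.all(np.isfinite(np.asarray(cand.fe_params)))
                and np.all(np.isfinite(np.asarray(cand.bse_fe)))
            )
            if ok:
                res = cand
                break
        if res is None:
            raise RuntimeError(f"mixed-model fit failed for terms {terms}")
    res.model.exog_names_ = list(X.columns)
    return res, X


def icc(res) -> float:
    """Between-subject share of outcome variance (random-intercept model)."""
    var_b = float(np.asarray(res.cov_re)[0, 0])
    var_e = float(res.scale)
    return var_b / (var_b + var_e)


def _wrap(res, X: pd.DataFrame, name: str, terms: tuple[str, ...], table, dv) -> ModelResult:
    k = X.shape[1] + 2  # fixed effects + intercept variance + residual variance
    llf = float(res.llf)
    names = list(X.columns)
    params = pd.Series(res.fe_params, index=names)
    bse = pd.Series(np.asarray(res.bse_fe), index=names)
    ci = pd.DataFrame(
        np.column_stack([params - 1.959964 * bse, params + 1.959964 * bse]),
        index=names,
        columns=["ci_lo", "ci_hi"],
    )
    var_b = float(np.asarray(res.cov_re)[0, 0])
    singular = var_b <= 1e-10 * max(float(res.scale), 1e-300)
    return ModelResult(
        name=name,
        terms=terms,
        loglik=llf,
        aic=2 * k - 2 * llf,
        params=params,
        bse=bse,
        tvalues=params / bse,
        pvalues=pd.Series(2 * stats.norm.sf(np.abs(params / bse)), index=names),
        conf_int=ci,
        icc=icc(res),
        n_obs=int(res.nobs),
        df_resid=int(res.nobs) - X.shape[1],
        converged=bool(res.converged),
        singular=singular,
        _fit=res,
        _table=table,
        _dv=dv,
    )


@dataclass
class LadderResult:
    """All rungs of the ladder plus the retained model (REML refit)."""

    dv: str
    steps: list[ModelResult]
    selected: ModelResult           # REML refit of the winning step
    selected_terms: tuple[str, ...]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append(
                {
                    "model": s.name,
                    "loglik": s.loglik,
                    "aic": s.aic,
                    "lrt_chi2": s.lrt_chi2,
                    "lrt_df": s.lrt_df,
                    "lrt_p": s.lrt_p,
                    "accepted": s.accepted,
                    "icc": s.icc,
                    "singular": s.singular,
                }
            )
        return pd.DataFrame(rows)


_LADDER = (
    ("order", ("order",)),
    ("condition", ("condition",)),
    ("age", ("age",)),
    ("condition:order", ("condition", "order", "condition:order")),
)


def fit_ladder(
    table: pd.DataFrame, dv: str, alpha: float = 0.05
) -> LadderResult:
    """Fit the stepwise model ladder for one dependent variable.

    Candidate terms are added to the current best model in the order: trial
    order, condition, age, condition-by-order interaction (the interaction
    step pulls in any missing main effects).  A step is accepted when its
    likelihood-ratio test against the current model is significant; among
    the baseline and all accepted steps the lowest-AIC model is retained and
    refit with REML for reporting.  Singular fits (zero between-subject
    variance) are flagged on the result, never silently accepted.
    """
    if table["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    if table["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions")

    res, X = _fit_mixedlm(table, dv, (), reml=False)
    base = _wrap(res, X, "intercept-only", (), table, dv)
    base.accepted = True
    steps = [base]
    current = base

    for name, add in _LADDER:
        terms = tuple(dict.fromkeys(current.terms + add))
        if terms == current.terms:
            continue
        res, X = _fit_mixedlm(table, dv, terms, reml=False)
        step = _wrap(res, X, f"+ {name}", terms, table, dv)
        step.lrt_chi2 = max(0.0, 2 * (step.loglik - current.loglik))
        step.lrt_df = len(step.params) - len(current.params)
        step.lrt_p = float(stats.chi2.sf(step.lrt_chi2, step.lrt_df))
        if step.lrt_p < alpha:
            step.accepted = True
            current = step
        steps.append(step)

    candidates = [s for s in steps if s.accepted]
    winner = min(candidates, key=lambda s: s.aic)
    res_reml, X = _fit_mixedlm(table, dv, winner.terms, reml=True)
    selected = _wrap(res_reml, X, winner.name + " (REML)", winner.terms, table, dv)
    return LadderResult(dv=dv, steps=steps, selected=selected, selected_terms=winner.terms)


# --- contrasts --------------------------------------------------------------


def _coding_row(level: str) -> dict[str, float]:
    return {f"c_{lev}": (1.0 if level == lev else 0.0) - 1.0 / 3.0 for lev in _SIMPLE_LEVELS}


def _mean_vector(names: list[str], level: str, order: float | None) -> np.ndarray:
    """Linear combination giving the model-implied condition mean.

    Age enters at its centered value 0; order at ``order`` if in the model.
    """
    code = _coding_row(level)
    v = np.zeros(len(names))
    for i, nm in enumerate(names):
        if nm == "Intercept":
            v[i] = 1.0
        elif nm == "order":
            v[i] = order if order is not None else 0.0
        elif nm in code:
            v[i] = code[nm]
        elif nm.startswith("order:"):
            v[i] = (order if order is not None else 0.0) * code[nm.split(":", 1)[1]]
    return v


def _slope_vector(names: list[str], level: str) -> np.ndarray:
    code = _coding_row(level)
    v = np.zeros(len(names))
    for i, nm in enumerate(names):
        if nm == "order":
            v[i] = 1.0
        elif nm.startswith("order:"):
            v[i] = code[nm.split(":", 1)[1]]
    return v


def _estimate(res, vec: np.ndarray) -> tuple[float, float]:
    est = float(vec @ res.fe_params)
    cov = np.asarray(res.cov_params())[: vec.size, : vec.size]
    se = float(np.sqrt(vec @ cov @ vec))
    return est, se


_PAIRS = (("doublet", "random"), ("doublet", "control"), ("control", "random"))


@dataclass
class ContrastResult:
    """Tukey-adjusted pairwise condition contrasts from the retained model.

    ``df`` is the residual degrees of freedom used for the studentized
    range (nobs - n_fixed).  ``means`` holds per-condition model-implied
    means (with 10^x back-transform for log-scale outcomes); ``pairwise``
    and ``slopes`` hold the contrast tables; ``by_order`` compares
    conditions at fixed trial orders.
    """

    dv: str
    df: int
    means: pd.DataFrame
    pairwise: pd.DataFrame
    slopes: pd.DataFrame | None
    by_order: pd.DataFrame | None


def _tukey_p(est: float, se: float, df: int, k: int = 3) -> float:
    if se <= 0:
        return float("nan")
    q = abs(est) / se * np.sqrt(2.0)
    return float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))


def post_hoc(ladder: LadderResult, orders: tuple[float, ...] = (1, 5, 9)) -> ContrastResult:
    """Pairwise condition contrasts (Tukey-adjusted) on the retained model.

    When condition is absent from the retained model the contrasts are
    computed from the condition-augmented design refit (so the three
    comparisons of interest are always available), flagged by the model
    name stored in the result tables.
    """
    sel = ladder.selected
    if "condition" not in sel.terms:
        res, X = _fit_mixedlm(sel._table, sel._dv, tuple(dict.fromkeys(sel.terms + ("condition",))), reml=True)
        sel = _wrap(res, X, sel.name + " (+condition for contrasts)", sel.terms + ("condition",), sel._table, sel._dv)
    res = sel._fit
    names = list(sel.params.index)
    df = sel.df_resid
    has_order = "order" in sel.terms
    has_inter = "condition:order" in sel.terms
    log_scale = ladder.dv in LOG_DVS

    # condition means at the mean order (marginal means)
    mean_order = float(sel._table["order"].mean()) if has_order else None
    mean_rows = []
    for lev in CONDITIONS:
        est, se = _estimate(res, _mean_vector(names, lev, mean_order))
        row = {
            "condition": lev,
            "estimate": est,
            "se": se,
            "ci_lo": est - 1.959964 * se,
            "ci_hi": est + 1.959964 * se,
        }
        if log_scale:
            row.update(
                back_mean=back_transform(est),
                back_ci_lo=back_transform(row["ci_lo"]),
                back_ci_hi=back_transform(row["ci_hi"]),
            )
        mean_rows.append(row)
    means = pd.DataFrame(mean_rows)

    pair_rows = []
    for a, b in _PAIRS:
        vec = _mean_vector(names, a, mean_order) - _mean_vector(names, b, mean_order)
        est, se = _estimate(res, vec)
        pair_rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "t": est / se if se > 0 else np.nan,
                "p_tukey": _tukey_p(est, se, df),
            }
        )
    pairwise = pd.DataFrame(pair_rows)

    slopes = None
    if has_inter:
        rows = []
        for lev in CONDITIONS:
            est, se = _estimate(res, _slope_vector(names, lev))
            rows.append({"condition": lev, "slope": est, "se": se})
        for a, b in _PAIRS:
            vec = _slope_vector(names, a) - _slope_vector(names, b)
            est, se = _estimate(res, vec)
            rows.append(
                {
                    "condition": f"{a} - {b}",
                    "slope": est,
                    "se": se,
                    "p_tukey": _tukey_p(est, se, df),
                }
            )
        slopes = pd.DataFrame(rows)

    by_order = None
    if has_order:
        rows = []
        for o in orders:
            for a, b in _PAIRS:
                vec = _mean_vector(names, a, o) - _mean_vector(names, b, o)
                est, se = _estimate(res, vec)
                rows.append(
                    {
                        "order": o,
                        "contrast": f"{a} - {b}",
                        "estimate": est,
                        "se": se,
                        "p_tukey": _tukey_p(est, se, df),
                    }
                )
        by_order = pd.DataFrame(rows)

    return ContrastResult(
        dv=ladder.dv, df=df, means=means, pairwise=pairwise, slopes=slopes, by_order=by_order
    )


def back_transform(log10_mean: float) -> float:
    """Return a log10-scale estimate to the SNR scale (10**x).

    Saturates to ``inf`` instead of overflowing when a degenerate fit yields
    an unbounded confidence limit.
    """
    with np.errstate(over="ignore"):
        return float(np.power(10.0, np.float64(log10_mean)))


# --- table-level generator for statistical validation -----------------------


def simulate_analysis_table(
    n_per_condition: int = 10,
    n_orders: int = 9,
    grand_mean: float = 0.15,
    condition_effects: dict[str, float] | None = None,
    order_slope: float = 0.0,
    age_effect: float = 0.0,
    subject_sd: float = 0.1,
    residual_sd: float = 0.2,
    rng: np.random.Generator | None = None,
    dv: str = "log_snr_doublet",
) -> pd.DataFrame:
    """Directly simulate a valid-trial table under a known mixed model.

    Used to validate the ladder, contrasts and ICC at scale (hundreds of
    cohorts) without synthesizing EEG.  ``condition_effects`` are additive
    offsets per condition (default all 0); between-subject intercepts are
    N(0, subject_sd^2); residuals N(0, residual_sd^2).  The requested ``dv``
    column is filled; ``snr_base``/``snr_doublet`` companions are added so
    :func:`build_table` consumers can run on the output.
    """
    rng = rng or np.random.default_rng()
    effects = condition_effects or {c: 0.0 for c in CONDITIONS}
    rows = []
    sid = 0
    for cond in CONDITIONS:
        for _ in range(n_per_condition):
            b = rng.normal(0.0, subject_sd)
            age = rng.uniform(120, 195)
            for order in range(1, n_orders + 1):
                y = (
                    grand_mean
                    + effects.get(cond, 0.0)
                    + order_slope * order
                    + age_effect * (age - 157.5)
                    + b
                    + rng.normal(0.0, residual_sd)
                )
                rows.append(
                    {
                        "subject_id": f"S{sid:02d}",
                        "condition": cond,
                        "age_days": age,
                        "order": order,
                        dv: y,
                    }
                )
            sid += 1
    t = pd.DataFrame(rows)
    t["age_c"] = t["age_days"] - t["age_days"].mean()
    if dv == "log_snr_doublet":
        t["snr_doublet"] = 10 ** t[dv]
        t["snr_base"] = 10 ** rng.normal(0.4, 0.1, size=len(t))
    elif dv == "log_snr_base":
        t["snr_base"] = 10 ** t[dv]
        t["snr_doublet"] = 10 ** rng.normal(0.0, 0.1, size=len(t))
    return t
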