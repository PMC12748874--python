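"""Derived behavioural measures and the trial-wise / group-level regressions.

From a trial table this module computes the estimated feedback implied by
the current ratings, rating errors and accuracies, the total prediction
error (tPE) and its control-weighted split into self- and other-assigned
parts (sPE, oPE), the feedback-difference-based point estimate of control,
and the regressors used by the trial-wise models (AD lags, switch flags,
inverse self).  It then fits the registered per-participant regressions
with standardized predictors, the cohort-level control-inference model,
and the group-level ANOVA / t-test / Spearman wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from disambig.task_engine import (
    PHASE_CONTROL_OTHER,
    PHASE_SELF_ONLY,
    PHASE_SELF_OTHER,
)

__all__ = [
    "RegressionResult",
    "FORMULAS",
    "estimated_feedback",
    "rating_accuracy",
    "compute_tpe_and_split",
    "infer_control_point",
    "add_derived_measures",
    "standardize",
    "fit_trialwise_regression",
    "build_switch_dataset",
    "fit_control_inference",
    "mixed_anova_test",
    "one_sample_test",
    "spearman_validation",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary derived quantities
# ---------------------------------------------------------------------------

def estimated_feedback(self_rating, other_rating, control_estimate):
    """Feedback implied by the current beliefs under the task equation.

    ``self_rating*control + other_rating*(1-control)``.  In the Self-Other
    phase the control estimate is the instructed true control level.
    """
    self_rating = np.asarray(self_rating, dtype=float)
    other_rating = np.asarray(other_rating, dtype=float)
    control = np.asarray(control_estimate, dtype=float)
    full = control == 1.0
    if np.any((self_rating < 0) | (self_rating > 100)):
        raise ValueError("self_rating outside [0, 100]")
    if np.any((control < 0) | (control > 1)):
        raise ValueError("control_estimate outside [0, 1]")
    checked_other = np.where(full, 0.0, other_rating)
    if np.any((checked_other < 0) | (checked_other > 100)):
        raise ValueError("other_rating outside [0, 100]")
    out = self_rating * control + checked_other * (1.0 - control)
    return out if out.ndim else float(out)


def rating_accuracy(rating, true_level):
    """Accuracy of a rating: ``1 - |rating - true| / max(100 - true, true)``.

    Both arguments live on the 0-100 scale (multiply control by 100 first);
    the denominator is the maximum possible error for that true level, so
    accuracy spans [0, 1].
    """
    rating = np.asarray(rating, dtype=float)
    true_level = np.asarray(true_level, dtype=float)
    if np.any((true_level < 0) | (true_level > 100)):
        raise ValueError("true_level outside [0, 100]")
    max_err = np.maximum(100.0 - true_level, true_level)
    out = 1.0 - np.abs(rating - true_level) / max_err
    return out if out.ndim else float(out)


def compute_tpe_and_split(feedback, est_feedback, control_estimate):
    """Total prediction error and its control-weighted self/other split.

    ``tPE = feedback - estimated feedback``; ``sPE = tPE * control`` and
    ``oPE = tPE - sPE`` (the other's complementary share), the unique
    linear split for which ``sPE + oPE = tPE`` holds exactly, bit for bit.
    """
    tpe = np.asarray(feedback, dtype=float) - np.asarray(est_feedback, dtype=float)
    control = np.asarray(control_estimate, dtype=float)
    spe = tpe * control
    ope = tpe - spe
    if tpe.ndim:
        return tpe, spe, ope
    return float(tpe), float(spe), float(ope)


def infer_control_point(feedback_difference, self_level):
    """Point estimate of control from the normal-vs-AD feedback difference.

    ``control = (normal feedback - AD feedback) / self``, clipped to [0, 1].
    Requires a positive self level (zero self performance makes the
    inference undefined).
    """
    self_level = float(self_level)
    if self_level <= 0:
        raise ValueError("self_level must be > 0 for control inference")
    return float(np.clip(float(feedback_difference) / self_level, 0.0, 1.0))


def _inverse_self(self_rating):
    """ln(1 / self rating), with ratings floored at 1 to keep the log finite."""
    return -np.log(np.maximum(np.asarray(self_rating, dtype=float), 1.0))


def standardize(x):
    """Z-score an array; a (numerically) constant column comes back as zeros."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    scale = max(1.0, np.abs(np.nanmean(x)))
    if not np.isfinite(sd) or sd <= 1e-12 * scale:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


# ---------------------------------------------------------------------------
# trial-table augmentation
# ---------------------------------------------------------------------------

def add_derived_measures(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the trial table with all derived per-trial measures.

    Adds: ``control_estimate`` (instructed control in Self-Other, control
    rating in Control-Other), ``est_feedback``, ``tpe``/``spe``/``ope``,
    per-target rating errors and accuracies, ``summed_rating_errors``,
    rating updates, lagged-AD indicators, ``other_changed``,
    ``inverse_self`` and the switch-trial ``feedback_difference``.
    Lag-based quantities are computed within phase and are NaN on the first
    trial(s) of a phase.
    """
    t = table.sort_values(["block", "trial_in_block"]).copy()
    is_so = t["phase_label"] == PHASE_SELF_OTHER
    is_co = t["phase_label"] == PHASE_CONTROL_OTHER
    is_sonly = t["phase_label"] == PHASE_SELF_ONLY

    t["control_estimate"] = np.where(
        is_so, t["true_control"], np.where(is_co, t["control_rating"], 1.0)
    )
    t["est_feedback"] = np.where(
        is_sonly,
        t["self_rating"],
        t["self_rating"] * t["control_estimate"]
        + t["other_rating"].fillna(0.0) * (1.0 - t["control_estimate"]),
    )
    tpe, spe, ope = compute_tpe_and_split(
        t["feedback"], t["est_feedback"], t["control_estimate"]
    )
    t["tpe"], t["spe"], t["ope"] = tpe, spe, ope

    # rating errors/accuracies against the scheduled true levels
    t["self_rating_error"] = np.abs(t["self_rating"] - t["true_self"])
    t["self_accuracy"] = rating_accuracy(t["self_rating"], t["true_self"])
    t["other_rating_error"] = np.abs(t["other_rating"] - t["true_other_level"])
    t["other_accuracy"] = np.where(
        is_sonly,
        np.nan,
        rating_accuracy(
            t["other_rating"].fillna(0.0), t["true_other_level"].fillna(0.0)
        ),
    )
    t["control_rating_error"] = np.abs(t["control_estimate"] - t["true_control"])
    t["control_accuracy"] = np.where(
        is_sonly,
        np.nan,
        rating_accuracy(100.0 * t["control_estimate"], 100.0 * t["true_control"]),
    )
    # estimated-feedback accuracy: true level = phase mean of normal feedback
    means = t.loc[~t["is_ad"]].groupby(["block", "phase_label"])["feedback"].mean()
    key = pd.MultiIndex.from_frame(t[["block", "phase_label"]])
    fb_ref = pd.Series(means.reindex(key).to_numpy(), index=t.index)
    t["feedback_true_level"] = fb_ref
    t["est_feedback_accuracy"] = rating_accuracy(
        np.clip(t["est_feedback"], 0, 100), np.clip(fb_ref, 0, 100)
    )
    t["summed_rating_errors"] = np.where(
        is_co,
        t["self_rating_error"]
        + t["other_rating_error"]
        + 100.0 * t["control_rating_error"],
        t["self_rating_error"] + t["other_rating_error"].fillna(0.0),
    )

    g = t.groupby(["block", "phase_label"], sort=False)
    t["self_update"] = t["self_rating"] - g["self_rating"].shift(1)
    t["other_update"] = t["other_rating"] - g["other_rating"].shift(1)
    t["control_update"] = t["control_rating"] - g["control_rating"].shift(1)
    t["tpe_prev"] = g["tpe"].shift(1)
    t["feedback_prev"] = g["feedback"].shift(1)
    t["feedback_change"] = t["feedback"] - t["feedback_prev"]
    t["ad_lag1"] = g["is_ad"].shift(1).astype(float)
    t["ad_lag2"] = g["is_ad"].shift(2).astype(float)
    prev_ad = g["is_ad"].shift(1)
    t["is_switch"] = prev_ad.notna() & (prev_ad != t["is_ad"])
    t["prev_ad"] = prev_ad.astype(float)
    t["other_changed"] = (
        (t["trial_in_phase"] >= 12) & ~is_sonly
    ).astype(float)
    t["inverse_self"] = _inverse_self(t["self_rating"])
    # signed normal-minus-AD feedback difference, defined on switch trials
    fb_diff = np.where(
        t["is_switch"] & t["is_ad"].astype(bool),
        t["feedback_prev"] - t["feedback"],  # normal -> AD
        np.where(
            t["is_switch"] & ~t["is_ad"].astype(bool),
            t["feedback"] - t["feedback_prev"],  # AD -> normal
            np.nan,
        ),
    )
    t["feedback_difference"] = fb_diff
    # next trial's control rating (outcome of the control-inference model)
    t["next_control_rating"] = g["control_rating"].shift(-1)
    return t


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    formula_id: str
    params: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi (95%)
    pvalues: pd.Series
    nobs: int
    selection: str
    participant: str = "group"

    def term(self, name: str) -> float:
        return float(self.params[name])


def _select_credit(t, target):
    sel = (
        (t["phase_label"] == PHASE_SELF_OTHER)
        & ~t["is_ad"].astype(bool)
        & t["tpe_prev"].notna()
    )
    d = t.loc[sel].copy()
    control = d["true_control"] if target == "self" else 1.0 - d["true_control"]
    X = pd.DataFrame(
        {
            "tpe": d["tpe_prev"],
            "control": control,
            "tpe_x_control": d["tpe_prev"] * control,
            "trial_number": d["trial_in_phase"],
        },
        index=d.index,
    )
    y = d[f"{target}_update"]
    return X, y, "normal Self-Other trials with a defined previous-trial tPE"


def _select_ad_lags(t, outcome):
    if outcome not in t.columns:
        raise ValueError(
            f"trial table lacks an {outcome!r} column; simulate with the agent's "
            "belief state or merge learner refits first"
        )
    sel = t["ad_lag1"].notna() & t["ad_lag2"].notna() & t[outcome].notna()
    d = t.loc[sel].copy()
    # other_changed enters both outcomes: the unannounced other change
    # inflates uncertainty and errors late in the phase, where AD is also
    # elevated, and would otherwise confound the AD lags.
    X = pd.DataFrame(
        {
            "ad_lag1": d["ad_lag1"],
            "ad_lag2": d["ad_lag2"],
            "trial_number": d["trial_in_phase"],
            "other_changed": d["other_changed"],
            "phase": (d["phase_label"] == PHASE_SELF_OTHER).astype(float),
        },
        index=d.index,
    )
    return X, d[outcome], "all trials with both AD lags defined"


FORMULAS = {
    "credit_self": lambda t: _select_credit(t, "self"),
    "credit_other": lambda t: _select_credit(t, "other"),
    "ad_uncertainty": lambda t: _select_ad_lags(t, "uncertainty"),
    "ad_rating_error": lambda t: _select_ad_lags(t, "summed_rating_errors"),
}


def _ols(X: pd.DataFrame, y, standardize_predictors=True):
    X = X.copy()
    if standardize_predictors:
        for c in X.columns:
            X[c] = standardize(X[c].to_numpy())
    X = sm.add_constant(X, has_constant="add")
    model = sm.OLS(np.asarray(y, dtype=float), X)
    fit = model.fit()
    # guard against silently dropped / collinear designs
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear terms: {worst}")
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["lo", "hi"]
    return fit, ci


def fit_trialwise_regression(
    table: pd.DataFrame,
    formula_id: str,
    participant: str = "participant",
    min_trials: int = 8,
) -> RegressionResult:
    """Fit one registered trial-wise formula to one participant's table.

    ``credit_self`` / ``credit_other``: rating update on previous-trial tPE,
    control (or 1-control), their interaction and trial number, on normal
    Self-Other trials.  ``ad_uncertainty``: uncertainty on lagged AD
    indicators, trial number, other-changed and phase.  ``ad_rating_error``:
    the same with summed rating errors as the outcome.  Predictors are
    z-scored on the analysed subset.
    """
    if formula_id not in FORMULAS:
        raise KeyError(f"unknown formula {formula_id!r}; options: {list(FORMULAS)}")
    derived = table if "tpe" in table.columns else add_derived_measures(table)
    X, y, selection = FORMULAS[formula_id](derived)
    if len(y) < min_trials:
        logger.info("participant %s skipped for %s: %d usable trials",
                    participant, formula_id, len(y))
        raise ValueError(
            f"too few usable trials ({len(y)} < {min_trials}) for {formula_id}"
        )
    fit, ci = _ols(X, y)
    return RegressionResult(
        formula_id=formula_id,
        params=fit.params,
        conf_int=ci,
        pvalues=fit.pvalues,
        nobs=int(fit.nobs),
        selection=selection,
        participant=participant,
    )


def build_switch_dataset(
    tables: dict[str, pd.DataFrame],
    control_col: str = "control_rating",
    min_switch_trials: int = 3,
) -> pd.DataFrame:
    """Assemble the Control-Other switch-trial dataset for control inference.

    One row per switch trial with a defined next-trial control rating:
    outcome (next trial's control), feedback difference, inverse self,
    previous control (the current trial's rating) and participant id.
    Participants with fewer than ``min_switch_trials`` rows are excluded
    (logged), mirroring the low-switch-count exclusion rule.
    """
    rows = []
    for pid, table in tables.items():
        d = table if "feedback_difference" in table.columns else add_derived_measures(table)
        sel = (
            (d["phase_label"] == PHASE_CONTROL_OTHER)
            & d["is_switch"].astype(bool)
            & d["feedback_difference"].notna()
            & d["next_control_rating"].notna()
        )
        d = d.loc[sel]
        if len(d) < min_switch_trials:
            logger.info("participant %s excluded: %d switch trials", pid, len(d))
            continue
        rows.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "next_control": d["next_control_rating"],
                    "feedback_difference": d["feedback_difference"],
                    "inverse_self": d["inverse_self"],
                    "prev_control": d[control_col],
                }
            )
        )
    if not rows:
        raise ValueError("no participant has enough switch trials")
    return pd.concat(rows, ignore_index=True)


def fit_control_inference(
    data: pd.DataFrame, hierarchical: bool = False
) -> tuple[RegressionResult, list[RegressionResult]]:
    """Fit the control-inference regression on the switch-trial dataset.

    ``next_control ~ feedback_difference + inverse_self + feedback_difference
    * inverse_self + prev_control``, predictors standardized across
    participants.  The default backend fits per participant and tests each
    coefficient against zero across participants (two-stage summary); with
    ``hierarchical=True`` a linear mixed model with per-participant random
    intercepts and feedback-difference slopes is fitted instead.
    Returns ``(group_result, per_participant_results)``.
    """
    d = data.copy()
    for c in ("feedback_difference", "inverse_self", "prev_control"):
        d[c] = standardize(d[c].to_numpy())
    d["fbdiff_x_invself"] = d["feedback_difference"] * d["inverse_self"]
    terms = ["feedback_difference", "inverse_self", "fbdiff_x_invself", "prev_control"]

    per_part: list[RegressionResult] = []
    for pid, grp in d.groupby("participant"):
        X = sm.add_constant(grp[terms], has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            logger.info("participant %s dropped: degenerate switch design", pid)
            continue
        fit = sm.OLS(grp["next_control"].to_numpy(), X).fit()
        ci = fit.conf_int(alpha=0.05)
        ci.columns = ["lo", "hi"]
        per_part.append(
            RegressionResult(
                formula_id="control_inference",
                params=fit.params,
                conf_int=ci,
                pvalues=fit.pvalues,
                nobs=int(fit.nobs),
                selection="Control-Other switch trials",
                participant=str(pid),
            )
        )

    if hierarchical:
        X = sm.add_constant(d[terms], has_constant="add")
        model = sm.MixedLM(
            d["next_control"].to_numpy(),
            X,
            groups=d["participant"].to_numpy(),
            exog_re=X[["const", "feedback_difference"]],
        )
        fit = model.fit(method="lbfgs", maxiter=500)
        params = fit.fe_params
        ci = fit.conf_int(alpha=0.05).loc[params.index]
        ci.columns = ["lo", "hi"]
        group = RegressionResult(
            formula_id="control_inference",
            params=params,
            conf_int=ci,
            pvalues=fit.pvalues.loc[params.index],
            nobs=int(fit.nobs),
            selection="Control-Other switch trials (mixed model)",
        )
        return group, per_part

    # two-stage: one-sample t-test per coefficient across participants
    coefs = pd.DataFrame({r.participant: r.params for r in per_part}).T
    means, los, his, ps = {}, {}, {}, {}
    for c in coefs.columns:
        vals = coefs[c].to_numpy()
        res = stats.ttest_1samp(vals, 0.0)
        lo, hi = res.confidence_interval(0.95)
        means[c], los[c], his[c], ps[c] = vals.mean(), lo, hi, res.pvalue
    group = RegressionResult(
        formula_id="control_inference",
        params=pd.Series(means),
        conf_int=pd.DataFrame({"lo": pd.Series(los), "hi": pd.Series(his)}),
        pvalues=pd.Series(ps),
        nobs=len(per_part),
        selection="Control-Other switch trials (two-stage)",
    )
    return group, per_part


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------

def mixed_anova_test(
    df: pd.DataFrame, dv: str, within: str, subject: str, between: str | None = None
) -> pd.DataFrame:
    """Mixed ANOVA (between: sample; within: stated factor) with eta-squared.

    Falls back to a paired t-test layout (single-group warning) when the
    between factor has one level or is omitted.
    """
    import pingouin as pg

    if between is not None and df[between].nunique() < 2:
        logger.warning("single-group input: reducing mixed ANOVA to within-only RM ANOVA")
        between = None
    if between is None:
        out = pg.rm_anova(data=df, dv=dv, within=within, subject=subject,
                          detailed=True)
    else:
        out = pg.mixed_anova(
            data=df, dv=dv, within=within, subject=subject, between=between
        )
    return out.rename(columns={"p-unc": "p_unc", "np2": "ng2"})


def one_sample_test(values, popmean: float = 0.0) -> dict:
    """Two-tailed one-sample t-test with Cohen's d and a 95% CI."""
    values = np.asarray(values, dtype=float)
    res = stats.ttest_1samp(values, popmean)
    lo, hi = res.confidence_interval(0.95)
    sd = values.std(ddof=1)
    d = (values.mean() - popmean) / sd if sd > 0 else np.inf
    return {
        "mean": float(values.mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "ci95": (float(lo), float(hi)),
        "cohens_d": float(d),
        "n": int(values.size),
    }


def spearman_validation(reported, detected) -> dict:
    """Spearman correlation (with CI) of reported vs detected AD counts."""
    import pingouin as pg

    res = pg.corr(np.asarray(reported, float), np.asarray(detected, float),
                  method="spearman")
    row = res.iloc[0]
    pcol = "p_val" if "p_val" in res.columns else "p-val"
    cicol = "CI95" if "CI95" in res.columns else "CI95%"
    return {
        "rho": float(row["r"]),
        "p": float(row[pcol]),
        "ci95": tuple(np.asarray(row[cicol], dtype=float)),
        "n": int(row["n"]),
    }
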