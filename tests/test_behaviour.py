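import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disambig import behaviour_pipeline as bp
from disambig import synthetic_cohort as sc


class TestElementaryMeasures:
    @pytest.mark.parametrize(
        "s, o, c, expected", [(80, 40, 0.5, 60.0), (50, 20, 0.8, 44.0), (63, 10, 1.0, 63.0)]
    )
    def test_estimated_feedback(self, s, o, c, expected):
        assert bp.estimated_feedback(s, o, c) == pytest.approx(expected)

    def test_estimated_feedback_scale_checks(self):
        with pytest.raises(ValueError):
            bp.estimated_feedback(120, 50, 0.5)
        with pytest.raises(ValueError):
            bp.estimated_feedback(50, 50, 1.2)

    @pytest.mark.parametrize(
        "rating, true, expected", [(70, 50, 0.6), (50, 50, 1.0), (0, 100, 0.0), (25, 80, 1 - 55 / 80)]
    )
    def test_rating_accuracy(self, rating, true, expected):
        assert bp.rating_accuracy(rating, true) == pytest.approx(expected)

    def test_rating_accuracy_rejects_bad_truth(self):
        with pytest.raises(ValueError):
            bp.rating_accuracy(50, 120)

    @pytest.mark.parametrize(
        "fb, est, c, expected",
        [
            (60, 50, 0.8, (10, 8, 2)),
            (50, 50, 0.4, (0, 0, 0)),
            (30, 70, 0.0, (-40, 0, -40)),
        ],
    )
    def test_tpe_split(self, fb, est, c, expected):
        assert bp.compute_tpe_and_split(fb, est, c) == pytest.approx(expected)

    @given(
        fb=st.floats(0, 100), est=st.floats(0, 100), c=st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_pe_split_sums_exactly(self, fb, est, c):
        tpe, spe, ope = bp.compute_tpe_and_split(fb, est, c)
        # oPE is constructed as tPE - sPE, so the identity holds to the ulp
        assert spe + ope == pytest.approx(tpe, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize(
        "diff, s, expected", [(40, 50, 0.8), (0, 37, 0.0), (62, 62, 1.0), (90, 50, 1.0)]
    )
    def test_infer_control_point(self, diff, s, expected):
        assert bp.infer_control_point(diff, s) == pytest.approx(expected)

    def test_infer_control_needs_positive_self(self):
        with pytest.raises(ValueError):
            bp.infer_control_point(10, 0)

    @given(x=st.lists(st.floats(-50, 50), min_size=3, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_standardize_idempotent(self, x):
        z = bp.standardize(np.asarray(x))
        np.testing.assert_allclose(bp.standardize(z), z, atol=1e-9)


class TestDerivedMeasures:
    def test_switch_and_lag_columns(self, participant_table):
        d = bp.add_derived_measures(participant_table)
        g = d.groupby(["block", "phase_label"], sort=False)
        prev = g["is_ad"].shift(1)
        expect = prev.notna() & (prev != d["is_ad"])
        pd.testing.assert_series_equal(d["is_switch"], expect, check_names=False)
        # first trial of each phase has no lagged quantities
        firsts = d[d.trial_in_phase == 1]
        assert firsts["tpe_prev"].isna().all()
        assert firsts["ad_lag1"].isna().all()
        # other_changed flags trials 12-16 of paired phases only
        assert (d["other_changed"] == ((d.trial_in_phase >= 12)
                                       & (d.phase_label != "self_only"))).all()

    def test_feedback_difference_is_normal_minus_ad(self, participant_table):
        d = bp.add_derived_measures(participant_table)
        sw = d[d["feedback_difference"].notna()]
        assert len(sw) > 0
        to_normal = sw[~sw.is_ad.astype(bool)]
        np.testing.assert_allclose(
            to_normal["feedback_difference"],
            to_normal["feedback"] - to_normal["feedback_prev"],
        )
        to_ad = sw[sw.is_ad.astype(bool)]
        np.testing.assert_allclose(
            to_ad["feedback_difference"], to_ad["feedback_prev"] - to_ad["feedback"]
        )

    def test_inverse_self_floors_at_one(self):
        t = pd.DataFrame(
            {"block": [1], "phase_label": ["control_other"], "trial_in_phase": [1],
             "trial_in_block": [1], "self_rating": [0.0], "other_rating": [50.0],
             "control_rating": [0.5], "objective_error": [1.0], "self_score": [50.0],
             "other_score": [50.0], "is_ad": [False], "is_switch": [False],
             "feedback": [50.0], "true_self": [50.0], "true_other_level": [50.0],
             "true_control": [0.5]}
        )
        d = bp.add_derived_measures(t)
        assert d["inverse_self"].iloc[0] == pytest.approx(0.0)  # ln(1/1)


class TestTrialwiseRegressions:
    def _table_from_linear_model(self, seed, betas=(1.5, -0.8, 0.6, 0.0), noise=1.0,
                                 n=500):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"tpe": rng.normal(size=n), "control": rng.normal(size=n),
             "tpe_x_control": rng.normal(size=n), "trial_number": rng.normal(size=n)}
        )
        y = X.to_numpy() @ np.asarray(betas) + rng.normal(0, noise, n)
        return X, y

    def test_recovers_known_coefficients(self):
        X, y = self._table_from_linear_model(0)
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for term, true in zip(["tpe", "control", "tpe_x_control", "trial_number"],
                              [1.5, -0.8, 0.6, 0.0]):
            assert abs(fit.params[term] - true) < 2 * fit.bse[term]

    def test_null_outcome_interval_coverage(self):
        """Pure-noise outcomes: 95% intervals cover zero ~95% of the time."""
        import statsmodels.api as sm

        covered = 0
        total = 0
        for seed in range(100):
            X, _ = self._table_from_linear_model(seed, n=60)
            rng = np.random.default_rng(1000 + seed)
            y = rng.normal(size=60)
            ci = sm.OLS(y, sm.add_constant(X)).fit().conf_int(alpha=0.05)
            inside = ((ci[0] <= 0) & (0 <= ci[1])).drop("const")
            covered += int(inside.sum())
            total += len(inside)
        assert covered >= 0.90 * total  # nominal coverage is 95% per interval

    def test_formula_registry_on_simulated_participant(self, participant_table):
        res = bp.fit_trialwise_regression(participant_table, "credit_self", "p")
        assert set(res.params.index) >= {"tpe", "control", "tpe_x_control",
                                         "trial_number"}
        res = bp.fit_trialwise_regression(participant_table, "ad_uncertainty", "p")
        assert set(res.params.index) >= {"ad_lag1", "ad_lag2", "other_changed"}
        assert res.nobs > 50

    def test_unknown_formula_and_short_tables_rejected(self, participant_table):
        with pytest.raises(KeyError):
            bp.fit_trialwise_regression(participant_table, "nope")
        tiny = participant_table.head(9)  # leaves only 7 trials with both lags
        with pytest.raises(ValueError, match="too few"):
            bp.fit_trialwise_regression(tiny, "ad_uncertainty")

    def test_collinear_design_names_terms(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            bp._ols(X, rng.normal(size=50))


class TestControlInference:
    def test_switch_dataset_excludes_sparse_participants(self, cohort):
        _, tables = cohort
        few = {pid: tab.head(40) for pid, tab in list(tables.items())[:3]}
        full = {list(tables)[0]: tables[list(tables)[0]]}
        data = bp.build_switch_dataset({**few, **full})
        assert set(data["participant"]) <= set(few) | set(full)

    def test_two_stage_group_has_interaction_term(self, cohort):
        _, tables = cohort
        data = bp.build_switch_dataset(tables)
        group, per = bp.fit_control_inference(data)
        assert "fbdiff_x_invself" in group.params.index
        assert group.nobs == len(per)
        assert {r.participant for r in per} == set(data["participant"].unique())
        # outcome responds to the feedback difference for behaving agents
        assert group.params["feedback_difference"] > 0
        assert group.pvalues["feedback_difference"] < 0.01


class TestGroupLevel:
    def test_identical_samples_show_no_between_effect(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=10)
        shift = vals + 1 + rng.normal(0, 0.5, 10)
        half = np.column_stack([vals, shift]).ravel()
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "dv": np.concatenate([half, half]),  # sample b copies sample a
                "time": np.tile(["start", "end"], 20),
                "sample": np.repeat(["a", "b"], 20),
            }
        )
        out = bp.mixed_anova_test(df, dv="dv", within="time", subject="subject",
                                  between="sample")
        p_between = float(out.loc[out["Source"] == "sample", "p_unc"].iloc[0])
        assert p_between > 0.9

    def test_within_shift_detected_with_power(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=30)
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(30), 2),
                    "dv": np.column_stack([base, base + 1.0 + rng.normal(0, 1, 30)]).ravel(),
                    "time": np.tile(["start", "end"], 30),
                }
            )
            out = bp.mixed_anova_test(df, dv="dv", within="time", subject="subject")
            p = float(out.loc[out["Source"] == "time", "p_unc"].iloc[0])
            hits += p < 0.05
        assert hits >= 40  # >= 80% power at a 1 SD within shift

    def test_one_sample_test_reports_effect_size(self):
        res = bp.one_sample_test(np.array([0.4, 0.6, 0.5, 0.45, 0.55]))
        assert res["p"] < 0.001 and res["cohens_d"] > 3
        assert res["ci95"][0] < res["mean"] < res["ci95"][1]

    def test_noiseless_debrief_correlates_perfectly(self):
        detected = np.array([1.0, 4.0, 2.0, 9.0, 6.0, 3.0, 7.0, 5.0])
        out = bp.spearman_validation(detected, detected)
        assert out["rho"] == pytest.approx(1.0)
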