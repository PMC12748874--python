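import numpy as np
import pandas as pd
import pytest
from scipy import stats

from disambig import belief_models as bm
from disambig import task_engine as te


class TestCredibleIntervalWidth:
    def test_initial_performance_prior_width(self):
        """The Normal(rating, 30) prior spans a 90% interval of ~98.70."""
        w = bm.credible_interval_width(stats.norm(50, 30), 0.9)
        assert w == pytest.approx(98.70, abs=0.01)

    def test_standard_normal_closed_form(self):
        w = bm.credible_interval_width(stats.norm(0, 1), 0.9)
        assert w == pytest.approx(2 * stats.norm.ppf(0.95), abs=1e-9)
        assert w == pytest.approx(3.2897, abs=1e-4)

    def test_width_vanishes_with_level(self):
        assert bm.credible_interval_width(stats.norm(0, 1), 1e-8) < 1e-6

    def test_sample_and_grid_inputs(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(50, 30, 200_000)
        assert bm.credible_interval_width(samples, 0.9) == pytest.approx(98.7, rel=0.02)
        x = np.linspace(-200, 300, 4001)
        w = stats.norm.pdf(x, 50, 30)
        assert bm.credible_interval_width((x, w), 0.9) == pytest.approx(98.7, abs=0.3)

    def test_degenerate_posterior_warns(self):
        with pytest.warns(UserWarning):
            assert bm.credible_interval_width(np.full(100, 3.0), 0.9) == 0.0

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            bm.credible_interval_width(stats.norm(0, 1), 1.2)


class TestComputeUncertainty:
    def test_self_other_average(self):
        u = bm.compute_uncertainty({"self": 98.70, "other": 98.70}, "self_other")
        assert u == pytest.approx(98.70)

    def test_control_other_rescales_control(self):
        u = bm.compute_uncertainty({"control": 0.5, "other": 40.0}, "control_other")
        assert u == pytest.approx(45.0)

    def test_missing_width_rejected(self):
        with pytest.raises(ValueError):
            bm.compute_uncertainty({"self": 10.0}, "self_other")
        with pytest.raises(ValueError):
            bm.compute_uncertainty({"self": 1.0, "other": 1.0}, "no_such_phase")


def _oracle_control_other(feedback, is_ad, self_level, prior, n=201, floor=1.0):
    """Independent dense-grid posterior for the Control-Other context."""
    other = np.linspace(0, 100, n)
    control = np.linspace(0, 1, n)
    sig = np.linspace(0.25, 15, n)
    O, C, S = np.meshgrid(other, control, sig, indexing="ij")
    logp = (
        stats.norm.logpdf(O, prior.other_mean, prior.other_sd)
        + stats.norm.logpdf(C, prior.control_mean, prior.control_sd)
        + stats.halfnorm.logpdf(S, scale=prior.sigma_scale)
    )
    for fb, ad in zip(feedback, is_ad):
        if ad:
            mu = O * (1 - C)
            sd = np.sqrt((S * (1 - C)) ** 2 + floor**2)
        else:
            mu = self_level * C + O * (1 - C)
            sd = np.sqrt((5.0 * C) ** 2 + (S * (1 - C)) ** 2 + floor**2)
        logp = logp + stats.norm.logpdf(fb, mu, sd)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    out = {}
    for name, axis, grid in (("other", 0, other), ("control", 1, control),
                             ("sigma_other", 2, sig)):
        w = p.sum(axis=tuple(i for i in range(3) if i != axis))
        out[name] = float(np.sum(w * grid))
    return out


PRIOR = bm.PriorSpec(other_mean=40.0, control_mean=0.5)
TOY_FB = [44.0, 4.0]
TOY_AD = [False, True]


class TestGridOracleEquivalence:
    @pytest.mark.parametrize("variant", bm.VARIANTS)
    def test_two_trial_posterior_matches_dense_grid(self, variant):
        """Sequential filter equals a 201-points-per-dimension brute force."""
        if variant == "active":
            ofb, oad = TOY_FB, TOY_AD
        elif variant == "ignorant":
            ofb, oad = TOY_FB, [False, False]
        else:  # passive discards the AD trial
            ofb, oad = [TOY_FB[0]], [False]
        oracle = _oracle_control_other(ofb, oad, 50.0, PRIOR)
        res = bm.fit_learner(
            TOY_FB, TOY_AD, variant, "control_other", PRIOR,
            clamped={"self": 50.0}, new_other_trial=None,
        )
        row = res.iloc[-1]
        for name, rng_ in (("other", 100.0), ("control", 1.0), ("sigma_other", 14.75)):
            assert row[f"{name}_mean"] == pytest.approx(
                oracle[name], abs=0.02 * rng_
            ), name


class TestLearnerVariants:
    def test_no_ad_sequences_make_all_variants_identical(self):
        rng = np.random.default_rng(4)
        fb = np.clip(rng.normal(50, 10, 8), 0, 100)
        ad = np.zeros(8, dtype=bool)
        fits = {
            v: bm.fit_learner(fb, ad, v, "control_other", PRIOR, clamped={"self": 55.0})
            for v in bm.VARIANTS
        }
        cols = [c for c in fits["active"].columns if c.endswith("_mean")]
        for v in ("ignorant", "passive"):
            pd.testing.assert_frame_equal(fits["active"][cols], fits[v][cols])

    def test_worked_example_control_converges(self):
        """Alternating 44/4 feedback with self 50 implies control 0.8."""
        fb = [44.0, 4.0] * 8
        ad = [False, True] * 8
        res = bm.fit_learner(fb, ad, "active", "control_other", bm.PriorSpec(),
                             clamped={"self": 50.0})
        assert res.iloc[-1]["control_mean"] == pytest.approx(0.8, abs=0.05)
        # the implied other level (AD feedback / other weight) is ~20
        assert res.iloc[-1]["other_mean"] == pytest.approx(20.0, abs=5.0)

    def test_passive_all_ad_prefix_reports_prior(self):
        res = bm.fit_learner([4.0, 5.0], [True, True], "passive", "control_other",
                             PRIOR, clamped={"self": 50.0})
        assert bool(res.iloc[-1]["prior_only"])
        assert res.iloc[-1]["control_mean"] == pytest.approx(
            res.iloc[0]["control_mean"], abs=1e-9
        )
        active = bm.fit_learner([4.0, 5.0], [True, True], "active", "control_other",
                                PRIOR, clamped={"self": 50.0})
        assert not bool(active.iloc[-1]["prior_only"])

    def test_truncation_keeps_means_on_support(self, participant_table):
        co = participant_table[participant_table.phase_label == "control_other"]
        grp = co[co.block == 1].sort_values("trial_in_phase")
        res = bm.fit_learner(
            grp["feedback"], grp["is_ad"], "active", "control_other",
            bm.PriorSpec(other_mean=5.0, control_mean=0.05),
            clamped={"self": float(grp["true_self"].iloc[0])},
        )
        assert res["other_mean"].between(0, 100).all()
        assert res["control_mean"].between(0, 1).all()
        assert (res["uncertainty"] >= 0).all()
        for p in ("self", "other", "control"):
            assert (res[f"{p}_ci_lo"] <= res[f"{p}_mean"] + 1e-9).all()
            assert (res[f"{p}_mean"] <= res[f"{p}_ci_hi"] + 1e-9).all()

    def test_new_other_reset_raises_uncertainty(self):
        """Re-estimating the other from trial 12 widens the other belief."""
        rng = np.random.default_rng(0)
        fb = np.clip(rng.normal(40, 3, 16), 0, 100)
        ad = np.zeros(16, dtype=bool)
        with_reset = bm.fit_learner(fb, ad, "active", "control_other", PRIOR,
                                    clamped={"self": 50.0})
        without = bm.fit_learner(fb, ad, "active", "control_other", PRIOR,
                                 clamped={"self": 50.0}, new_other_trial=None)
        w_reset = with_reset.iloc[12]["other_ci_hi"] - with_reset.iloc[12]["other_ci_lo"]
        w_none = without.iloc[12]["other_ci_hi"] - without.iloc[12]["other_ci_lo"]
        assert w_reset > w_none

    def test_uncertainty_declines_over_a_phase(self):
        """End-of-phase uncertainty is below the starting uncertainty."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            true_c, true_o, true_s = 0.5, 60.0, 50.0
            learner = bm.GridLearner("control_other", bm.PriorSpec(),
                                     clamped={"self": true_s})
            for t in range(1, 17):
                ad = rng.random() < 0.25
                s = 0.0 if ad else float(np.clip(rng.normal(true_s, 5), 0, 100))
                o = te.draw_other_score(true_o, 6.5, rng)
                learner.update(s * true_c + o * (1 - true_c), ad)
            hist = learner.history
            wins += hist[16]["uncertainty"] < hist[1]["uncertainty"]
        assert wins >= 95

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            bm.fit_learner([], [], "active", "control_other", PRIOR,
                           clamped={"self": 50.0})
        with pytest.raises(ValueError):
            bm.GridLearner("control_other", PRIOR)  # missing clamped self
        with pytest.raises(ValueError):
            bm.GridLearner("self_other", PRIOR)  # missing clamped control
        with pytest.raises(ValueError):
            bm.GridLearner("control_other", PRIOR, variant="oracle",
                           clamped={"self": 50.0})
        with pytest.raises(RuntimeError, match="trial 2"):
            bm.fit_learner([40.0, np.nan], [False, False], "active",
                           "control_other", PRIOR, clamped={"self": 50.0})
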