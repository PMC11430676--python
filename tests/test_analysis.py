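"""Outcome construction, centering, and model recovery checks."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from nfbtrain.analysis import (
    AnalysisError,
    brain_behavior_model,
    center_design,
    fit_training_model,
    moderation_analysis,
    motivation_model,
    per_participant_slopes,
    summarize_runs,
)
from nfbtrain.experiments import (
    acc_coupling_sign_recovery,
    simulate_null_run_summaries,
)
from nfbtrain.simulate import GROUP_PRESETS, simulate_training_course


def _toy_trials():
    """Four regulation trials + two baseline trials with hand-checkable
    summaries."""
    rows = [
        # participant, session, run, block_kind, correct, responded, rt,
        # earned, window_dacc, window_global, motivation
        ("p1", 1, 1, "baseline", True, True, 0.9, 0.0, 1000.0, 1000.0, 80.0),
        ("p1", 1, 1, "baseline", False, True, 1.1, 0.0, 1000.0, 1000.0, 80.0),
        ("p1", 1, 1, "regulation", True, True, 1.0, 2.5, 1010.0, 1000.0, 80.0),
        ("p1", 1, 1, "regulation", True, True, 0.8, 7.5, 1030.0, 1000.0, 80.0),
        ("p1", 1, 1, "regulation", False, True, 1.4, 0.0, 990.0, 1000.0, 80.0),
        ("p1", 1, 1, "regulation", False, False, np.nan, 0.0, 1010.0, 1000.0, 80.0),
    ]
    return pd.DataFrame(rows, columns=[
        "participant", "session", "run", "block_kind", "correct", "responded",
        "rt", "earned_points", "window_dacc", "window_global", "motivation"])


class TestSummaries:
    def test_toy_run_matches_hand_arithmetic(self):
        out = summarize_runs(_toy_trials())
        assert len(out) == 1
        row = out.iloc[0]
        assert row.reward_points == pytest.approx(10.0)  # 2.5 + 7.5
        assert row.accuracy == 2
        assert row.rt_mean == pytest.approx((1.0 + 0.8) / 2)
        assert row.dacc_ratio == pytest.approx((1.010 + 1.030 + 0.990 + 1.010) / 4)
        assert row.motivation == 80.0

    def test_no_correct_trials_leaves_rt_missing(self):
        df = _toy_trials()
        df["correct"] = False
        out = summarize_runs(df)
        assert np.isnan(out.iloc[0].rt_mean)
        assert out.iloc[0].accuracy == 0

    def test_run_without_regulation_trials_rejected(self):
        df = _toy_trials()
        with pytest.raises(AnalysisError):
            summarize_runs(df[df.block_kind == "baseline"])

    def test_canonical_bounds_hold_on_simulated_cohort(self, small_cohort):
        rs = summarize_runs(small_cohort.trials)
        assert rs.reward_points.between(0, 360).all()
        assert rs.accuracy.between(0, 36).all()
        assert len(rs) == 13 * 36


class TestCentering:
    def _balanced(self):
        rows = [(f"p{i}", s, r)
                for i in range(2) for s in range(1, 8) for r in range(1, 7)]
        return pd.DataFrame(rows, columns=["participant", "session", "run"])

    def test_balanced_session_centering(self):
        d = center_design(self._balanced())
        assert sorted(d.session_c.unique()) == [-3, -2, -1, 0, 1, 2, 3]
        assert abs(d.session_c.mean()) < 1e-12

    def test_run_centering_within_session(self):
        d = center_design(self._balanced())
        assert sorted(d.run_c.unique()) == [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5]
        assert (d.groupby("session").run_c.mean().abs() < 1e-12).all()

    def test_canonical_unbalanced_design_grand_mean(self):
        rows = [("p1", s, r)
                for s, n in enumerate((3, 6, 6, 6, 6, 6, 3), start=1)
                for r in range(1, n + 1)]
        d = center_design(pd.DataFrame(rows, columns=["participant",
                                                      "session", "run"]))
        # 36-run schedule is symmetric around session 4
        assert d.session_c.mean() == pytest.approx(0.0, abs=1e-12)
        assert d.session_c.min() == -3 and d.session_c.max() == 3

    def test_single_run_per_session_centers_to_zero(self):
        df = pd.DataFrame({"participant": "p1", "session": [1, 2, 3],
                           "run": [1, 1, 1]})
        d = center_design(df)
        assert (d.run_c == 0).all()

    def test_single_session_warns(self):
        df = pd.DataFrame({"participant": "p1", "session": [1, 1],
                           "run": [1, 2]})
        with pytest.warns(UserWarning, match="one session"):
            center_design(df)


def _injected_summaries(n_participants=4, session_slope=2.5, run_slope=0.0,
                        noise_sd=0.0, intercept_sd=0.0, seed=0,
                        runs_per_session=(6,) * 7, group=None):
    rng = np.random.default_rng(seed)
    rows = []
    sessions = range(1, len(runs_per_session) + 1)
    smean = np.mean([s for s, n in zip(sessions, runs_per_session)
                     for _ in range(n)])
    for i in range(n_participants):
        b = rng.normal(0, intercept_sd)
        for s, n_runs in zip(sessions, runs_per_session):
            for r in range(1, n_runs + 1):
                y = (50 + b + session_slope * (s - smean)
                     + run_slope * (r - (n_runs + 1) / 2)
                     + rng.normal(0, noise_sd))
                rows.append((f"{group or 'g'}-p{i}", s, r, y))
    df = pd.DataFrame(rows, columns=["participant", "session", "run",
                                     "reward_points"])
    if group is not None:
        df["group"] = group
    return df


class TestTrainingModel:
    def test_noiseless_slope_recovered_exactly(self):
        df = _injected_summaries(session_slope=2.5, run_slope=-1.25)
        fit = fit_training_model(df, "reward_points")
        assert fit.estimate("session_c") == pytest.approx(2.5, abs=1e-8)
        assert fit.estimate("run_c") == pytest.approx(-1.25, abs=1e-8)

    def test_balanced_mixed_model_equals_ols_oracle(self):
        df = _injected_summaries(session_slope=1.0, noise_sd=5.0,
                                 intercept_sd=8.0, seed=3)
        fit = fit_training_model(df, "reward_points")
        assert fit.converged
        fb = fit.fallback
        for term in ("session_c", "run_c", "session_c:run_c"):
            a = fit.estimate(term)
            b = float(fb.loc[fb.term == term, "estimate"].iloc[0])
            assert a == pytest.approx(b, abs=1e-6)

    def test_null_slope_not_flagged(self):
        rng = np.random.default_rng(1)
        df = simulate_null_run_summaries(10, rng)
        fit = fit_training_model(df, "reward_points")
        assert fit.pvalue("session_c") > 0.001  # no systematic session effect
        assert fit.n_obs == len(df)

    def test_listwise_missing_exclusion(self):
        df = _injected_summaries(noise_sd=1.0, seed=2)
        df.loc[df.index[:5], "reward_points"] = np.nan
        fit = fit_training_model(df, "reward_points")
        assert fit.n_obs == len(df) - 5

    def test_requires_two_participants(self):
        df = _injected_summaries(n_participants=1)
        with pytest.raises(AnalysisError):
            fit_training_model(df, "reward_points")

    def test_fallback_estimator_is_self_consistent(self):
        df = center_design(_injected_summaries(session_slope=2.0,
                                               noise_sd=1.0, seed=4))
        tab = per_participant_slopes(df, "reward_points")
        est = float(tab.loc[tab.term == "session_c", "estimate"].iloc[0])
        assert est == pytest.approx(2.0, abs=0.2)


class TestModeration:
    def _two_groups(self, slope_a, slope_b, seed=0):
        a = _injected_summaries(6, session_slope=slope_a, noise_sd=2.0,
                                intercept_sd=3.0, seed=seed,
                                group="experimental")
        b = _injected_summaries(6, session_slope=slope_b, noise_sd=2.0,
                                intercept_sd=3.0, seed=seed + 100,
                                group="age-control")
        return pd.concat([a, b], ignore_index=True)

    @staticmethod
    def _term(fit, pattern):
        hit = fit.fixed[fit.fixed.term.str.fullmatch(pattern)]
        assert len(hit) == 1, f"no unique term matching {pattern}"
        return float(hit.estimate.iloc[0])

    def test_identical_slopes_give_null_interaction(self):
        fit = moderation_analysis(self._two_groups(2.0, 2.0), "reward_points")
        inter = self._term(fit, r"session_c:C\(group.*age-control\]")
        assert inter == pytest.approx(0.0, abs=0.35)

    def test_known_contrast_recovered(self):
        fit = moderation_analysis(self._two_groups(3.0, 0.0), "reward_points")
        main = self._term(fit, r"session_c")
        inter = self._term(fit, r"session_c:C\(group.*age-control\]")
        assert main == pytest.approx(3.0, abs=0.35)
        assert inter == pytest.approx(-3.0, abs=0.5)

    def test_reference_relabeling_is_consistent(self):
        data = self._two_groups(3.0, 1.0)
        ref_exp = moderation_analysis(data, "reward_points",
                                      reference="experimental")
        ref_ctl = moderation_analysis(data, "reward_points",
                                      reference="age-control")
        exp_main = self._term(ref_exp, r"session_c")
        exp_inter = self._term(ref_exp, r"session_c:C\(group.*age-control\]")
        ctl_main = self._term(ref_ctl, r"session_c")
        # control slope expressed two ways must agree algebraically
        assert ctl_main == pytest.approx(exp_main + exp_inter, abs=1e-4)

    def test_missing_reference_rejected(self):
        df = _injected_summaries(4, group="age-control")
        with pytest.raises(AnalysisError, match="reference"):
            moderation_analysis(df, "reward_points")


class TestBrainBehavior:
    def test_generative_coupling_signs_recovered(self, small_cohort):
        tr = small_cohort.trials
        fits = brain_behavior_model(tr[tr.group == "experimental"])
        assert fits["rt"].estimate("dacc_sig") < 0
        assert fits["accuracy"].estimate("dacc_sig") > 0

    def test_zero_couplings_recover_null(self):
        preset = replace(GROUP_PRESETS["experimental"], rt_coupling=0.0,
                         acc_coupling=0.0)
        ds = simulate_training_course(
            n_per_group={"experimental": 8}, presets={"experimental": preset},
            seed=8, runs_per_session=(3, 3), assign_stims=False)
        fits = brain_behavior_model(ds.trials)
        for name in ("rt", "accuracy"):
            row = fits[name].fixed.set_index("term").loc["dacc_sig"]
            # the dACC ratio predictor has SD ~3e-3; a standardized effect
            # near zero is what "no coupling" must recover
            sd = (ds.trials.window_dacc / ds.trials.window_global).std()
            assert abs(row.estimate) * sd < 0.25
            assert abs(row.z) < 3.5

    def test_sign_recovery_rate_across_replicates(self):
        res = acc_coupling_sign_recovery(n_reps=100, seed=0)
        assert res["rate"] >= 0.95

    def test_degenerate_all_correct_is_flagged(self):
        df = _toy_trials()
        df["correct"] = True
        df["displayed_points"] = df["earned_points"]
        fits = brain_behavior_model(df)
        assert not fits["accuracy"].converged
        assert fits["accuracy"].warnings_


class TestMotivation:
    def _motivated_cohort(self, run_slope, seed=0):
        preset = replace(
            GROUP_PRESETS["age-control"], motivation_run_slope=run_slope,
            motivation_noise_sd=1.0, motivation_0_sd=1.0, motivation_0=80.0,
            gain_run_slope=0.0)
        return simulate_training_course(
            n_per_group={"age-control": 4}, presets={"age-control": preset},
            seed=seed, runs_per_session=(6, 6), assign_stims=False)

    def test_injected_run_slope_recovered(self):
        rs = summarize_runs(self._motivated_cohort(-5.0).trials)
        fit = motivation_model(rs)
        assert fit.estimate("run_c") == pytest.approx(-5.0, abs=0.5)

    def test_flat_motivation_recovers_null(self):
        rs = summarize_runs(self._motivated_cohort(0.0, seed=1).trials)
        fit = motivation_model(rs)
        assert fit.estimate("run_c") == pytest.approx(0.0, abs=0.5)

    def test_young_up_preset_declines_experimental_does_not(self, small_cohort):
        rs = summarize_runs(small_cohort.trials)
        two = rs[rs.group.isin(["experimental", "age-control"])]
        fit = motivation_model(two)
        run_main = float(fit.fixed.loc[fit.fixed.term == "run_c",
                                       "estimate"].iloc[0])
        inter = fit.fixed[fit.fixed.term.str.contains(
            r"run_c:C\(group.*age-control")]
        assert abs(run_main) < 1.5  # experimental group: flat
        assert float(inter.estimate.iloc[0]) < -3.0  # young group: decline

    def test_out_of_range_motivation_rejected(self):
        rs = summarize_runs(_toy_trials())
        rs["motivation"] = 150.0
        with pytest.raises(AnalysisError):
            motivation_model(rs)

    def test_constant_motivation_rejected(self):
        df = _injected_summaries(3, noise_sd=1.0)
        df["motivation"] = 50.0
        with pytest.raises(AnalysisError, match="constant"):
            motivation_model(df)
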