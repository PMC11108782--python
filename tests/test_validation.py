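"""Downstream validation statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import csfstage as cs


# ---------------------------------------------------------------------------
# stage trajectories and contrasts
# ---------------------------------------------------------------------------

class TestStageTrajectory:
    def test_identical_values_flat_and_nonsignificant(self):
        values = np.ones(60)
        stages = np.repeat(np.arange(6), 10)
        res = cs.stage_trajectory(values, stages)
        assert (res.contrasts["q"] == 1.0).all()
        assert res.summary["trend"].std() == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_stage_values_all_significant(self):
        stages = np.repeat(np.arange(6), 6)
        values = stages.astype(float)
        res = cs.stage_trajectory(values, stages)
        assert (np.diff(res.summary["trend"]) > 0).all()
        assert (res.contrasts["q"] < 0.05).all()

    def test_ranksum_matches_exhaustive_permutation(self):
        """Two-sided rank-sum on {1,2,3} vs {4,5,6} has exact p = 0.1
        (2 of the 20 arrangements are as extreme)."""
        values = np.array([1.0, 2, 3, 4, 5, 6])
        stages = np.array([0, 0, 0, 1, 1, 1])
        res = cs.stage_trajectory(values, stages)
        assert res.contrasts["p"].iloc[0] == pytest.approx(0.1)
        # same number from scipy's exact two-sample computation
        assert mannwhitneyu([1, 2, 3], [4, 5, 6],
                            alternative="two-sided").pvalue == pytest.approx(0.1)

    def test_small_group_contrast_skipped(self):
        values = np.array([1.0, 2, 3, 4, 9])
        stages = np.array([0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="skipped"):
            res = cs.stage_trajectory(values, stages)
        assert len(res.contrasts) == 0

    def test_bh_qvalues_monotone_and_above_p(self, cohort):
        res = cs.stage_trajectory(
            cohort["centiloids"].to_numpy(),
            cohort["truth_stage"].to_numpy(),
        )
        c = res.contrasts.sort_values("p")
        assert (c["q"].to_numpy() >= c["p"].to_numpy() - 1e-12).all()
        assert (np.diff(c["q"].to_numpy()) >= -1e-12).all()


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def rank_auc(stages, outcome):
    """Independent Mann-Whitney formulation of the AUC."""
    pos = stages[outcome == 1]
    neg = stages[outcome == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocOptimalStage:
    def test_perfect_predictor(self):
        stages = np.repeat(np.arange(6), 10)
        outcome = (stages >= 2).astype(int)
        res = cs.roc_optimal_stage(stages, outcome, n_boot=100, seed=0)
        assert res.auc == 1.0
        assert res.cutoff == 2
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_chance_level(self):
        res = cs.roc_optimal_stage([0, 0, 1, 1], [0, 1, 0, 1], n_boot=50,
                                   seed=0)
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            cs.roc_optimal_stage([0, 1, 2], [1, 1, 1], n_boot=10, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_rank_formula(self, seed):
        rng = np.random.default_rng(seed)
        stages = rng.integers(0, 6, 200)
        outcome = (rng.random(200) < (stages + 1) / 7).astype(int)
        res = cs.roc_optimal_stage(stages, outcome, n_boot=10, seed=0)
        assert res.auc == pytest.approx(rank_auc(stages, outcome))

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        stages = rng.integers(0, 6, 100)
        outcome = (rng.random(100) < stages / 5).astype(int)
        res = cs.roc_optimal_stage(stages, outcome, n_boot=500, seed=1)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_generator_amyloid_link_puts_cutoff_at_stage_2(self, cohort,
                                                           events, fitted):
        """With the amyloid-PET link centred between stages 1 and 2, the
        Youden-optimal threshold is CSF stage 2."""
        sa = cs.stage_subjects(events, fitted.model)
        res = cs.roc_optimal_stage(
            sa.stages, cohort["amyloid_pet_status"].to_numpy(),
            n_boot=200, seed=0,
        )
        assert res.cutoff == 2
        assert res.auc > 0.9

    def test_generator_tau_link_puts_cutoff_at_stage_4(self, cohort):
        """On planted stages the tau-PET link (centred between stages 3
        and 4) puts the Youden-optimal threshold at stage 4."""
        res = cs.roc_optimal_stage(
            cohort["truth_stage"].to_numpy(),
            cohort["tau_pet_status"].to_numpy(),
            n_boot=200, seed=0,
        )
        assert res.cutoff == 4


# ---------------------------------------------------------------------------
# ordinal prediction / concordance
# ---------------------------------------------------------------------------

def pairwise_c_index(stages, categories):
    """Exhaustive pair enumeration oracle."""
    conc = ties = usable = 0
    n = len(stages)
    for i in range(n):
        for j in range(i + 1, n):
            if categories[i] == categories[j]:
                continue
            usable += 1
            lo, hi = (i, j) if categories[i] < categories[j] else (j, i)
            if stages[lo] < stages[hi]:
                conc += 1
            elif stages[lo] == stages[hi]:
                ties += 1
    return (conc + 0.5 * ties) / usable


class TestOrdinalPrediction:
    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            cs.ordinal_prediction([0, 1, 2], ["A", "A", "A"], n_boot=10,
                                  seed=0)

    def test_perfectly_concordant_pairs(self):
        stages = np.repeat([0, 2, 4], 10)
        cats = np.repeat(["A", "B", "C"], 10)
        res = cs.ordinal_prediction(stages, cats, n_boot=50, seed=0)
        assert res.c_index == 1.0
        assert res.separation_flag  # clean separation detected

    def test_c_index_toy_and_oracle(self):
        """(0,A),(1,A),(2,B),(3,B),(4,C): 8 usable pairs, all concordant;
        injecting (4,A) makes 7 concordant of 12 usable."""
        stages = np.array([0, 1, 2, 3, 4])
        cats = np.array(["A", "A", "B", "B", "C"])
        assert cs.concordance_index(stages, cats) == 1.0
        assert pairwise_c_index(stages, cats) == 1.0
        stages2 = np.append(stages, 4)
        cats2 = np.append(cats, "A")
        oracle = pairwise_c_index(stages2, cats2)
        assert cs.concordance_index(stages2, cats2) == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", range(3))
    def test_c_index_matches_enumeration_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        stages = rng.integers(0, 6, 60)
        cats = rng.integers(0, 3, 60)
        assert cs.concordance_index(stages, cats) == pytest.approx(
            pairwise_c_index(stages, cats)
        )

    def test_agrees_with_statsmodels_on_noisy_data(self):
        """Proportional-odds coefficients match statsmodels OrderedModel
        (independent ML implementation) when there is no separation."""
        rng = np.random.default_rng(7)
        stages = rng.integers(0, 6, 400).astype(float)
        latent = stages + rng.logistic(0, 1.5, 400)
        cats = np.digitize(latent, [1.0, 3.5])
        res = cs.ordinal_prediction(stages, cats, n_boot=10, seed=0)
        assert not res.separation_flag
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        sm = OrderedModel(cats, stages, distr="logit").fit(
            method="bfgs", disp=False
        )
        assert res.coef == pytest.approx(np.asarray(sm.params)[0], abs=0.02)

    def test_predicted_probabilities_stochastically_ordered(self, cohort,
                                                            events, fitted):
        sa = cs.stage_subjects(events, fitted.model)
        res = cs.ordinal_prediction(
            sa.stages, cohort["diagnosis"].to_numpy(), n_boot=50, seed=0,
            categories=list(cs.simulate.DIAGNOSIS_LEVELS),
        )
        probs = res.stage_probs.to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        cum = probs.cumsum(axis=1)
        # cumulative P(category <= j) decreases with stage for every j
        assert (np.diff(cum[:, :-1], axis=0) <= 1e-9).all()


# ---------------------------------------------------------------------------
# longitudinal slopes
# ---------------------------------------------------------------------------

class TestSubjectSlopes:
    def test_exact_line(self):
        df = pd.DataFrame({"subject_id": "a", "time": [0.0, 1, 2],
                           "value": [1.0, 2, 3]})
        res = cs.subject_slopes(df)
        assert res["slope"].iloc[0] == pytest.approx(1.0)

    def test_constant_values_zero_slope(self):
        df = pd.DataFrame({"subject_id": "a", "time": [0.0, 1, 2],
                           "value": 5.0})
        assert cs.subject_slopes(df)["slope"].iloc[0] == pytest.approx(0.0)

    def test_insufficient_visits_excluded(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b", "b", "c", "c"],
             "time": [0.0, 0, 1, 2, 2],
             "value": [1.0, 1, 2, 3, 4]}
        )
        with pytest.warns(UserWarning, match="excluded 2"):
            res = cs.subject_slopes(df)
        assert list(res["subject_id"]) == ["b"]


# ---------------------------------------------------------------------------
# stage transitions
# ---------------------------------------------------------------------------

class TestStabilityTransitions:
    def test_identical_vectors_fully_stable(self):
        s = pd.Series([0, 1, 2, 3], index=list("abcd"))
        tm = cs.stability_transitions(s, s)
        assert tm.pct_stable == 100.0 and tm.n_pairs == 4

    def test_uniform_progression_one_stage(self):
        b = pd.Series([0, 1, 2], index=list("abc"))
        tm = cs.stability_transitions(b, b + 1)
        assert tm.pct_progressed == 100.0
        assert tm.pct_progressed_one_stage == 100.0

    def test_no_paired_subjects_raises(self):
        with pytest.raises(ValueError, match="paired"):
            cs.stability_transitions(pd.Series([1], index=["a"]),
                                     pd.Series([1], index=["b"]))

    def test_generator_followup_proportions(self, default_config):
        """Observed transition shares match the generator parameters after
        accounting for boundary clipping (computed expectation)."""
        import dataclasses

        cfg = dataclasses.replace(default_config, n_subjects=2000)
        c = cs.simulate_cohort(cfg)
        both = cs.simulate_followup(c, cfg)
        base = both[both["visit_time"] == 0].set_index("subject_id")
        fu = both[both["visit_time"] > 0].set_index("subject_id")
        tm = cs.stability_transitions(base["truth_stage"], fu["truth_stage"])
        p_stay, p_up, p_down = cfg.transition_probs
        pi = np.array(cfg.stage_distribution)
        exp_stable = p_stay + pi[0] * p_down + pi[-1] * p_up
        exp_up = p_up * (1 - pi[-1])
        exp_down = p_down * (1 - pi[0])
        n = tm.n_pairs
        assert tm.pct_stable / 100 == pytest.approx(
            exp_stable, abs=4 * np.sqrt(exp_stable * (1 - exp_stable) / n))
        assert tm.pct_progressed / 100 == pytest.approx(
            exp_up, abs=4 * np.sqrt(exp_up * (1 - exp_up) / n))
        assert tm.pct_regressed / 100 == pytest.approx(
            exp_down, abs=4 * np.sqrt(exp_down * (1 - exp_down) / n))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def hand_cox_partial_loglik(beta, times, events, x):
    """Hand-coded Breslow partial log-likelihood (no ties in the data used)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestKmCox:
    def test_no_events_km_flat_hr_undefined(self):
        res = cs.km_cox(
            time=[1.0, 2, 3, 4], event=[0, 0, 0, 0],
            group=["1-3", "1-3", "4-5", "4-5"],
        )
        for curve in res.km_curves.values():
            assert (curve["survival"] == 1.0).all()
        assert np.isnan(res.hazard_ratio) and "undefined" in res.note

    def test_tied_pair_efron_hr_is_one(self):
        """Two subjects, tied event times, one per group: the Efron
        partial likelihood is maximized exactly at HR = 1."""
        res = cs.km_cox(time=[1.0, 1.0], event=[1, 1],
                        group=["1-3", "4-5"])
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-4)

    def test_matches_hand_partial_likelihood(self):
        """Four untied subjects: lifelines' estimate maximizes the
        hand-coded partial likelihood (independent grid/scipy oracle)."""
        from scipy.optimize import minimize_scalar

        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = cs.km_cox(times, events,
                        np.where(x == 1, "4-5", "1-3"))
        opt = minimize_scalar(
            lambda b: -hand_cox_partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
        )
        assert np.log(res.hazard_ratio) == pytest.approx(opt.x, abs=1e-3)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 40).round(2) + 0.01
        res = cs.km_cox(t, np.ones(40, int), np.repeat("1-3", 40),
                        reference="1-3", comparison="none")
        curve = res.km_curves["1-3"]
        for tt, s in zip(curve["time"], curve["survival"]):
            if tt > 0:
                assert s == pytest.approx(np.mean(t > tt) + 1e-12, abs=1e-9)

    def test_planted_hazard_ratio_recovered(self, default_config):
        """Cox HR on generator survival data close to the planted
        0.15/0.02 ratio (single large cohort)."""
        import dataclasses

        cfg = dataclasses.replace(default_config, n_subjects=4000)
        c = cs.simulate_cohort(cfg)
        groups = cs.stage_group_labels(c["truth_stage"])
        mask = groups.isin(["1-3", "4-5"]).to_numpy()
        res = cs.km_cox(c["time_to_event"].to_numpy()[mask],
                        c["event"].to_numpy()[mask],
                        groups.to_numpy()[mask])
        assert res.hr_ci[0] < 7.5 < res.hr_ci[1]
        assert res.hazard_ratio == pytest.approx(7.5, rel=0.35)
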