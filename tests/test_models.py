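"""Logistic/multinomial fits, screening, stepwise AIC, table models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from engagetraj.models import (
    RankDeficiencyError,
    SeparationError,
    baseline_predictor_model,
    fit_logistic,
    fit_multinomial,
    group_outcome_model,
    model_report,
    stepwise_aic,
    univariate_screen,
)
from conftest import participant_table


def two_group_data(n_a=100, n_b=100, events_a=23, events_b=56):
    y = np.r_[np.ones(events_a), np.zeros(n_a - events_a),
              np.ones(events_b), np.zeros(n_b - events_b)]
    x = pd.DataFrame({"group_b": np.r_[np.zeros(n_a), np.ones(n_b)]})
    return y, x


class TestLogistic:
    def test_two_by_two_or_matches_cross_product(self):
        y, x = two_group_data()
        fit = fit_logistic(y, x)
        expected = (56 * 77) / (44 * 23)
        assert fit.odds_ratio("group_b") == pytest.approx(expected, abs=1e-6)

    def test_equal_rates_give_unit_or(self):
        y, x = two_group_data(events_a=30, events_b=30)
        assert fit_logistic(y, x).odds_ratio("group_b") == pytest.approx(1.0, abs=1e-9)

    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.table.loc["Intercept", "coef"] == pytest.approx(np.log(25 / 75),
                                                                   abs=1e-8)
        expected_llf = 25 * np.log(0.25) + 75 * np.log(0.75)
        assert fit.log_likelihood == pytest.approx(expected_llf, abs=1e-6)
        assert fit.aic == pytest.approx(2 - 2 * expected_llf, abs=1e-6)

    def test_wald_interval_contract(self):
        y, x = two_group_data()
        t = fit_logistic(y, x).table
        assert np.allclose(t["odds_ratio"], np.exp(t["coef"]), rtol=1e-12)
        assert (t["ci_low"] <= t["ci_high"]).all()

    def test_separation_detected(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = pd.DataFrame({"mirror": y})
        with pytest.raises(SeparationError):
            fit_logistic(y, x)

    def test_collinear_design_named(self):
        y, x = two_group_data()
        x["twin"] = x["group_b"]
        with pytest.raises(RankDeficiencyError, match="twin"):
            fit_logistic(y, x)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), pd.DataFrame(index=range(10)))


class TestMultinomial:
    def test_two_categories_reduce_to_logistic(self, rng):
        x = pd.DataFrame({"z": rng.normal(size=400)})
        y = (rng.random(400) < expit(0.5 + 0.8 * x["z"])).astype(int)
        logi = fit_logistic(y.to_numpy(), x)
        multi = fit_multinomial(np.where(y, "b", "a"), x, reference="a")
        for term in ("Intercept", "z"):
            assert multi.table.loc[("b", term), "coef"] == pytest.approx(
                logi.table.loc[term, "coef"], abs=1e-6)

    def test_null_covariate_or_near_one(self, rng):
        n = 10_000
        y = rng.choice(list("abc"), size=n, p=[0.5, 0.3, 0.2])
        x = pd.DataFrame({"noise": rng.normal(size=n)})
        fit = fit_multinomial(y, x, reference="a")
        ors = fit.table.xs("noise", level="term")["odds_ratio"]
        assert ((ors > 0.9) & (ors < 1.1)).all()

    def test_planted_category_effect_recovered(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        base = np.ones(n)
        eta_b, eta_c = np.zeros(n), -0.3 + np.log(2) * x
        denom = base + np.exp(eta_b) + np.exp(eta_c)
        u = rng.random(n)
        p_a, p_b = base / denom, np.exp(eta_b) / denom
        y = np.where(u < p_a, "a", np.where(u < p_a + p_b, "b", "c"))
        fit = fit_multinomial(y, pd.DataFrame({"x": x}), reference="a")
        assert 1.8 < fit.odds_ratio("x", category="c") < 2.2

    def test_missing_category_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_multinomial(["a"] * 10 + ["b"] * 10, pd.DataFrame(index=range(20)),
                            reference="c")


class TestScreen:
    def test_type_one_error_calibrated_on_noise(self):
        retained = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = (r.random(5000) < 0.3).astype(float)
            cov = pd.DataFrame(r.normal(size=(5000, 40)),
                               columns=[f"c{i:02d}" for i in range(40)])
            retained += len(univariate_screen(y, cov).kept)
        # total kept ~ Binomial(200, 0.05): 10 +/- 3*sqrt(200*.05*.95)
        assert abs(retained - 10) <= 3 * np.sqrt(200 * 0.05 * 0.95)

    def test_separating_covariate_retained_and_flagged(self):
        y = np.r_[np.zeros(30), np.ones(30)]
        cov = pd.DataFrame({"copy": y})
        res = univariate_screen(y, cov)
        assert res.kept == ["copy"] and res.separating == ["copy"]

    def test_empty_covariate_set(self):
        res = univariate_screen(np.r_[0.0, 1.0, 0.0, 1.0], pd.DataFrame(index=range(4)))
        assert res.kept == []


class TestStepwise:
    def make_data(self, rng, n=5000, beta=np.log(2)):
        true = rng.normal(size=n)
        noise = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=[f"n{i}" for i in range(5)])
        y = (rng.random(n) < expit(-0.5 + beta * true)).astype(float)
        cand = noise.copy()
        cand["true_cov"] = true
        return y, cand

    def test_true_covariate_selected(self, rng):
        y, cand = self.make_data(rng)
        forced = pd.DataFrame(index=cand.index)
        fit = stepwise_aic(y, forced, cand)
        assert "true_cov" in fit.terms

    def test_final_aic_never_exceeds_forced_model(self, rng):
        y, cand = self.make_data(rng)
        forced = pd.DataFrame(index=cand.index)
        base = fit_logistic(y, forced)
        fit = stepwise_aic(y, forced, cand)
        assert fit.aic <= base.aic

    def test_all_noise_keeps_nearly_nothing(self, rng):
        y, cand = self.make_data(rng, beta=0.0)
        cand = cand.drop(columns="true_cov")
        fit = stepwise_aic(y, pd.DataFrame(index=cand.index), cand)
        assert len(fit.terms) <= 2  # intercept plus at most one lucky noise term

    def test_invalid_direction_rejected(self, rng):
        y, cand = self.make_data(rng, n=100)
        with pytest.raises(ValueError):
            stepwise_aic(y, pd.DataFrame(index=cand.index), cand, direction="back")


class TestGroupOutcomeModel:
    def test_planted_rates_give_closed_form_or(self, icq_run):
        records, result = icq_run
        table = participant_table(records, result.matrix)
        fit = group_outcome_model(result.solution, table)
        assert fit.reference_levels["group"] == "1-week users"
        or_26 = fit.odds_ratio("group[26-week users]")
        closed_form = (0.56 * 0.77) / (0.44 * 0.23)  # ~4.26 from planted rates
        lo = fit.table.loc["group[26-week users]", "ci_low"]
        hi = fit.table.loc["group[26-week users]", "ci_high"]
        assert lo < closed_form < hi
        assert 2.5 < or_26 < 7.5

    def test_null_outcome_gives_unit_ors(self, icq_run, rng):
        records, result = icq_run
        table = participant_table(records, result.matrix)
        table = table.copy()
        table["abstinent"] = (rng.random(len(table)) < 0.3).astype(float)
        fit = group_outcome_model(result.solution, table)
        for term in fit.terms:
            if term.startswith("group["):
                lo = fit.table.loc[term, "ci_low"]
                hi = fit.table.loc[term, "ci_high"]
                assert lo < 1.0 < hi

    def test_group_without_outcomes_rejected(self, icq_run):
        records, result = icq_run
        table = participant_table(records, result.matrix).copy()
        smallest = np.argmin(result.solution.group_sizes)
        table.loc[result.solution.labels == smallest, "abstinent"] = np.nan
        with pytest.raises(ValueError, match="zero retained outcomes"):
            group_outcome_model(result.solution, table)

    def test_missing_as_smoker_recodes(self, icq_run, rng):
        records, result = icq_run
        table = participant_table(records, result.matrix).copy()
        drop = rng.random(len(table)) < 0.1
        table.loc[drop, "abstinent"] = np.nan
        fit = group_outcome_model(result.solution, table, missing_as_smoker=True)
        assert fit.n_used == len(table)


class TestBaselinePredictorModel:
    def test_two_group_solution_routes_to_logistic(self, qg_run, rng):
        records, result = qg_run
        table = participant_table(records, result.matrix)
        fit = baseline_predictor_model(result.solution, table,
                                       ["age", "female", "minority"])
        assert fit.model_family == "logistic"
        assert fit.reference_levels["group"] == "1-week users"

    def test_three_group_solution_routes_to_multinomial(self, icq_run):
        records, result = icq_run
        table = participant_table(records, result.matrix).copy()
        # plant a membership signal so at least one covariate survives
        sol = result.solution
        most = sol.groups_by_persistence()[-1]
        r = np.random.default_rng(8)
        table["engaged_marker"] = r.normal(size=len(table)) + 0.8 * (
            sol.labels == most)
        fit = baseline_predictor_model(sol, table, ["engaged_marker", "age"])
        assert fit.model_family == "multinomial"
        assert fit.odds_ratio("engaged_marker", category="26-week users") > 1.3


class TestCoverage:
    def test_planted_effect_inside_wald_ci_most_of_the_time(self):
        beta = np.log(2)
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = pd.DataFrame({"x": r.normal(size=5000)})
            y = (r.random(5000) < expit(-0.4 + beta * x["x"])).astype(float)
            t = fit_logistic(y.to_numpy(), x).table
            if t.loc["x", "ci_low"] <= np.exp(beta) <= t.loc["x", "ci_high"]:
                hits += 1
        assert hits >= 45  # >= 90% coverage


def test_model_report_structure(icq_run):
    records, result = icq_run
    table = participant_table(records, result.matrix)
    report = model_report(group_outcome_model(result.solution, table))
    assert {"term", "odds_ratio", "ci_low", "ci_high", "p_value", "aic"} <= set(
        report.columns)
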