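import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import predsize as ps
from predsize.metrics import (
    PredictionMatrix,
    _logistic_irls,
    treat_all_net_benefit,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def _all_pairs_c(p, y):
    events = p[y == 1]
    nonevents = p[y == 0]
    wins = ties = 0
    for a in events:
        for b in nonevents:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(events) * len(nonevents))


class TestCStatistic:
    @given(st.integers(0, 10_000))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.choice([0.1, 0.3, 0.5, 0.7], size=20)  # forced ties
        y = rng.integers(0, 2, size=20).astype(float)
        if y.min() == y.max():
            y[0] = 1.0 - y[0]
        assert ps.c_statistic(p, y) == pytest.approx(_all_pairs_c(p, y))

    def test_perfect_and_random(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert ps.c_statistic(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert ps.c_statistic(np.array([0.5, 0.5, 0.5, 0.5]), y) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ps.c_statistic(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestCalibration:
    def test_well_calibrated_risks(self):
        rng = np.random.default_rng(0)
        p = expit(rng.normal(0.0, 1.5, 200_000))
        y = (rng.random(p.size) < p).astype(float)
        slope, intercept, _, flagged = ps.calibration(p, y)
        assert not flagged
        assert slope == pytest.approx(1.0, abs=0.02)
        assert intercept == pytest.approx(0.0, abs=0.02)

    def test_overfitted_risks_give_slope_below_one(self):
        rng = np.random.default_rng(1)
        lp = rng.normal(0.0, 1.0, 100_000)
        y = (rng.random(lp.size) < expit(lp)).astype(float)
        p_over = expit(2.0 * lp)  # spread out too far
        slope, _, _, _ = ps.calibration(p_over, y)
        assert slope == pytest.approx(0.5, abs=0.03)

    def test_intercept_detects_systematic_shift(self):
        rng = np.random.default_rng(2)
        p = expit(rng.normal(-1.0, 1.0, 100_000))
        y = (rng.random(p.size) < p).astype(float)
        p_low = expit(logit(p) - 0.8)  # under-prediction
        _, intercept, _, _ = ps.calibration(p_low, y)
        assert intercept == pytest.approx(0.8, abs=0.05)

    def test_constant_predictions_flagged(self):
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        slope, intercept, _, flagged = ps.calibration(np.full(5, 0.6), y)
        assert flagged
        assert slope == 0.0

    def test_irls_matches_statsmodels_glm(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(500), rng.normal(size=500)])
        y = (rng.random(500) < expit(0.3 + 0.8 * X[:, 1])).astype(float)
        ours = _logistic_irls(X, y)
        theirs = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_irls_offset_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        off = rng.normal(size=400)
        X = np.ones((400, 1))
        y = (rng.random(400) < expit(0.5 + off)).astype(float)
        ours = _logistic_irls(X, y, offset=off)
        theirs = sm.GLM(y, X, family=sm.families.Binomial(), offset=off).fit().params
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_calibration_curve_tracks_truth(self):
        rng = np.random.default_rng(5)
        p = expit(rng.normal(0.0, 1.0, 50_000))
        y = (rng.random(p.size) < p).astype(float)
        grid, observed = ps.calibration_curve(p, y)
        mid = (grid > 0.2) & (grid < 0.8)
        assert np.abs(grid[mid] - observed[mid]).max() < 0.05


class TestPredictionError:
    @given(st.integers(0, 1000))
    def test_rmspe_at_least_mape(self, seed):
        rng = np.random.default_rng(seed)
        p_hat = rng.random(50)
        p_true = rng.random(50)
        mape, rmspe = ps.prediction_error(p_hat, p_true)
        assert rmspe >= mape - 1e-12

    def test_hand_example(self):
        mape, rmspe = ps.prediction_error([0.2, 0.5], [0.1, 0.7])
        assert mape == pytest.approx(0.15)
        assert rmspe == pytest.approx(np.sqrt((0.01 + 0.04) / 2))


class TestNetBenefit:
    def test_treat_all_formula(self):
        assert treat_all_net_benefit(0.68, 0.5) == pytest.approx(0.36)

    def test_hand_counts(self):
        y = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        classify = np.array([1, 0, 1, 0, 0])
        # TP=1, FP=1, n=5, t=0.2 -> 0.2 - 0.2*0.25
        assert ps.net_benefit(classify, y, 0.2) == pytest.approx(0.2 - 0.2 * 0.25)

    def test_treat_none_is_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert ps.net_benefit(np.zeros(3), y, 0.3) == 0.0

    def test_value_of_information(self):
        degradation, rvsi = ps.value_of_information(0.36, 0.41)
        assert rvsi == pytest.approx(100 * 0.36 / 0.41)
        assert degradation == pytest.approx(-0.05)

    def test_rvsi_undefined_when_nb_max_nonpositive(self):
        with pytest.warns(RuntimeWarning):
            _, rvsi = ps.value_of_information(0.0, 0.0)
        assert np.isnan(rvsi)

    def test_winner_prefers_model_on_ties(self):
        rng = np.random.default_rng(6)
        p = expit(rng.normal(0.5, 1.0, 5000))
        y = (rng.random(5000) < p).astype(float)
        # oracle risks: the model should win (or tie) against treat-all/none
        nb_win = ps.winner_net_benefit(p, y, p, y, 0.5)
        nb_model = ps.net_benefit((p >= 0.5).astype(int), y, 0.5)
        assert nb_win == pytest.approx(nb_model)


class TestInstability:
    def _pm(self):
        values = np.array([[0.1, 0.2, 0.3, 0.4], [0.6, 0.6, 0.6, 0.6]])
        truth = np.array([0.25, 0.4])
        return PredictionMatrix(values=values, truth=truth, ids=np.array([0, 1]))

    def test_misclassification(self):
        pm = self._pm()
        # ind 0: truth 0.25 < 0.5, draws all below 0.5 -> never misclassified
        # ind 1: truth 0.4 < 0.5, draws all 0.6 -> always misclassified
        np.testing.assert_allclose(
            ps.misclassification_probability(pm, 0.5), [0.0, 1.0]
        )

    def test_threshold_boundary_counts_as_positive(self):
        pm = PredictionMatrix(
            values=np.array([[0.5, 0.5]]), truth=np.array([0.4]), ids=np.array([0])
        )
        np.testing.assert_allclose(ps.misclassification_probability(pm, 0.5), [1.0])

    def test_instability_summaries(self):
        pm = self._pm()
        tab = ps.instability_summaries(pm)
        assert tab.loc[0, "interval_width"] == pytest.approx(0.3, abs=0.02)
        assert bool(tab.loc[1, "ess_capped"])  # zero variance capped


class TestR2:
    def test_matches_statsmodels_likelihoods(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=2000)
        p = expit(0.2 + 0.9 * x)
        y = (rng.random(2000) < p).astype(float)
        r2_cs, r2_n = ps.r2_measures(p, y)
        n = y.size
        ll_model = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        ybar = y.mean()
        ll_null = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        expected_cs = 1 - np.exp(-2 * (ll_model - ll_null) / n)
        assert r2_cs == pytest.approx(expected_cs, rel=1e-6)
        assert r2_n == pytest.approx(expected_cs / (1 - np.exp(2 * ll_null / n)), rel=1e-6)


class TestEvaluate:
    def test_oracle_predictions_have_zero_degradation(self, small_population):
        pop = small_population
        c_true = ps.c_statistic(pop.p, pop.y)
        m = ps.evaluate_predictions(pop.p, pop, c_true=c_true, thresholds=(0.3,))
        assert m.mape == pytest.approx(0.0, abs=1e-12)
        assert m.degradations["c"] == pytest.approx(0.0, abs=1e-12)
        assert m.cal_slope == pytest.approx(1.0, abs=0.05)
        row = m.to_row()
        assert "rvsi@0.3" in row and "nb_model@0.3" in row

    def test_subgroup_metrics_partial_on_single_class(self, small_population):
        import pandas as pd

        pop = small_population
        groups = pd.DataFrame({"g": ["a"] * (pop.n_T - 1) + ["b"]})
        by = ps.subgroup_metrics(pop.p, pop, groups, "g")
        assert set(by) == {"a", "b"}
        assert by["a"].mape == pytest.approx(0.0, abs=1e-12)
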