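import json

import numpy as np
import pandas as pd
import pytest

import predsize as ps
from predsize.engine import AssuranceTarget, Criterion, summarise


def _sim(strategy="logistic", n=150, n_sims=6, seed=3, **kw):
    return ps.SampleSizeSimulation(
        ps.CaseMixSpec.standard_normal(4),
        {"relative_beta": [1.0] * 4, "target_c": 0.72, "target_prev": 0.3},
        strategy,
        n,
        n_sims=n_sims,
        population_size=10_000,
        seed=seed,
        calibration_sample_size=10_000,
        instability_individuals=200,
        **kw,
    )


@pytest.fixture(scope="module")
def small_run():
    return _sim().fit()


class TestSummarise:
    def test_known_values(self):
        v = np.arange(1, 101, dtype=float)
        s = summarise(v, metric="m")
        assert s.mean == pytest.approx(50.5)
        assert s.q025 == pytest.approx(np.percentile(v, 2.5))
        assert s.mc_se == pytest.approx(v.std(ddof=1) / 10.0)
        assert not s.flagged

    def test_single_draw_flagged(self):
        s = summarise([3.0], metric="m")
        assert s.flagged
        assert np.isnan(s.mc_se)

    def test_assurance_probability(self):
        t = AssuranceTarget("in_unit", "m", 0.0, 1.0)
        s = summarise([0.5, 1.5, 0.2, 0.9], targets=(t,), metric="m")
        assert s.assurance["in_unit"] == pytest.approx(0.75)


class TestAssuranceTarget:
    def test_needs_a_bound(self):
        with pytest.raises(ValueError, match="bound"):
            AssuranceTarget("t", "m")

    def test_ordered_bounds(self):
        with pytest.raises(ValueError, match="lower > upper"):
            AssuranceTarget("t", "m", 1.0, 0.5)


class TestCriterion:
    def test_exactly_one_kind(self):
        with pytest.raises(ValueError):
            Criterion("m")
        with pytest.raises(ValueError):
            Criterion("m", min_prob=0.5, max_mean=1.0)

    def test_check_mean_and_assurance(self):
        df = pd.DataFrame({"m": [0.1, 0.2, 0.3, 0.4]})
        assert Criterion("m", max_mean=0.3).check(df)
        assert not Criterion("m", max_mean=0.2).check(df)
        assert Criterion("m", upper=0.35, min_prob=0.7).check(df)
        assert not Criterion("m", upper=0.35, min_prob=0.9).check(df)


class TestSimulationRun:
    def test_replicate_frame_shape(self, small_run):
        assert len(small_run.replicates) == 6
        needed = {"replicate", "c", "cal_slope", "mape", "rvsi@0.5", "degradation_c"}
        assert needed <= set(small_run.replicates.columns)
        assert small_run.n_failed == 0

    def test_deterministic_given_seed(self, small_run):
        again = _sim().fit()
        pd.testing.assert_frame_equal(small_run.replicates, again.replicates)

    def test_strategy_swap_keeps_population_fixed(self, small_run):
        oracle = _sim(strategy="oracle").fit()
        np.testing.assert_array_equal(oracle.population.p, small_run.population.p)
        np.testing.assert_array_equal(oracle.population.y, small_run.population.y)

    def test_oracle_degradation_near_zero(self):
        res = _sim(strategy="oracle").fit()
        assert np.abs(res.replicates["degradation_c"]).max() < 1e-12
        assert np.abs(res.replicates["mape"]).max() < 1e-12

    def test_summary_text(self, small_run):
        text = small_run.summary()
        assert "cal_slope" in text and "assurance" in text
        assert "logistic" in text

    def test_prediction_matrix_tracks_subset(self, small_run):
        pm = small_run.prediction_matrix
        assert pm.values.shape == (200, 6)
        assert small_run.instability is not None
        assert "p_misclassification@0.5" in small_run.instability.columns

    def test_long_frame_layout(self, small_run):
        lf = small_run.to_long_frame()
        assert list(lf.columns) == ["replicate", "strategy", "n", "metric", "value", "subgroup"]
        assert (lf["n"] == 150).all()

    def test_all_failures_abort(self):
        bad = ps.Strategy("broken", lambda dev, rng=None, reference=None: 1 / 0, {})
        with pytest.raises(RuntimeError, match="replicates failed"):
            _sim(strategy=bad).fit()

    def test_failures_flagged_when_tolerated(self):
        bad = ps.Strategy("broken", lambda dev, rng=None, reference=None: 1 / 0, {})
        res = _sim(strategy=bad, max_failure_rate=2.0).fit()
        assert res.n_failed == 6
        assert res.replicates["flag_failed"].all()


class TestMixture:
    def _models(self):
        m1 = ps.ReferenceModel(alpha=-1.0, delta=0.5, beta=np.ones(4))
        m2 = ps.ReferenceModel(alpha=-0.5, delta=1.0, beta=np.ones(4))
        return m1, m2

    def test_mixture_of_one_equals_single_model(self):
        m1, _ = self._models()
        a = ps.SampleSizeSimulation(
            ps.CaseMixSpec.standard_normal(4), m1, "logistic", 150,
            n_sims=4, population_size=5_000, seed=9, instability_individuals=0,
        ).fit()
        b = ps.SampleSizeSimulation(
            ps.CaseMixSpec.standard_normal(4),
            ps.ReferenceMixture(models=(m1,), probs=(1.0,)),
            "logistic", 150,
            n_sims=4, population_size=5_000, seed=9, instability_individuals=0,
        ).fit()
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_two_component_mixture_varies_truth(self):
        m1, m2 = self._models()
        res = ps.SampleSizeSimulation(
            ps.CaseMixSpec.standard_normal(4),
            ps.ReferenceMixture(models=(m1, m2), probs=(0.5, 0.5)),
            "logistic", 150,
            n_sims=8, population_size=5_000, seed=10, instability_individuals=0,
        ).fit()
        # the nb_max column responds to the drawn truth, so it must vary
        assert res.replicates["nb_max@0.5"].nunique() > 1


class TestSweep:
    def test_min_n_found(self):
        cfg = ps.SimulationConfig(
            casemix=ps.CaseMixSpec.standard_normal(4),
            reference=ps.ReferenceModel(alpha=-0.8, delta=0.4, beta=np.ones(4)),
            strategy="logistic",
            n_grid=(60, 400),
            n_sims=12,
            population_size=5_000,
            seed=2,
            instability_individuals=0,
        )
        sweep = ps.sweep_sample_sizes(cfg, [Criterion("mape", max_mean=0.08)])
        assert sweep.n_min == 400
        assert list(sweep.table.index) == [60, 400]

    def test_none_met(self):
        cfg = ps.SimulationConfig(
            casemix=ps.CaseMixSpec.standard_normal(4),
            reference=ps.ReferenceModel(alpha=-0.8, delta=0.4, beta=np.ones(4)),
            strategy="logistic",
            n_grid=(60,),
            n_sims=6,
            population_size=5_000,
            seed=2,
            instability_individuals=0,
        )
        sweep = ps.sweep_sample_sizes(cfg, [Criterion("mape", max_mean=0.0001)])
        assert sweep.n_min is None
        assert not sweep.all_met

    def test_degradation_shrinks_with_n(self):
        """More development data gives less degradation on average."""
        ref = ps.ReferenceModel(alpha=-0.8, delta=0.4, beta=np.ones(4))
        out = {}
        for n in (60, 800):
            res = ps.SampleSizeSimulation(
                ps.CaseMixSpec.standard_normal(4), ref, "logistic", n,
                n_sims=25, population_size=10_000, seed=4,
                instability_individuals=0,
            ).fit()
            out[n] = res.replicates
        assert out[800]["mape"].mean() < out[60]["mape"].mean()
        assert (
            np.abs(out[800]["degradation_cal_slope"]).mean()
            < np.abs(out[60]["degradation_cal_slope"]).mean()
        )


class TestConfigAndReport:
    CONFIG = """
casemix:
  standard_normal: 4
reference:
  relative_beta: [1, 1, 1, 1]
  target_c: 0.72
  target_prev: 0.3
strategy:
  name: logistic
run:
  n: 150
  n_sims: 4
  population_size: 5000
  seed: 3
"""

    def test_parse_and_run(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(self.CONFIG)
        cfg = ps.parse_config(path)
        res = ps.run_simulation(cfg)
        assert len(res.replicates) == 4

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(self.CONFIG + "\nextra_block: {}\n")
        with pytest.raises(ValueError, match="extra_block"):
            ps.parse_config(path)
        path.write_text(self.CONFIG.replace("n_sims", "nsims"))
        with pytest.raises(ValueError, match="nsims"):
            ps.parse_config(path)

    def test_missing_block_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            ps.parse_config({"casemix": {"standard_normal": 2}, "reference": {}})

    def test_report_roundtrip(self, small_run, tmp_path):
        paths = ps.write_report(small_run, tmp_path / "out")
        for key in ("summary", "replicates", "assurance", "instability", "manifest"):
            assert paths[key].exists()
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["strategy"] == "logistic"
        long_df = pd.read_csv(paths["replicates"])
        regenerated = ps.engine.summarise_replicates(long_df)
        slope_row = regenerated[regenerated["metric"] == "cal_slope"].iloc[0]
        assert slope_row["mean"] == pytest.approx(
            small_run.replicates["cal_slope"].mean()
        )
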