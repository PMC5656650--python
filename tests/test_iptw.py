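import numpy as np
import pandas as pd
import pytest

from msmhazard import (
    DGPConfig,
    PropensitySpec,
    build_design,
    compute_stabilized_weights,
    fit_denominator_model,
    fit_numerator_model,
    generate_cohort,
    truncate_weights,
    weight_diagnostics,
)
from msmhazard.errors import (
    ConfigError,
    InfiniteWeightError,
    SchemaError,
    SeparationError,
)
from msmhazard.iptw import WeightSet

from conftest import make_panel


def weight_table(values):
    """WeightSet with given stabilized weights, one visit per patient."""
    tab = pd.DataFrame({
        "patient_id": np.arange(len(values)),
        "visit": 1,
        "ps_pred_denominator": 0.5,
        "ps_pred_numerator": 0.5,
        "stabilized_weight": np.asarray(values, dtype=float),
    })
    return WeightSet(table=tab)


class TestBuildDesign:
    def test_visit_one_uses_baseline_treatment_and_labs(self, tiny_panel):
        spec = PropensitySpec(time_dependent=["ua"], baseline=["age"])
        rows = build_design(tiny_panel, spec, visit=1)
        base = tiny_panel.baselines.set_index("patient_id")
        assert (rows.set_index("patient_id")["prev_treatment"]
                == base["baseline_treatment"]).all()
        assert (rows.set_index("patient_id")["prev_ua"]
                == base["baseline_ua"]).all()

    def test_later_visits_use_lagged_lab(self, tiny_panel):
        spec = PropensitySpec(time_dependent=["ua"], baseline=[])
        r2 = build_design(tiny_panel, spec, visit=2)
        d = tiny_panel.data
        lag = d[d.visit == 1].set_index("patient_id")["ua"]
        assert (r2.set_index("patient_id")["prev_ua"] == lag).all()

    def test_dead_patient_absent_from_later_designs(self):
        rows = [{"patient_id": 1, "visit": 1, "ua": 6.0, "event_death": 1},
                {"patient_id": 2, "visit": 1, "ua": 7.0},
                {"patient_id": 2, "visit": 2, "ua": 7.0}]
        panel = make_panel(rows)
        spec = PropensitySpec(time_dependent=["ua"], baseline=[])
        r2 = build_design(panel, spec, visit=2)
        assert r2["patient_id"].tolist() == [2]

    def test_missing_lab_named(self, tiny_panel):
        spec = PropensitySpec(time_dependent=["ferritin"], baseline=[])
        with pytest.raises(SchemaError, match="ferritin"):
            build_design(tiny_panel, spec, visit=1)


class TestPropensityModels:
    def test_random_assignment_recovers_half(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in range(1500):
            for v in (1, 2, 3):
                rows.append({"patient_id": pid, "visit": v,
                             "treatment": int(rng.uniform() < 0.5),
                             "ua": rng.normal(7.3, 1.3)})
        panel = make_panel(rows)
        spec = PropensitySpec(time_dependent=["ua"], baseline=[])
        fit, preds = fit_denominator_model(panel, spec)
        assert preds.mean() == pytest.approx(0.5, abs=0.02)
        # no real signal: coefficients within sampling noise of zero
        assert abs(fit.coefficients[1]) < 3.5 * fit.bse_model[1]
        assert preds.std() < 0.05

    def test_numerator_has_fewer_columns_than_denominator(self, recovery_cohort):
        panel, fix = recovery_cohort
        den, _ = fit_denominator_model(panel, fix.propensity)
        num, _ = fit_numerator_model(panel, fix.propensity)
        assert len(num.column_names) < len(den.column_names)
        assert (len(den.column_names) - len(num.column_names)
                == len(fix.propensity.time_dependent))

    def test_no_time_dependent_covariates_models_coincide(self, recovery_cohort):
        panel, _ = recovery_cohort
        spec = PropensitySpec(time_dependent=[], baseline=["age", "bmi"])
        den, dp = fit_denominator_model(panel, spec)
        num, np_ = fit_numerator_model(panel, spec)
        np.testing.assert_allclose(den.coefficients, num.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(dp, np_, atol=1e-12)

    def test_deterministic_prev_treatment_separates(self):
        rows = []
        for pid in range(30):
            a = pid % 2
            for v in (1, 2, 3):
                rows.append({"patient_id": pid, "visit": v, "treatment": a,
                             "baseline_treatment": a, "ua": 7.0})
        panel = make_panel(rows)
        spec = PropensitySpec(time_dependent=[], baseline=[])
        with pytest.raises(SeparationError):
            fit_denominator_model(panel, spec)


class TestStabilizedWeights:
    def _two_visit_panel(self):
        return make_panel([
            {"patient_id": 1, "visit": 1, "treatment": 1},
            {"patient_id": 1, "visit": 2, "treatment": 1},
        ])

    def test_forced_arithmetic_example(self):
        panel = self._two_visit_panel()
        ws = compute_stabilized_weights(
            panel, denom_preds=pd.Series([0.5, 0.25]),
            numer_preds=pd.Series([0.4, 0.2]))
        row = ws.table.iloc[-1]
        assert row["cumulative_denominator_inverse"] == pytest.approx(8.0)
        assert row["cumulative_numerator"] == pytest.approx(0.08)
        assert row["stabilized_weight"] == pytest.approx(0.64, abs=1e-12)

    def test_perfect_cancellation_gives_unit_weights(self, recovery_cohort):
        panel, _ = recovery_cohort
        preds = pd.Series(np.full(panel.n_rows, 0.37))
        ws = compute_stabilized_weights(panel, preds, preds.copy())
        np.testing.assert_allclose(ws.table["stabilized_weight"], 1.0,
                                   atol=1e-12)

    def test_exact_zero_prediction_rejected(self):
        panel = self._two_visit_panel()
        with pytest.raises(InfiniteWeightError):
            compute_stabilized_weights(panel, pd.Series([0.0, 0.5]),
                                       pd.Series([0.5, 0.5]))

    def test_untreated_rule_uses_complement(self):
        panel = make_panel([{"patient_id": 1, "visit": 1, "treatment": 0}])
        ws = compute_stabilized_weights(panel, pd.Series([0.8]),
                                        pd.Series([0.6]))
        # untreated: denominator factor 1/(1-0.8)=5, numerator 0.4
        assert ws.table["stabilized_weight"].iloc[0] == pytest.approx(2.0)

    def test_single_visit_reduces_to_point_treatment_weight(self):
        rng = np.random.default_rng(3)
        n = 40
        rows = [{"patient_id": i, "visit": 1,
                 "treatment": int(rng.uniform() < 0.4)} for i in range(n)]
        panel = make_panel(rows, T=1)
        pd_den = pd.Series(rng.uniform(0.2, 0.8, n))
        pd_num = pd.Series(np.full(n, 0.4))
        ws = compute_stabilized_weights(panel, pd_den, pd_num)
        a = panel.data["treatment"].to_numpy()
        expected = np.where(a == 1, 0.4 / pd_den, 0.6 / (1 - pd_den))
        np.testing.assert_allclose(ws.table["stabilized_weight"], expected,
                                   atol=1e-12)


class TestTruncation:
    def test_paper_style_bounds_clip_extremes(self):
        ws = weight_table([21.95, 0.0089, 1.0])
        tab = ws.table.copy()
        tab["truncated_weight"] = np.clip(tab["stabilized_weight"], 0.26, 3.62)
        assert tab["truncated_weight"].tolist() == [3.62, 0.26, 1.0]

    def test_percentile_bounds_are_mirrored(self):
        rng = np.random.default_rng(1)
        ws = weight_table(rng.lognormal(0, 0.5, 2000))
        out = truncate_weights(ws, 95)
        lo, hi = out.truncation_bounds
        sw = ws.table["stabilized_weight"]
        assert lo == np.percentile(sw, 5, method="lower")
        assert hi == np.percentile(sw, 95, method="higher")
        assert lo < 1.0 < hi
        assert out.table["truncated_weight"].min() == pytest.approx(lo)
        assert out.table["truncated_weight"].max() == pytest.approx(hi)

    def test_all_inside_bounds_identity(self):
        ws = weight_table(np.linspace(0.9, 1.1, 50))
        out = truncate_weights(ws, None)
        np.testing.assert_allclose(out.table["truncated_weight"],
                                   ws.table["stabilized_weight"])

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(2)
        ws = weight_table(rng.lognormal(0, 1.0, 500))
        once = truncate_weights(ws, 99)
        again = WeightSet(table=once.table.assign(
            stabilized_weight=once.table["truncated_weight"]))
        twice = truncate_weights(again, 99)
        np.testing.assert_allclose(twice.table["truncated_weight"],
                                   once.table["truncated_weight"], rtol=1e-12)
        # monotone: order of weights preserved
        sw = ws.table["stabilized_weight"].to_numpy()
        tw = once.table["truncated_weight"].to_numpy()
        idx = np.argsort(sw)
        assert (np.diff(tw[idx]) >= -1e-12).all()

    def test_invalid_percentile_rejected(self):
        ws = weight_table([1.0, 2.0])
        with pytest.raises(ConfigError):
            truncate_weights(ws, 90)


class TestDiagnostics:
    def test_single_weight(self):
        d = weight_diagnostics(weight_table([1.0]))
        assert d.mean == 1.0 and d.sd == 0.0
        assert d.percentile_95 == 1.0 and d.max == 1.0

    def test_simple_mean(self):
        d = weight_diagnostics(weight_table([1, 2, 3, 4]))
        assert d.mean == pytest.approx(2.5)
        assert d.min == 1.0 and d.max == 4.0
        assert d.min <= d.percentile_95 <= d.percentile_99 <= d.max

    def test_mean_stabilized_weight_near_one_small_cohort(self, recovery_cohort):
        panel, fix = recovery_cohort
        _, dp = fit_denominator_model(panel, fix.propensity)
        _, np_ = fit_numerator_model(panel, fix.propensity)
        ws = compute_stabilized_weights(panel, dp, np_)
        d = weight_diagnostics(ws)
        assert 0.85 < d.mean < 1.15
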