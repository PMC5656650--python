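import numpy as np
import pandas as pd
import pytest

from msmhazard import (
    MarginalStructuralModel,
    OutcomeModelSpec,
    PropensitySpec,
    compute_stabilized_weights,
    fit_msm,
    generate_cohort,
    load_fixture,
    run_quintile_analysis,
    sensitivity_truncation,
    truncate_weights,
)
from msmhazard.errors import ConfigError, ZeroEventsError

from conftest import make_panel


@pytest.fixture(scope="module")
def fitted_recovery():
    fix = load_fixture("recovery-A")
    panel = generate_cohort(fix.dgp.with_(n_patients=1200, seed=3))
    model = MarginalStructuralModel(panel, propensity=fix.propensity,
                                    outcome=fix.outcome)
    return model, model.fit()


class TestSpec:
    def test_unknown_outcome_rejected(self):
        with pytest.raises(ConfigError):
            OutcomeModelSpec(outcome="stroke")

    def test_bad_weight_source_rejected(self):
        with pytest.raises(ConfigError):
            OutcomeModelSpec(weight_source="winsorized")


class TestFitMSM:
    def test_weighted_estimate_and_ci_shape(self, fitted_recovery):
        _, res = fitted_recovery
        est = res.effect
        assert est.ci_lower < est.hr < est.ci_upper
        assert est.ci_lower == pytest.approx(
            np.exp(est.log_hr - 1.959963984540054 * est.robust_se))
        assert est.n_events > 0

    def test_weight_scaling_leaves_point_estimate(self, fitted_recovery):
        model, res = fitted_recovery
        ws = res.weights
        scaled = type(ws)(table=ws.table.assign(
            stabilized_weight=ws.table["stabilized_weight"] * 13.7))
        spec = OutcomeModelSpec(weight_source="stabilized")
        a = fit_msm(model.panel, ws, spec, quintiles=model.quintiles)
        b = fit_msm(model.panel, scaled, spec, quintiles=model.quintiles)
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-8)

    def test_unit_weights_match_naive(self, fitted_recovery):
        model, res = fitted_recovery
        ws = res.weights
        unit = type(ws)(table=ws.table.assign(
            stabilized_weight=np.ones(len(ws.table))))
        spec = OutcomeModelSpec(weight_source="stabilized")
        a = fit_msm(model.panel, unit, spec, quintiles=model.quintiles)
        assert a.log_hr == pytest.approx(res.naive.log_hr, abs=1e-10)

    def test_zero_events_error_mentions_reduced_model(self):
        rows = [{"patient_id": i, "visit": v} for i in range(8)
                for v in (1, 2)]
        panel = make_panel(rows)
        with pytest.raises(ZeroEventsError, match="polynomial"):
            fit_msm(panel, None, OutcomeModelSpec(weight_source="none"))

    def test_cvd_rows_stop_at_first_event(self):
        rows = [
            {"patient_id": 1, "visit": 1, "event_cvd": 0},
            {"patient_id": 1, "visit": 2, "event_cvd": 1},
            {"patient_id": 1, "visit": 3, "event_cvd": 0},
            {"patient_id": 2, "visit": 1, "event_cvd": 0},
        ]
        panel = make_panel(rows)
        from msmhazard.msm import _outcome_rows
        out = _outcome_rows(panel, "cvd")
        assert len(out) == 3  # visit 3 of patient 1 is past the first event


class TestPointTreatmentEquivalence:
    def test_t1_reduces_to_stabilized_ps_weighting(self):
        """With one visit the MSM is a point-treatment stabilized-PS fit.

        Independent route: statsmodels GLM fits for the propensity and the
        weighted outcome model, with the classic P(A)/ps formula for the
        weights.  Agreement is required to 1e-8 on the log-HR.
        """
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        n = 3000
        ua = rng.normal(7.3, 1.3, n)
        p_treat = 1 / (1 + np.exp(-(-1.0 - 0.6 * (ua - 7.3) / 1.3)))
        a = (rng.uniform(size=n) < p_treat).astype(int)
        p_death = 1 / (1 + np.exp(-(-2.0 - 0.7 * a + 0.3 * (ua - 7.3) / 1.3)))
        y = (rng.uniform(size=n) < p_death).astype(int)
        prev_treat = (rng.uniform(size=n) < 0.2).astype(int)
        rows = [{"patient_id": i, "visit": 1, "treatment": int(a[i]),
                 "event_death": int(y[i]), "ua": ua[i], "baseline_ua": ua[i],
                 "baseline_treatment": int(prev_treat[i])}
                for i in range(n)]
        panel = make_panel(rows, T=1)

        spec = PropensitySpec(time_dependent=["ua"], baseline=[])
        model = MarginalStructuralModel(
            panel, propensity=spec,
            outcome=OutcomeModelSpec(time_terms="linear"))
        ours = model.fit().effect.log_hr

        # independent implementation (note prev_treatment at visit 1 is the
        # baseline treatment indicator, included in both models)
        prev = panel.data["baseline_treatment"].to_numpy(dtype=float)
        Xd = np.column_stack([np.ones(n), prev, ua])
        ps = sm.GLM(a, Xd, family=sm.families.Binomial()).fit(tol=1e-12).predict(Xd)
        Xn = np.column_stack([np.ones(n), prev])
        pa = sm.GLM(a, Xn, family=sm.families.Binomial()).fit(tol=1e-12).predict(Xn)
        w = np.where(a == 1, pa / ps, (1 - pa) / (1 - ps))
        Xo = np.column_stack([np.ones(n), np.ones(n), a])  # month/T == 1
        Xo = Xo[:, [0, 2]]  # month column is constant at T=1 -> drop
        ref = sm.GLM(y, Xo, family=sm.families.Binomial(),
                     freq_weights=w).fit(tol=1e-13, maxiter=300)
        assert ours == pytest.approx(ref.params[-1], abs=1e-8)


class TestQuintilesAndSensitivity:
    def test_quintile_batch_collects_errors(self, fitted_recovery):
        model, res = fitted_recovery
        out = run_quintile_analysis(model.panel, res.weights,
                                    res.effect.spec,
                                    quintiles=model.quintiles)
        assert len(out) == 5
        ok = [e for e in out if not isinstance(e, Exception)]
        assert len(ok) >= 3  # small cohort: some quintiles may be sparse
        for est in ok:
            assert est.spec.time_terms == "cubic"

    def test_zero_event_quintile_marked_not_fatal(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            ua = rng.normal(7.3, 1.3)
            # deaths only among high-UA patients
            dead = ua > 8.0 and rng.uniform() < 0.5
            rows.append({"patient_id": i, "visit": 1, "baseline_ua": ua,
                         "ua": ua, "treatment": int(rng.uniform() < 0.3),
                         "event_death": int(dead)})
        panel = make_panel(rows, T=1)
        out = run_quintile_analysis(panel, None,
                                    OutcomeModelSpec(weight_source="none"))
        assert any(isinstance(e, ZeroEventsError) for e in out)
        assert any(not isinstance(e, Exception) for e in out)

    def test_truncation_sensitivity_three_rows(self, fitted_recovery):
        model, res = fitted_recovery
        table = sensitivity_truncation(model.panel, res.weights,
                                       res.effect.spec)
        assert set(table) == {"none", "95", "99"}
        hrs = [table[k].hr for k in ("none", "95", "99")]
        assert all(h > 0 for h in hrs)

    def test_weights_inside_bounds_identity_fit(self, fitted_recovery):
        model, res = fitted_recovery
        ws = res.weights
        # clip stabilized weights into a narrow band: 99% truncation of the
        # clipped set then changes (almost) nothing
        clipped = type(ws)(table=ws.table.assign(
            stabilized_weight=ws.table["stabilized_weight"].clip(0.8, 1.2)))
        t99 = truncate_weights(clipped, 99)
        spec = OutcomeModelSpec(weight_source="stabilized")
        a = fit_msm(model.panel, clipped, spec, quintiles=model.quintiles)
        b = fit_msm(model.panel, t99,
                    OutcomeModelSpec(weight_source="truncated-99"),
                    quintiles=model.quintiles)
        assert a.log_hr == pytest.approx(b.log_hr, abs=0.02)


class TestResultsObject:
    def test_summary_mentions_both_estimates(self, fitted_recovery):
        _, res = fitted_recovery
        text = res.summary()
        assert "IPTW-weighted HR" in text
        assert "naive (unweighted) HR" in text
        assert "stabilized weights" in text

    def test_diagnostics_orderings(self, fitted_recovery):
        _, res = fitted_recovery
        d = res.diagnostics
        assert d.min <= d.percentile_95 <= d.percentile_99 <= d.max
        assert d.n_person_visits == len(res.weights.table)
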