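import math

import numpy as np
import pytest

from seqsurv import (CenteringContext, Perturbation, breslow_baseline,
                     estimate_local_hr, five_year_risk, fit_cox,
                     linear_preset, reference_person)
from seqsurv.inference import InferenceError
from seqsurv.records import covariate_names, make_covariate_vector
from seqsurv.simulate import generate_cohort

from _oracles import breslow_cumhaz_bruteforce


class TestBreslowBaseline:
    def test_single_event_uniform_risk_set(self):
        n = 8
        f = np.zeros(n)
        times = np.arange(1.0, n + 1)
        events = np.zeros(n, dtype=bool)
        events[0] = True  # earliest time -> full risk set
        base = breslow_baseline(f, times, events)
        assert base.cum_hazard[0] == pytest.approx(1.0 / n, abs=1e-15)

    def test_four_person_hand_computed_sum(self):
        # times 2+, 3, 5+, 7 (+ = event); f - f_ref = 0, log2, 0, log2
        f = np.array([0.0, math.log(2), 0.0, math.log(2)])
        times = np.array([2.0, 3.0, 5.0, 7.0])
        events = np.array([True, False, True, False])
        base = breslow_baseline(f, times, events)
        # at t=2 risk set {2,3,5,7}: denom = 1+2+1+2 = 6
        # at t=5 risk set {5,7}:     denom = 1+2 = 3
        assert base.cum_hazard.tolist() == pytest.approx(
            [1.0 / 6.0, 1.0 / 6.0 + 1.0 / 3.0], abs=1e-15)
        oracle = breslow_cumhaz_bruteforce(f, times, events, 5.0)
        assert base.cum_hazard[-1] == pytest.approx(oracle, abs=1e-15)

    def test_step_function_flat_beyond_last_event(self):
        f = np.zeros(4)
        times = np.array([2.0, 4.0, 6.0, 8.0])
        events = np.array([True, True, False, False])
        base = breslow_baseline(f, times, events)
        assert base.survival(4.0) == base.survival(1826.0)
        assert base.survival(0.0) == 1.0

    def test_survival_monotone_nonincreasing(self, survival_arrays):
        cohort, times, events = survival_arrays
        f = np.random.default_rng(1).normal(size=len(times))
        base = breslow_baseline(f, times, events)
        s = base.survival(np.arange(0.0, 1827.0, 30.0))
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s > 0) & (s <= 1))

    def test_no_events_error(self):
        with pytest.raises(InferenceError, match="no events"):
            breslow_baseline(np.zeros(3), np.arange(1.0, 4.0),
                             np.zeros(3, dtype=bool))


class TestFiveYearRisk:
    def test_reference_person_risk(self):
        f = np.zeros(5)
        times = np.array([100.0, 400.0, 900.0, 1400.0, 1826.0])
        events = np.array([True, True, False, True, False])
        base = breslow_baseline(f, times, events)
        s5 = float(base.survival(1826.0))
        assert five_year_risk(np.array([0.0]), base)[0] \
            == pytest.approx(1.0 - s5, abs=1e-15)

    def test_power_rule(self):
        # S_ref(5y) = 0.99 and a doubled hazard give 1 - 0.99^2
        base = breslow_baseline(np.zeros(2), np.array([5.0, 1826.0]),
                                np.array([True, False]))
        s5 = float(base.survival(1826.0))
        r = five_year_risk(np.array([math.log(2.0)]), base)[0]
        assert r == pytest.approx(1.0 - s5 ** 2, abs=1e-12)

    def test_strictly_increasing_in_f(self, survival_arrays):
        _, times, events = survival_arrays
        base = breslow_baseline(np.zeros(len(times)), times, events)
        f = np.linspace(-2, 2, 9)
        risks = five_year_risk(f, base)
        assert np.all(np.diff(risks) > 0)
        assert np.all((risks >= 0) & (risks <= 1))


class TestLocalHR:
    def _linear_predictor(self, beta, centering):
        def predict(persons):
            return np.array([
                make_covariate_vector(p, centering) @ beta
                for p in persons])
        return predict

    def test_identity_perturbation_is_exactly_one(self, centering):
        beta = np.zeros(len(covariate_names()))
        pred = self._linear_predictor(beta, centering)
        [rec] = estimate_local_hr([pred, pred],
                                  [Perturbation("none", "identity")],
                                  centering)
        assert rec.hr == 1.0 and (rec.ci_low, rec.ci_high) == (1.0, 1.0)

    def test_constant_replicates_collapse_ci(self, centering):
        names = covariate_names()
        beta = np.zeros(len(names))
        beta[names.index("diabetes")] = math.log(2.0)
        pred = self._linear_predictor(beta, centering)
        [rec] = estimate_local_hr(
            [pred, pred, pred],
            [Perturbation("diabetes", "binary", field="diabetes")],
            centering)
        assert rec.hr == pytest.approx(2.0, abs=1e-12)
        assert rec.ci_low == pytest.approx(2.0, abs=1e-12)
        assert rec.ci_high == pytest.approx(2.0, abs=1e-12)

    def test_cox_binary_perturbation_recovers_exp_beta(self):
        cohort, _ = generate_cohort(linear_preset(3000, seed=31,
                                                  p_female=1.0))
        model = fit_cox(cohort)
        pred = model.linear_predictor
        [rec] = estimate_local_hr(
            [pred, pred],
            [Perturbation("diabetes", "binary", field="diabetes")],
            model.centering)
        j = model.names.index("diabetes")
        assert rec.hr == pytest.approx(float(np.exp(model.beta[j])),
                                       abs=1e-12)

    def test_shift_invariance_within_replicate(self, centering):
        names = covariate_names()
        beta = np.zeros(len(names))
        beta[names.index("bp_lowering")] = 0.4
        base_pred = self._linear_predictor(beta, centering)

        def shifted(persons):
            return base_pred(persons) + 57.0
        pert = [Perturbation("bp", "binary", field="bp_lowering")]
        [a] = estimate_local_hr([base_pred, base_pred], pert, centering)
        [b] = estimate_local_hr([shifted, shifted], pert, centering)
        assert a.hr == pytest.approx(b.hr, rel=1e-12)

    def test_continuous_perturbation_per_unit(self, centering):
        names = covariate_names()
        beta = np.zeros(len(names))
        beta[names.index("age")] = 0.08
        pred = self._linear_predictor(beta, centering)
        pert = Perturbation("age", "continuous", field="age",
                            grid=(40.0, 50.0, 60.0))
        [rec] = estimate_local_hr([pred, pred], [pert], centering)
        assert rec.hr == pytest.approx(math.exp(0.08), abs=1e-12)

    def test_single_replicate_rejected(self, centering):
        with pytest.raises(InferenceError, match="K >= 2"):
            estimate_local_hr([lambda persons: np.zeros(len(persons))],
                              [Perturbation("none", "identity")],
                              centering)

    def test_unknown_code_rejected_when_vocab_known(self, centering):
        from seqsurv import build_vocabulary
        from seqsurv.records import CodeEvent
        from conftest import make_person
        vocab = build_vocabulary(
            [make_person(events=[CodeEvent("A", "primary_dx", 0)])],
            min_persons=1)
        pred = lambda persons: np.zeros(len(persons))  # noqa: E731
        with pytest.raises(InferenceError, match="not in the model"):
            estimate_local_hr([pred, pred],
                              [Perturbation("code_Z", "code", code="Z",
                                            code_type="primary_dx")],
                              centering, vocab=vocab)

    def test_reference_person_definition(self, centering):
        ref = reference_person(centering)
        v = make_covariate_vector(ref, centering)
        assert np.all(v == 0.0) and ref.events == []
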