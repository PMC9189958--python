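import math

import numpy as np
import pytest

from seqsurv import (CohortError, SimulationConfig, generate_cohort,
                     generate_histories, harrells_c, kaplan_meier,
                     linear_preset, nonlinear_preset, simulate_outcomes,
                     true_linear_predictor)
from seqsurv.records import CodeEvent
from seqsurv.simulate import TRUE_MEAN_AGE

from conftest import make_person


class TestConfigValidation:
    def test_rejects_nonpositive_sizes_and_hazards(self):
        with pytest.raises(CohortError):
            SimulationConfig(n_persons=0)
        with pytest.raises(CohortError):
            SimulationConfig(zipf_exponent=0.0)
        with pytest.raises(CohortError):
            SimulationConfig(baseline_hazard=-1e-5)

    def test_rejects_unknown_effect_names(self):
        with pytest.raises(CohortError, match="unknown covariate"):
            SimulationConfig(covariate_effects={"smoking": 1.0})


class TestHistories:
    def test_zero_intensity_gives_empty_sequences(self):
        cohort, _ = generate_histories(
            SimulationConfig(n_persons=50, seed=1,
                             events_per_person_month=0.0,
                             replicate_prob=0.0))
        assert all(len(p.events) == 0 for p in cohort)

    def test_same_seed_identical_cohorts(self):
        a, ta = generate_histories(SimulationConfig(n_persons=40, seed=9))
        b, tb = generate_histories(SimulationConfig(n_persons=40, seed=9))
        assert a == b
        assert np.array_equal(ta.eta, tb.eta)

    def test_prefix_stable_under_larger_n(self):
        a, _ = generate_histories(SimulationConfig(n_persons=30, seed=5))
        b, _ = generate_histories(SimulationConfig(n_persons=60, seed=5))
        assert b[:30] == a

    def test_mean_event_count_matches_poisson_intensity(self):
        config = SimulationConfig(n_persons=10_000, seed=3,
                                  replicate_prob=0.0)
        cohort, _ = generate_histories(config)
        counts = np.array([len(p.events) for p in cohort])
        expected = config.events_per_person_month * 60
        se = math.sqrt(expected / len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_condition_linked_codes_boosted_by_flag(self):
        config = SimulationConfig(n_persons=4000, seed=6)
        cohort, _ = generate_histories(config)
        has = {True: 0, False: 0}
        tot = {True: 0, False: 0}
        for p in cohort:
            tot[p.diabetes] += 1
            if any(e.code == "D017" for e in p.events):
                has[p.diabetes] += 1
        rate_diab = has[True] / max(tot[True], 1)
        rate_rest = has[False] / max(tot[False], 1)
        assert rate_diab > 2 * rate_rest


class TestTruth:
    def test_eta_reproducible_from_config(self, small_sim):
        cohort, truth = small_sim
        assert np.array_equal(truth.recompute(cohort), truth.eta)

    def test_planted_code_doubles_hazard(self):
        config = SimulationConfig(n_persons=1, seed=0,
                                  code_effects={"D004": math.log(2.0)},
                                  recency_timescale=0.0)
        bare = make_person(age=TRUE_MEAN_AGE)
        coded = make_person(events=[CodeEvent("D004", "primary_dx", 12)],
                            age=TRUE_MEAN_AGE)
        ratio = math.exp(true_linear_predictor(coded, config)
                         - true_linear_predictor(bare, config))
        assert ratio == pytest.approx(2.0, abs=1e-12)

    def test_recency_weight_decays_with_age_of_listing(self):
        config = SimulationConfig(n_persons=1, seed=0,
                                  code_effects={"D004": math.log(2.0)},
                                  recency_timescale=12.0)
        recent = make_person(events=[CodeEvent("D004", "primary_dx", 59)],
                             age=TRUE_MEAN_AGE)
        old = make_person(events=[CodeEvent("D004", "primary_dx", 0)],
                          age=TRUE_MEAN_AGE)
        e_recent = true_linear_predictor(recent, config)
        e_old = true_linear_predictor(old, config)
        assert e_recent == pytest.approx(math.log(2.0), abs=1e-12)
        assert 0 < e_old < 0.01


class TestOutcomes:
    def _null_config(self, n, seed, lam=3.5e-5, mu=0.0, nu=0.0):
        return SimulationConfig(
            n_persons=n, seed=seed, covariate_effects={}, code_effects={},
            events_per_person_month=0.0, replicate_prob=0.0,
            baseline_hazard=lam, noncvd_death_hazard=mu,
            emigration_hazard=nu)

    def test_no_hazards_all_administratively_censored(self):
        cohort, truth = generate_histories(self._null_config(100, 2,
                                                             lam=1e-12))
        done = simulate_outcomes(cohort, truth)
        assert all(p.follow_up_days == 1826 and not p.cvd_event
                   for p in done)

    def test_event_fraction_matches_closed_form(self):
        # competing exponentials: P(event) =
        # lam/(lam+mu+nu) * (1 - exp(-(lam+mu+nu) * horizon))
        lam, mu, nu = 6e-5, 7e-6, 4e-5
        cohort, truth = generate_histories(
            self._null_config(50_000, 4, lam=lam, mu=mu, nu=nu))
        done = simulate_outcomes(cohort, truth)
        frac = np.mean([p.cvd_event for p in done])
        tot = lam + mu + nu
        expected = lam / tot * (1.0 - math.exp(-tot * 1826))
        se = math.sqrt(expected * (1 - expected) / len(done))
        assert abs(frac - expected) < 3 * se

    def test_null_truth_concordance_is_half(self):
        cohort, truth = generate_histories(self._null_config(20_000, 5))
        done = simulate_outcomes(cohort, truth)
        rng = np.random.default_rng(0)
        f = rng.normal(size=len(done))  # any independent score
        t = [p.follow_up_days for p in done]
        e = [p.cvd_event for p in done]
        assert abs(harrells_c(f, t, e) - 0.5) < 0.02

    def test_km_matches_exponential_survival(self):
        lam = 8e-5
        cohort, truth = generate_histories(self._null_config(20_000, 6,
                                                             lam=lam))
        done = simulate_outcomes(cohort, truth)
        t = np.array([p.follow_up_days for p in done], dtype=float)
        e = np.array([p.cvd_event for p in done], dtype=bool)
        km = kaplan_meier(t, e)
        for day in (200, 600, 1000, 1500):
            expected = math.exp(-lam * day)
            se = math.sqrt(expected * (1 - expected) / len(done))
            assert abs(float(km(day)) - expected) < 4 * se

    def test_event_fraction_monotone_in_baseline_hazard(self):
        fracs = []
        for lam in (2e-5, 6e-5, 2e-4):
            cohort, truth = generate_histories(
                self._null_config(5000, 8, lam=lam))
            done = simulate_outcomes(cohort, truth)
            fracs.append(np.mean([p.cvd_event for p in done]))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_follow_up_day_rounding_floor_one(self, small_sim):
        cohort, _ = small_sim
        assert all(1 <= p.follow_up_days <= 1826 for p in cohort)


class TestPresets:
    def test_linear_preset_has_no_code_effects(self):
        cfg = linear_preset(10, seed=1)
        assert cfg.code_effects == {} and cfg.recency_timescale == 0.0

    def test_nonlinear_preset_recency_and_effects(self):
        cfg = nonlinear_preset(10, seed=1)
        assert cfg.recency_timescale == 12.0
        assert cfg.code_effects["D004"] == pytest.approx(math.log(4.0))
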