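import numpy as np
import pytest

from seqsurv import (brier_scores, censoring_km, decile_tables,
                     default_brier_grid, harrells_c, integrated_brier,
                     kaplan_meier, royston_d_r2)
from seqsurv.metrics import KAPPA, MetricError, StepFunction, d_to_r2

from _oracles import concordance_bruteforce


class TestHarrellsC:
    def test_perfect_discrimination(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=bool)
        f = -times  # earlier event, higher score
        assert harrells_c(f, times, events) == 1.0

    def test_constant_predictions_give_half(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 100, 50).astype(float)
        events = rng.random(50) < 0.5
        events[0] = True
        assert harrells_c(np.zeros(50), times, events) == 0.5

    def test_matches_bruteforce_on_random_censored_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            times = rng.integers(1, 20, n).astype(float)  # force ties
            events = rng.random(n) < 0.6
            if not events.any():
                events[0] = True
            f = np.round(rng.normal(size=n), 1)  # force score ties
            assert harrells_c(f, times, events) == pytest.approx(
                concordance_bruteforce(f, times, events), abs=1e-12)

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index
        rng = np.random.default_rng(5)
        n = 300
        times = rng.integers(1, 400, n).astype(float)
        events = rng.random(n) < 0.5
        events[:2] = True
        f = rng.normal(size=n)
        ours = harrells_c(f, times, events)
        theirs = concordance_index(times, -f, events)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(MetricError, match="comparable"):
            harrells_c([1.0, 2.0], [5.0, 5.0], [True, True])


class TestRoystonD:
    def test_constant_predictor_degenerate(self):
        times = np.arange(1.0, 31.0)
        events = np.ones(30, dtype=bool)
        res = royston_d_r2(np.ones(30), times, events)
        assert res.d == 0.0 and res.r2 == 0.0 and res.degenerate

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        n = 300
        f = rng.normal(size=n)
        times = rng.exponential(scale=np.exp(-f))
        events = rng.random(n) < 0.8
        events[0] = True
        a = royston_d_r2(f, times, events)
        b = royston_d_r2(np.exp(f), times, events)
        assert a.d == pytest.approx(b.d, abs=1e-10)

    def test_r2_consistency_identity(self):
        rng = np.random.default_rng(3)
        n = 500
        f = rng.normal(size=n)
        times = rng.exponential(scale=np.exp(-f))
        res = royston_d_r2(f, times, np.ones(n, dtype=bool))
        x = res.d ** 2 / KAPPA ** 2
        assert res.r2 == pytest.approx(x / (np.pi ** 2 / 6 + x),
                                       abs=1e-12)
        assert res.r2 == pytest.approx(d_to_r2(res.d), abs=1e-15)

    def test_sign_follows_direction(self):
        rng = np.random.default_rng(4)
        n = 400
        f = rng.normal(size=n)
        times = rng.exponential(scale=np.exp(-1.5 * f))
        events = np.ones(n, dtype=bool)
        assert royston_d_r2(f, times, events).d > 0
        assert royston_d_r2(-f, times, events).d < 0


class TestKaplanMeier:
    def test_simple_no_censoring(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [True, True, True])
        assert float(km(1.5)) == pytest.approx(2.0 / 3.0)
        assert float(km(3.0)) == pytest.approx(0.0)

    def test_left_limit_convention(self):
        G = censoring_km([2.0, 4.0], [True, False])
        # censoring jump at t=4 only
        assert float(G(4.0)) == pytest.approx(0.0)
        assert float(G.left_limit(4.0)) == pytest.approx(1.0)


class TestBrier:
    def test_perfect_forecaster_zero(self):
        times = np.array([5.0, 10.0, 15.0, 20.0])
        events = np.array([True, True, False, False])
        grid = np.array([7.0, 12.0])
        S = np.array([[0.0, 0.0],    # event at 5
                      [1.0, 0.0],    # event at 10
                      [1.0, 1.0],
                      [1.0, 1.0]])
        bs = brier_scores(S, times, events, grid)
        assert np.allclose(bs, 0.0, atol=1e-15)
        assert integrated_brier(S, times, events, grid) == 0.0

    def test_coin_flip_quarter_without_censoring(self):
        times = np.array([5.0, 10.0, 15.0, 20.0])
        events = np.array([True, True, True, True])
        grid = np.array([7.0, 12.0])
        S = np.full((4, 2), 0.5)
        bs = brier_scores(S, times, events, grid)
        assert np.allclose(bs, 0.25, atol=1e-15)

    def test_hand_expanded_ipcw_sum_on_censored_toy_set(self):
        # times 2+, 4, 5+, 7, 9 (+ = event); censoring KM G jumps at 4
        # (factor 3/4), 7 (factor 1/2) and 9
        times = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
        events = np.array([True, False, True, False, False])
        grid = np.array([3.0, 6.0])
        S = np.array([[0.9, 0.8],
                      [0.8, 0.7],
                      [0.7, 0.5],
                      [0.6, 0.4],
                      [0.5, 0.3]])
        bs = brier_scores(S, times, events, grid)
        # BS(3): event person 1: 0.9^2 / G(2-) = 0.81;
        #        at risk 2..5: (1-S)^2 / G(3)=1
        bs3 = (0.81 + 0.2 ** 2 + 0.3 ** 2 + 0.4 ** 2 + 0.5 ** 2) / 5
        # BS(6): events: 0.8^2/1 + 0.5^2/(3/4); at risk (7, 9):
        #        0.6^2/(3/4) + 0.7^2/(3/4); censored-at-4 contributes 0
        bs6 = (0.64 + 0.25 / 0.75 + 0.36 / 0.75 + 0.49 / 0.75) / 5
        assert bs[0] == pytest.approx(bs3, abs=1e-12)
        assert bs[1] == pytest.approx(bs6, abs=1e-12)
        ibs = integrated_brier(S, times, events, grid)
        assert ibs == pytest.approx((bs3 + bs6) / 2.0, abs=1e-12)

    def test_agrees_with_scikit_survival(self):
        from sksurv.metrics import brier_score
        from sksurv.util import Surv
        rng = np.random.default_rng(8)
        n = 200
        # unique times: tie conventions between event and censoring at
        # the same time differ across implementations
        times = rng.permutation(np.arange(1.0, n + 1.0))
        events = rng.random(n) < 0.6
        grid = np.array([50.0, 120.0, 180.0])
        f = rng.normal(size=n)
        S = np.exp(-np.exp(f)[:, None] * grid[None, :] / 300.0)
        y = Surv.from_arrays(events, times)
        _, theirs = brier_score(y, y, S, grid)
        ours = brier_scores(S, times, events, grid)
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_zero_censoring_weight_raises_with_time(self):
        times = np.array([7.0, 6.0])
        events = np.array([True, True])
        G = StepFunction(times=np.array([5.0]), values=np.array([0.0]))
        S = np.full((2, 1), 0.5)
        with pytest.raises(MetricError, match="zero at"):
            brier_scores(S, times, events, np.array([8.0]), censoring=G)

    def test_km_forecaster_beats_coin_flip_when_events_rare(
            self, survival_arrays):
        _, times, events = survival_arrays
        grid = default_brier_grid(times, events)
        km = kaplan_meier(times, events)
        S_km = np.tile(km(grid), (len(times), 1))
        S_half = np.full_like(S_km, 0.5)
        assert events.mean() < 0.5
        assert integrated_brier(S_km, times, events, grid) \
            <= integrated_brier(S_half, times, events, grid)

    def test_default_grid_thinning(self, survival_arrays):
        _, times, events = survival_arrays
        grid = default_brier_grid(times, events, max_points=50)
        assert len(grid) <= 50
        assert np.all(np.diff(grid) > 0)


class TestDecileTables:
    def test_event_shares_sum_to_one(self, survival_arrays):
        _, times, events = survival_arrays
        rng = np.random.default_rng(1)
        table = decile_tables(rng.random(len(times)), times, events)
        assert table.event_share.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.ptp(table.sizes) <= 1

    def test_degenerate_separation(self):
        n = 100
        risks = np.linspace(0, 1, n)
        times = np.full(n, 1000.0)
        events = np.zeros(n, dtype=bool)
        events[-10:] = True  # top decile by construction
        times[-10:] = 500.0
        table = decile_tables(risks, times, events, observed="raw")
        assert table.event_share[-1] == 1.0
        assert np.all(table.event_share[:-1] == 0.0)
        assert table.observed_proportion[-1] == 1.0

    def test_km_equals_raw_without_censoring(self):
        rng = np.random.default_rng(2)
        n = 500
        risks = rng.random(n)
        events = rng.random(n) < risks
        times = np.where(events, rng.integers(1, 1826, n), 1826)
        km_table = decile_tables(risks, times.astype(float), events,
                                 observed="km")
        raw_table = decile_tables(risks, times.astype(float), events,
                                  observed="raw")
        assert np.allclose(km_table.observed_proportion,
                           raw_table.observed_proportion, atol=1e-12)
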