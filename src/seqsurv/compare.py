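"""Cross-validated model comparison and subgroup evaluation.

Two models are compared by stratified 5x2 cross-validation: five
replications, each splitting the stratum into two event-proportion-
stratified halves; each half serves once as training and once as test
data. Both models are fitted on the same training half and evaluated on
the same test half, with all data contracts (vocabulary, covariate
centering, the censoring-distribution estimate behind the Brier weights,
the Breslow baseline) computed from the training half only.

Per-fold metric differences feed the combined 5x2 F test
(df 10, 5): F = (sum of all d_rj^2) / (2 sum_r s_r^2), where s_r^2 is the
within-replication variance of the two fold differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cox import CoxModel, fit_cox
from .inference import breslow_baseline, five_year_risk
from .metrics import (DecileTable, MetricError, censoring_km,
                      decile_tables, default_brier_grid, harrells_c,
                      integrated_brier, royston_d_r2)
from .network import ModelConfig
from .records import (CenteringContext, PersonRecord, build_vocabulary)
from .training import TrainedEnsemble, train_ensemble

logger = logging.getLogger(__name__)

METRIC_NAMES = ("c", "d", "r2", "ibs")


class ComparisonError(ValueError):
    pass


# -- learners ------------------------------------------------------------
@dataclass
class FittedModel:
    """A fitted model plus the training-half anchoring it needs."""

    scores_fn: object               # persons -> log relative risks f
    baseline: object                # BaselineSurvival from the train half
    censoring: object               # censoring KM from the train half
    grid: np.ndarray
    underlying: object = None

    def scores(self, persons: list[PersonRecord]) -> np.ndarray:
        return np.asarray(self.scores_fn(persons), dtype=float)

    def survival_matrix(self, persons: list[PersonRecord]) -> np.ndarray:
        f = self.scores(persons)
        s_ref = self.baseline.survival(self.grid)    # (m,)
        return s_ref[None, :] ** np.exp(f)[:, None]

    def risks(self, persons: list[PersonRecord],
              horizon: float = 1826.0) -> np.ndarray:
        return five_year_risk(self.scores(persons), self.baseline)


def _anchor(scores_fn, train: list[PersonRecord],
            underlying=None) -> FittedModel:
    times = np.array([p.follow_up_days for p in train], dtype=float)
    events = np.array([p.cvd_event for p in train], dtype=bool)
    f_train = np.asarray(scores_fn(train), dtype=float)
    baseline = breslow_baseline(f_train, times, events, f_ref=0.0)
    return FittedModel(scores_fn=scores_fn, baseline=baseline,
                       censoring=censoring_km(times, events),
                       grid=default_brier_grid(times, events),
                       underlying=underlying)


@dataclass
class CoxLearner:
    """Comparator: sex-stratum Cox model on the pre-specified predictors."""

    predictor_set: str = "full"
    ties: str = "efron"

    def fit(self, train: list[PersonRecord], seed: int = 0) -> FittedModel:
        model = fit_cox(train, predictor_set=self.predictor_set,
                        ties=self.ties)
        return _anchor(model.linear_predictor, train, underlying=model)


@dataclass
class DeepLearner:
    """The recurrent relative-risk ensemble, trained per fold."""

    config: ModelConfig
    min_persons: int = 10

    def fit(self, train: list[PersonRecord], seed: int = 0) -> FittedModel:
        vocab = build_vocabulary(train, min_persons=self.min_persons)
        centering = CenteringContext.fit(train)
        cfg = ModelConfig(**{**self.config.__dict__,
                             "seed": self.config.seed + seed})
        ensemble = train_ensemble(train, cfg, vocab, centering)
        return _anchor(ensemble.predict_log_risk, train,
                       underlying=ensemble)


# -- metric evaluation ----------------------------------------------------
def evaluate_fold(fitted: FittedModel, test: list[PersonRecord],
                  metrics: tuple[str, ...] = METRIC_NAMES
                  ) -> dict[str, float]:
    """All requested metrics of one fitted model on one test half."""
    times = np.array([p.follow_up_days for p in test], dtype=float)
    events = np.array([p.cvd_event for p in test], dtype=bool)
    f = fitted.scores(test)
    out: dict[str, float] = {}
    if "c" in metrics:
        out["c"] = harrells_c(f, times, events)
    if "d" in metrics or "r2" in metrics:
        rd = royston_d_r2(f, times, events)
        out["d"], out["r2"] = rd.d, rd.r2
    if "ibs" in metrics:
        S = fitted.survival_matrix(test)
        out["ibs"] = integrated_brier(S, times, events, fitted.grid,
                                      censoring=fitted.censoring)
    return out


def stratified_halves(events: np.ndarray, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into two halves with matched event proportions."""
    events = np.asarray(events, dtype=bool)
    cases = rng.permutation(np.flatnonzero(events))
    controls = rng.permutation(np.flatnonzero(~events))
    half_a = np.concatenate([cases[::2], controls[::2]])
    half_b = np.concatenate([cases[1::2], controls[1::2]])
    return np.sort(half_a), np.sort(half_b)


@dataclass
class CVResult:
    """Per-(replication, fold) metrics for two models and their F tests."""

    metrics_a: dict[str, np.ndarray]   # metric -> (5, 2)
    metrics_b: dict[str, np.ndarray]
    n_replications: int
    label_a: str = "A"
    label_b: str = "B"

    def differences(self, metric: str) -> np.ndarray:
        return self.metrics_a[metric] - self.metrics_b[metric]

    def f_test(self, metric: str) -> tuple[float, float]:
        return combined_f_test(self.differences(metric))

    def summary(self, metric: str, which: str = "a"
                ) -> tuple[float, float, float]:
        """Cross-validated mean with a t-based 95% interval."""
        vals = (self.metrics_a if which == "a"
                else self.metrics_b)[metric].ravel()
        mean = float(vals.mean())
        half = float(stats.t.ppf(0.975, len(vals) - 1)
                     * vals.std(ddof=1) / np.sqrt(len(vals)))
        return mean, mean - half, mean + half


def run_5x2_cv(stratum: list[PersonRecord], learner_a, learner_b,
               seed: int = 0, n_replications: int = 5,
               metrics: tuple[str, ...] = METRIC_NAMES) -> CVResult:
    """Stratified 5x2 cross-validated comparison of two learners."""
    events = np.array([p.cvd_event for p in stratum], dtype=bool)
    if events.sum() < 2 * n_replications:
        raise ComparisonError("too few events for event-stratified halves")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out_a = {m: np.zeros((n_replications, 2)) for m in metrics}
    out_b = {m: np.zeros((n_replications, 2)) for m in metrics}
    for r in range(n_replications):
        half_1, half_2 = stratified_halves(events, rng)
        for j, (train_idx, test_idx) in enumerate(
                [(half_1, half_2), (half_2, half_1)]):
            train = [stratum[i] for i in train_idx]
            test = [stratum[i] for i in test_idx]
            if not events[test_idx].any() or not events[train_idx].any():
                raise ComparisonError(
                    f"replication {r} fold {j}: a half has no events")
            fold_seed = r * 2 + j + 1
            for learner, sink in ((learner_a, out_a), (learner_b, out_b)):
                fitted = learner.fit(train, seed=fold_seed)
                vals = evaluate_fold(fitted, test, metrics)
                for m in metrics:
                    if m in vals:
                        sink[m][r, j] = vals[m]
            logger.info("5x2 replication %d fold %d done", r + 1, j + 1)
    return CVResult(metrics_a=out_a, metrics_b=out_b,
                    n_replications=n_replications,
                    label_a=type(learner_a).__name__,
                    label_b=type(learner_b).__name__)


def combined_f_test(d: np.ndarray) -> tuple[float, float]:
    """Combined 5x2 F test on a (5, 2) difference matrix.

    F = (sum_{r,j} d_rj^2) / (2 sum_r s_r^2) with s_r^2 the
    within-replication variance around the replication mean; the reference
    distribution is F with (10, 5) degrees of freedom. All-zero
    differences give (0, 1) by convention.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (5, 2):
        raise ComparisonError(f"difference matrix must be 5x2, got {d.shape}")
    num = float((d ** 2).sum())
    row_mean = d.mean(axis=1, keepdims=True)
    s2 = ((d - row_mean) ** 2).sum()
    if num == 0.0:
        return 0.0, 1.0
    if s2 == 0.0:
        raise ComparisonError("degenerate variance: identical fold "
                              "differences with nonzero magnitude")
    f_stat = num / (2.0 * s2)
    p = float(stats.f.sf(f_stat, 10, 5))
    return float(f_stat), p


# -- subgroup stratification ----------------------------------------------
AGE_BANDS = ((30, 45), (45, 60), (60, 75))


def builtin_strata(cohort: list[PersonRecord],
                   by: str) -> dict[str, np.ndarray]:
    """Index masks for the standard subgroup specifications."""
    if by == "age_bands":
        return {f"age_{lo}_{hi}": np.array([lo <= p.age < hi
                                            for p in cohort])
                for lo, hi in AGE_BANDS}
    if by == "ethnicity":
        levels = sorted({p.ethnicity for p in cohort})
        return {f"ethnicity_{e}": np.array([p.ethnicity == e
                                            for p in cohort])
                for e in levels}
    if by == "deprivation":
        return {f"deprivation_{q}": np.array([p.deprivation == q
                                              for p in cohort])
                for q in range(1, 6)}
    if by == "medications":
        return {flag: np.array([getattr(p, flag) for p in cohort])
                for flag in ("bp_lowering", "lipid_lowering",
                             "antiplatelet_anticoagulant")}
    if by == "all":
        return {"all": np.ones(len(cohort), dtype=bool)}
    raise ComparisonError(f"unknown stratification {by!r}")


@dataclass
class StratumReport:
    name: str
    n: int
    n_events: int
    c: float
    d: float
    r2: float
    deciles: DecileTable | None


def stratified_metrics(f: np.ndarray, risks: np.ndarray,
                       cohort: list[PersonRecord],
                       strata: dict[str, np.ndarray]
                       ) -> list[StratumReport]:
    """Discrimination and calibration metrics within each stratum.

    Strata without persons or events are skipped with a warning; decile
    tables require at least 10 persons.
    """
    f = np.asarray(f, dtype=float)
    risks = np.asarray(risks, dtype=float)
    times = np.array([p.follow_up_days for p in cohort], dtype=float)
    events = np.array([p.cvd_event for p in cohort], dtype=bool)
    reports = []
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0 or events[mask].sum() == 0:
            warnings.warn(f"stratum {name!r} empty or event-free; skipped",
                          stacklevel=2)
            continue
        try:
            c = harrells_c(f[mask], times[mask], events[mask])
            rd = royston_d_r2(f[mask], times[mask], events[mask])
        except MetricError as exc:
            warnings.warn(f"stratum {name!r} skipped: {exc}", stacklevel=2)
            continue
        dec = None
        if mask.sum() >= 10:
            dec = decile_tables(risks[mask], times[mask], events[mask])
        reports.append(StratumReport(
            name=name, n=int(mask.sum()), n_events=int(events[mask].sum()),
            c=c, d=rd.d, r2=rd.r2, deciles=dec))
    return reports
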