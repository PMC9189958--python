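"""Absolute risk anchoring and perturbation-based local hazard ratios.

Relative-risk models (Cox linear predictors and network log risks alike)
are identified only up to an additive constant, so absolute 5-year risks
are anchored at a *reference person*: mean age, deprivation quintile 3,
reference ethnicity, all condition/medication flags false, and an empty
coded history. The Breslow estimator gives the cumulative baseline hazard
at that person, and

    risk_i = 1 - S_ref(1826)^exp(f_i - f_ref).

Local hazard ratios probe a trained model by perturbing the reference
person — flipping a binary predictor, shifting a continuous one by one
unit, or appending a single coded event at the index month — and
exponentiating the change in f. Replicate models trained from different
random initializations give the spread; the mean and percentile 2.5/97.5
bounds across replicates are reported. These are model-explanation
quantities, not causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .records import (LOOKBACK_MONTHS, CenteringContext, PersonRecord,
                      with_event_appended)

HORIZON_DAYS = 1826


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineSurvival:
    """Breslow baseline survival S_ref(t) at the reference person."""

    event_times: np.ndarray
    cum_hazard: np.ndarray   # Lambda_ref at each event time

    def survival(self, t) -> np.ndarray:
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float),
                              side="right")
        lam = np.where(idx == 0, 0.0,
                       self.cum_hazard[np.maximum(idx - 1, 0)])
        return np.exp(-lam)

    def __call__(self, t) -> np.ndarray:
        return self.survival(t)


def breslow_baseline(predictions, times, events,
                     f_ref: float = 0.0) -> BaselineSurvival:
    """Breslow cumulative-hazard estimate anchored at ``f_ref``.

    Lambda_ref(t) = sum over event times t_j <= t of
    d_j / sum_{i in R(t_j)} exp(f_i - f_ref), with R(t) the persons whose
    follow-up reaches t. Works identically for Cox linear predictors and
    ensemble log risks.
    """
    f = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if e.sum() == 0:
        raise InferenceError("no events: baseline hazard is undefined")
    w = np.exp(f - f_ref)
    uniq = np.unique(t[e])
    # risk-set sums by sweeping times in decreasing order
    order = np.argsort(-t, kind="stable")
    sorted_t = t[order]
    csum = np.cumsum(w[order])
    increments = np.empty(uniq.size)
    for k, tj in enumerate(uniq):
        n_at_risk_idx = np.searchsorted(-sorted_t, -tj, side="right")
        denom = csum[n_at_risk_idx - 1]
        d_j = ((t == tj) & e).sum()
        increments[k] = d_j / denom
    return BaselineSurvival(event_times=uniq,
                            cum_hazard=np.cumsum(increments))


def five_year_risk(predictions, baseline: BaselineSurvival,
                   f_ref: float = 0.0,
                   horizon: float = HORIZON_DAYS) -> np.ndarray:
    """risk = 1 - S_ref(horizon)^exp(f - f_ref); increasing in f."""
    f = np.asarray(predictions, dtype=float)
    s_ref = float(baseline.survival(horizon))
    return 1.0 - s_ref ** np.exp(f - f_ref)


def reference_person(centering: CenteringContext,
                     sex: str = "F") -> PersonRecord:
    """Mean age, quintile 3, reference ethnicity, all flags false, no
    coded history."""
    return PersonRecord(
        person_id="__reference__", sex=sex, age=centering.mean_age,
        ethnicity="European", deprivation=centering.reference_deprivation,
        diabetes=False, atrial_fibrillation=False, bp_lowering=False,
        lipid_lowering=False, antiplatelet_anticoagulant=False, events=[])


@dataclass(frozen=True)
class Perturbation:
    """One probe of the reference person.

    kind:
      * ``binary``     — set the named flag to True
      * ``ethnicity``  — switch to the named level
      * ``continuous`` — per-unit effect of the named field, averaged over
                         ``grid`` (each grid value v contributes
                         exp(f(v + 1) - f(v)))
      * ``code``       — append one coded event at the index month
      * ``identity``   — no change (HR = 1, harness check)
    """

    label: str
    kind: str
    field: str | None = None
    value: object = None
    code: str | None = None
    code_type: str | None = None
    grid: tuple = ()


def _apply(person: PersonRecord, pert: Perturbation,
           value=None) -> PersonRecord:
    if pert.kind == "identity":
        return person
    if pert.kind == "binary":
        return replace(person, **{pert.field: True})
    if pert.kind == "ethnicity":
        return replace(person, ethnicity=pert.value)
    if pert.kind == "continuous":
        return replace(person, **{pert.field: value})
    if pert.kind == "code":
        return with_event_appended(person, pert.code, pert.code_type,
                                   month=LOOKBACK_MONTHS - 1)
    raise InferenceError(f"unknown perturbation kind {pert.kind!r}")


@dataclass(frozen=True)
class LocalHRRecord:
    """Mean local hazard ratio across replicates with percentile 95% CI."""

    label: str
    hr: float
    ci_low: float
    ci_high: float
    n_replicates: int

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise InferenceError("CI bounds must bracket the HR")
        if self.ci_low <= 0:
            raise InferenceError("hazard ratios must be positive")


def estimate_local_hr(replicate_predictors: list,
                      perturbations: list[Perturbation],
                      centering: CenteringContext,
                      sex: str = "F", vocab=None) -> list[LocalHRRecord]:
    """Local HRs averaged over replicate models.

    ``replicate_predictors`` are callables mapping a list of persons to
    their log relative risks f; one per independently trained replicate
    (K >= 2 so a CI exists). For each replicate k and perturbation,
    HR_k = exp(f_k(perturbed) - f_k(reference)); continuous perturbations
    average per-unit HRs over their value grid. When the models'
    ``vocab`` is supplied, code perturbations outside it are rejected
    (encoding would silently drop them, faking HR = 1).
    """
    K = len(replicate_predictors)
    if K < 2:
        raise InferenceError("need K >= 2 replicates for a CI")
    if vocab is not None:
        for pert in perturbations:
            if pert.kind == "code" and pert.code not in vocab:
                raise InferenceError(
                    f"code {pert.code!r} is not in the model vocabulary")
    base = reference_person(centering, sex=sex)
    records = []
    for pert in perturbations:
        hrs = np.empty(K)
        if pert.kind == "continuous":
            if not pert.grid:
                raise InferenceError(
                    f"continuous perturbation {pert.label!r} needs a grid")
            lo = [_apply(base, pert, value=v) for v in pert.grid]
            hi = [_apply(base, pert, value=v + 1) for v in pert.grid]
            for k, predict in enumerate(replicate_predictors):
                f_lo = np.asarray(predict(lo), dtype=float)
                f_hi = np.asarray(predict(hi), dtype=float)
                hrs[k] = float(np.mean(np.exp(f_hi - f_lo)))
        else:
            perturbed = _apply(base, pert)
            for k, predict in enumerate(replicate_predictors):
                f_pair = np.asarray(predict([base, perturbed]), dtype=float)
                hrs[k] = float(np.exp(f_pair[1] - f_pair[0]))
        records.append(LocalHRRecord(
            label=pert.label, hr=float(hrs.mean()),
            ci_low=float(min(np.percentile(hrs, 2.5), hrs.mean())),
            ci_high=float(max(np.percentile(hrs, 97.5), hrs.mean())),
            n_replicates=K))
    return records


def standard_perturbations(observed_ages, observed_deprivation,
                           codes: list[tuple[str, str]] = ()
                           ) -> list[Perturbation]:
    """The predictor probes matching the published table layout.

    Continuous age/deprivation use value grids over the observed range
    (age at its deciles, deprivation at quintiles 1-4 so v+1 stays valid).
    """
    ages = tuple(np.percentile(np.asarray(observed_ages, dtype=float),
                               np.arange(5, 96, 10)))
    perts = [
        Perturbation("age_per_year", "continuous", field="age", grid=ages),
        Perturbation("deprivation_per_quintile", "continuous",
                     field="deprivation", grid=(1, 2, 3, 4)),
        Perturbation("ethnicity_Maori", "ethnicity", value="Maori"),
        Perturbation("ethnicity_Pacific", "ethnicity", value="Pacific"),
        Perturbation("ethnicity_Indian", "ethnicity", value="Indian"),
        Perturbation("ethnicity_Other", "ethnicity", value="Other"),
        Perturbation("diabetes", "binary", field="diabetes"),
        Perturbation("atrial_fibrillation", "binary",
                     field="atrial_fibrillation"),
        Perturbation("bp_lowering", "binary", field="bp_lowering"),
        Perturbation("lipid_lowering", "binary", field="lipid_lowering"),
        Perturbation("antiplatelet_anticoagulant", "binary",
                     field="antiplatelet_anticoagulant"),
    ]
    for code, code_type in codes:
        perts.append(Perturbation(f"code_{code}", "code", code=code,
                                  code_type=code_type))
    return perts
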