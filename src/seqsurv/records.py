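"""Domain types and encoding rules for longitudinal coded health records.

A cohort is a list of :class:`PersonRecord`. Each person carries baseline
covariates (sex, age, ethnicity, deprivation quintile, condition and
medication flags), a chronologically ordered sequence of coded events
(diagnoses, procedures, medications) within a 60-month lookback window, and
a right-censored time-to-event outcome over a 5-year (1826-day) horizon.

Encoding conventions
--------------------
* Codes are mapped to contiguous integer indices starting at 1; index 0 is
  reserved for padding. Index order is lexicographic in the code string so
  vocabularies are deterministic across runs.
* Rare codes (distinct-person support below ``min_persons``) are excluded
  from the vocabulary; events carrying such codes are dropped before the
  inter-event time differences are computed, so the Δt sequence describes
  the sequence a model actually consumes.
* Age and deprivation are centred (stratum mean age; quintile 3), so the
  reference person maps to the all-zero covariate vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

LOOKBACK_MONTHS = 60
HORIZON_DAYS = 1826

#: event code types; order fixes the integer encoding (padding is 0)
CODE_TYPES = ("primary_dx", "secondary_dx", "external_cause", "procedure",
              "medication")
_TYPE_INDEX = {t: i + 1 for i, t in enumerate(CODE_TYPES)}

#: ethnicity levels; the first is the reference level (no one-hot column)
ETHNICITY_LEVELS = ("European", "Maori", "Pacific", "Indian", "Other")

#: interaction terms of the full pre-specified predictor set, as pairs of
#: base-covariate names (age means centred age)
INTERACTION_PAIRS = (
    ("age", "bp_lowering"),
    ("age", "diabetes"),
    ("age", "atrial_fibrillation"),
    ("bp_lowering", "diabetes"),
    ("antiplatelet_anticoagulant", "diabetes"),
    ("bp_lowering", "lipid_lowering"),
)

FLAG_FIELDS = ("diabetes", "atrial_fibrillation", "bp_lowering",
               "lipid_lowering", "antiplatelet_anticoagulant")


class CohortError(ValueError):
    """Invalid cohort input (empty cohort, malformed record, bad field)."""


@dataclass(frozen=True)
class CodeEvent:
    """One coded listing: a code, its type tag, and its calendar-month slot.

    ``month`` is a 0-based index within the lookback window; the index-date
    month is ``LOOKBACK_MONTHS - 1``. A hospitalization spanning several
    calendar months lists its codes once per month, so replicated events are
    legal and preserved.
    """

    code: str
    code_type: str
    month: int

    def __post_init__(self) -> None:
        if self.code_type not in _TYPE_INDEX:
            raise CohortError(f"unknown code_type {self.code_type!r}")
        if not (0 <= self.month < LOOKBACK_MONTHS):
            raise CohortError(
                f"month {self.month} outside [0, {LOOKBACK_MONTHS - 1}]")


@dataclass
class PersonRecord:
    """One individual: covariates, coded event sequence, censored outcome.

    ``cvd_event`` is True when ``follow_up_days`` is the day of the first
    CVD event, False when it is a censoring time (non-CVD death, emigration
    or the administrative 5-year horizon).
    """

    person_id: str
    sex: str                      # "F" or "M"
    age: float                    # years, 30-74
    ethnicity: str
    deprivation: int              # quintile 1-5
    diabetes: bool
    atrial_fibrillation: bool
    bp_lowering: bool
    lipid_lowering: bool
    antiplatelet_anticoagulant: bool
    events: list[CodeEvent] = field(default_factory=list)
    follow_up_days: int | None = None
    cvd_event: bool | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise CohortError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise CohortError(f"unknown ethnicity {self.ethnicity!r}")
        if not 1 <= self.deprivation <= 5:
            raise CohortError(
                f"deprivation quintile {self.deprivation} outside 1-5")
        months = [e.month for e in self.events]
        if any(b < a for a, b in zip(months, months[1:])):
            raise CohortError(
                f"person {self.person_id}: events not sorted by month")
        if self.follow_up_days is not None:
            if not 1 <= self.follow_up_days <= HORIZON_DAYS:
                raise CohortError(
                    f"follow_up_days {self.follow_up_days} outside "
                    f"[1, {HORIZON_DAYS}]")


@dataclass(frozen=True)
class Vocabulary:
    """Code -> contiguous index map with per-code distinct-person support.

    Indices start at 1 (0 is padding) and follow lexicographic code order.
    """

    index: dict[str, int]
    person_counts: dict[str, int]
    min_persons: int

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, code: str) -> bool:
        return code in self.index


@dataclass(frozen=True)
class EncodedHistory:
    """Integer sequences ready for the network: tokens, types, Δt (months)."""

    token_idx: np.ndarray
    type_idx: np.ndarray
    delta_t: np.ndarray

    def __len__(self) -> int:
        return len(self.token_idx)


@dataclass(frozen=True)
class CenteringContext:
    """Centering constants fitted on a training stratum.

    ``mean_age`` is the stratum's training-data mean age; deprivation is
    centred at the reference quintile 3. The reference person (mean age,
    quintile 3, reference ethnicity, all flags false) maps to the zero
    vector under both predictor sets.
    """

    mean_age: float
    reference_deprivation: int = 3
    sex: str | None = None

    @classmethod
    def fit(cls, cohort: list[PersonRecord], sex: str | None = None
            ) -> "CenteringContext":
        persons = [p for p in cohort if sex is None or p.sex == sex]
        if not persons:
            raise CohortError("cannot fit centering on an empty stratum")
        return cls(mean_age=float(np.mean([p.age for p in persons])), sex=sex)


def covariate_names(predictor_set: str = "full") -> list[str]:
    """Stable column layout of the covariate vector.

    full:    age, deprivation, ethnicity one-hot (reference omitted), the
             five condition/medication flags, then the six pre-specified
             first-order interactions.
    reduced: age, deprivation, ethnicity one-hot only (the ablation set).
    """
    names = ["age", "deprivation"]
    names += [f"ethnicity_{e}" for e in ETHNICITY_LEVELS[1:]]
    if predictor_set == "reduced":
        return names
    if predictor_set != "full":
        raise CohortError(f"predictor_set must be full/reduced, "
                          f"got {predictor_set!r}")
    names += list(FLAG_FIELDS)
    names += [f"{a}*{b}" for a, b in INTERACTION_PAIRS]
    return names


def make_covariate_vector(person: PersonRecord, centering: CenteringContext,
                          predictor_set: str = "full") -> np.ndarray:
    """Build the centred covariate vector for one person.

    Interaction entries are exact products of their (centred) factor
    entries; a reference person yields the all-zero vector.
    """
    if not 1 <= person.deprivation <= 5:
        raise CohortError(f"deprivation {person.deprivation} outside 1-5")
    base = {
        "age": person.age - centering.mean_age,
        "deprivation": float(person.deprivation
                             - centering.reference_deprivation),
    }
    for e in ETHNICITY_LEVELS[1:]:
        base[f"ethnicity_{e}"] = 1.0 if person.ethnicity == e else 0.0
    for f in FLAG_FIELDS:
        base[f] = 1.0 if getattr(person, f) else 0.0
    for a, b in INTERACTION_PAIRS:
        base[f"{a}*{b}"] = base[a] * base[b]
    return np.array([base[n] for n in covariate_names(predictor_set)],
                    dtype=float)


def covariate_matrix(cohort: list[PersonRecord], centering: CenteringContext,
                     predictor_set: str = "full") -> np.ndarray:
    """Stack covariate vectors for a cohort, one row per person."""
    return np.array([make_covariate_vector(p, centering, predictor_set)
                     for p in cohort])


def build_vocabulary(cohort: list[PersonRecord], min_persons: int = 1
                     ) -> Vocabulary:
    """Build the code vocabulary, excluding rare codes.

    A code's support is the number of distinct persons with at least one
    listing of it (replicated listings within one person count once). Codes
    supported by fewer than ``min_persons`` persons are excluded, mirroring
    the exclusion of rare codes and medications in national-scale cohorts.
    """
    if not cohort:
        raise CohortError("cannot build a vocabulary from an empty cohort")
    if min_persons < 1:
        raise CohortError("min_persons must be >= 1")
    counts: dict[str, int] = {}
    for person in cohort:
        for code in {e.code for e in person.events}:
            counts[code] = counts.get(code, 0) + 1
    kept = sorted(c for c, n in counts.items() if n >= min_persons)
    if not kept:
        raise CohortError(
            f"empty vocabulary: no code reaches min_persons={min_persons}")
    return Vocabulary(index={c: i + 1 for i, c in enumerate(kept)},
                      person_counts={c: counts[c] for c in kept},
                      min_persons=min_persons)


def encode_history(person: PersonRecord, vocab: Vocabulary) -> EncodedHistory:
    """Encode a person's event sequence under a fitted vocabulary.

    Out-of-vocabulary events are dropped before Δt computation, so Δt
    describes gaps in the retained sequence. An empty retained sequence is
    legal and yields length-0 arrays.
    """
    kept = [e for e in person.events if e.code in vocab]
    n_dropped = len(person.events) - len(kept)
    if n_dropped:
        logger.debug("person %s: dropped %d out-of-vocabulary events",
                     person.person_id, n_dropped)
    tokens = np.array([vocab.index[e.code] for e in kept], dtype=np.int64)
    types = np.array([_TYPE_INDEX[e.code_type] for e in kept], dtype=np.int64)
    months = np.array([e.month for e in kept], dtype=np.int64)
    delta = np.diff(months, prepend=months[:1]) if len(kept) else months
    return EncodedHistory(token_idx=tokens, type_idx=types, delta_t=delta)


def with_event_appended(person: PersonRecord, code: str, code_type: str,
                        month: int = LOOKBACK_MONTHS - 1) -> PersonRecord:
    """Copy of ``person`` with one extra event appended at ``month``.

    Used by the local hazard-ratio perturbation machinery; the event is
    placed at the index-date month by default, after any existing events.
    """
    ev = CodeEvent(code=code, code_type=code_type, month=month)
    if person.events and person.events[-1].month > month:
        raise CohortError("appended event would break chronological order")
    return replace(person, events=list(person.events) + [ev])
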