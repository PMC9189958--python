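import numpy as np
import pytest

from seqsurv import (CenteringContext, CodeEvent, PersonRecord,
                     SimulationConfig, generate_cohort)


def make_person(pid="P0", sex="F", age=52.0, ethnicity="European",
                deprivation=3, events=(), follow_up_days=None,
                cvd_event=None, **flags) -> PersonRecord:
    base = dict(diabetes=False, atrial_fibrillation=False,
                bp_lowering=False, lipid_lowering=False,
                antiplatelet_anticoagulant=False)
    base.update(flags)
    return PersonRecord(person_id=pid, sex=sex, age=age,
                        ethnicity=ethnicity, deprivation=deprivation,
                        events=list(events), follow_up_days=follow_up_days,
                        cvd_event=cvd_event, **base)


@pytest.fixture
def centering():
    return CenteringContext(mean_age=52.0)


@pytest.fixture
def tiny_cohort():
    """Three persons with overlapping codes and set outcomes."""
    return [
        make_person("P1", events=[CodeEvent("A", "primary_dx", 3),
                                  CodeEvent("B", "medication", 7)],
                    follow_up_days=400, cvd_event=True),
        make_person("P2", age=60.0, deprivation=5, diabetes=True,
                    events=[CodeEvent("A", "secondary_dx", 10)],
                    follow_up_days=1826, cvd_event=False),
        make_person("P3", sex="M", ethnicity="Maori",
                    events=[CodeEvent("C", "procedure", 59)],
                    follow_up_days=900, cvd_event=False),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A 600-person simulated cohort with outcomes (session-cached)."""
    config = SimulationConfig(n_persons=600, seed=42)
    cohort, truth = generate_cohort(config)
    return cohort, truth


@pytest.fixture(scope="session")
def survival_arrays(small_sim):
    cohort, _ = small_sim
    times = np.array([p.follow_up_days for p in cohort], dtype=float)
    events = np.array([p.cvd_event for p in cohort], dtype=bool)
    return cohort, times, events
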