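"""Plain-text cohort files: persons.csv, events.csv and a manifest.

The on-disk dialect is two UTF-8 comma-separated tables:

``persons.csv``
    one row per person: person_id, sex, age, ethnicity, deprivation,
    diabetes, atrial_fibrillation, bp_lowering, lipid_lowering,
    antiplatelet_anticoagulant, follow_up_days, cvd_event.
    Boolean columns hold 0/1; outcome columns may be empty when outcomes
    are not yet simulated/observed.

``events.csv``
    one row per code listing: person_id, code, code_type, month.
    Rows are written in each person's event order and read back in file
    order, so round-tripping preserves within-month tie order exactly.

``manifest.txt``
    flat ``key: value`` lines recording the lookback convention and, once
    fitted, the centering context.

Malformed rows raise :class:`~seqsurv.records.CohortError` naming the file,
line number and offending field.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .records import (LOOKBACK_MONTHS, CenteringContext, CodeEvent,
                      CohortError, PersonRecord)

PERSON_COLUMNS = ["person_id", "sex", "age", "ethnicity", "deprivation",
                  "diabetes", "atrial_fibrillation", "bp_lowering",
                  "lipid_lowering", "antiplatelet_anticoagulant",
                  "follow_up_days", "cvd_event"]
EVENT_COLUMNS = ["person_id", "code", "code_type", "month"]
_BOOL_FIELDS = ("diabetes", "atrial_fibrillation", "bp_lowering",
                "lipid_lowering", "antiplatelet_anticoagulant")


def _fail(path: Path, line: int, fieldname: str, message: str) -> None:
    raise CohortError(f"{path}:{line}: field {fieldname!r}: {message}")


def write_cohort(cohort: list[PersonRecord], directory: str | Path,
                 centering: CenteringContext | None = None) -> Path:
    """Write a cohort to ``directory`` (created if needed); returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "persons.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PERSON_COLUMNS)
        for p in cohort:
            w.writerow([
                p.person_id, p.sex, repr(p.age), p.ethnicity, p.deprivation,
                *[int(getattr(p, f)) for f in _BOOL_FIELDS],
                "" if p.follow_up_days is None else p.follow_up_days,
                "" if p.cvd_event is None else int(p.cvd_event),
            ])
    with open(directory / "events.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for p in cohort:
            for e in p.events:
                w.writerow([p.person_id, e.code, e.code_type, e.month])
    lines = [f"lookback_months: {LOOKBACK_MONTHS}",
             "index_date_month: last lookback month (0-based "
             f"{LOOKBACK_MONTHS - 1})"]
    if centering is not None:
        lines += [f"centering_mean_age: {centering.mean_age!r}",
                  f"centering_reference_deprivation: "
                  f"{centering.reference_deprivation}",
                  f"centering_sex: {centering.sex or ''}"]
    (directory / "manifest.txt").write_text("\n".join(lines) + "\n",
                                            encoding="utf-8")
    return directory


def _parse_int(value: str, path: Path, line: int, fieldname: str) -> int:
    try:
        return int(value)
    except ValueError:
        _fail(path, line, fieldname, f"expected an integer, got {value!r}")


def _parse_bool(value: str, path: Path, line: int, fieldname: str) -> bool:
    if value not in ("0", "1"):
        _fail(path, line, fieldname, f"expected 0/1, got {value!r}")
    return value == "1"


def read_cohort(directory: str | Path) -> list[PersonRecord]:
    """Read a cohort written by :func:`write_cohort`.

    Field-level validation errors carry the file, line and field name;
    person invariants (sorted events, outcome bounds) are re-checked on
    construction.
    """
    directory = Path(directory)
    ppath = directory / "persons.csv"
    epath = directory / "events.csv"
    persons: dict[str, PersonRecord] = {}
    with open(ppath, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != PERSON_COLUMNS:
            raise CohortError(f"{ppath}: header mismatch: {reader.fieldnames}")
        for i, row in enumerate(reader, start=2):
            pid = row["person_id"]
            if not pid:
                _fail(ppath, i, "person_id", "empty")
            if pid in persons:
                _fail(ppath, i, "person_id", f"duplicate id {pid!r}")
            try:
                age = float(row["age"])
            except ValueError:
                _fail(ppath, i, "age", f"expected a number, got {row['age']!r}")
            fu = row["follow_up_days"]
            ev = row["cvd_event"]
            try:
                persons[pid] = PersonRecord(
                    person_id=pid, sex=row["sex"], age=age,
                    ethnicity=row["ethnicity"],
                    deprivation=_parse_int(row["deprivation"], ppath, i,
                                           "deprivation"),
                    **{f: _parse_bool(row[f], ppath, i, f)
                       for f in _BOOL_FIELDS},
                    follow_up_days=(None if fu == "" else
                                    _parse_int(fu, ppath, i,
                                               "follow_up_days")),
                    cvd_event=(None if ev == "" else
                               _parse_bool(ev, ppath, i, "cvd_event")),
                )
            except CohortError as exc:
                raise CohortError(f"{ppath}:{i}: {exc}") from exc
    with open(epath, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != EVENT_COLUMNS:
            raise CohortError(f"{epath}: header mismatch: {reader.fieldnames}")
        for i, row in enumerate(reader, start=2):
            pid = row["person_id"]
            if pid not in persons:
                _fail(epath, i, "person_id", f"unknown person {pid!r}")
            month = _parse_int(row["month"], epath, i, "month")
            if not 0 <= month < LOOKBACK_MONTHS:
                _fail(epath, i, "month",
                      f"{month} outside [0, {LOOKBACK_MONTHS - 1}]")
            try:
                event = CodeEvent(code=row["code"],
                                  code_type=row["code_type"], month=month)
            except CohortError as exc:
                raise CohortError(f"{epath}:{i}: {exc}") from exc
            prev = persons[pid].events
            if prev and prev[-1].month > month:
                _fail(epath, i, "month",
                      f"person {pid!r}: months not non-decreasing")
            prev.append(event)
    return list(persons.values())


def read_manifest(directory: str | Path) -> dict[str, str]:
    """Parse manifest.txt into a flat string dict."""
    text = (Path(directory) / "manifest.txt").read_text(encoding="utf-8")
    out = {}
    for line in text.splitlines():
        if line.strip():
            key, _, value = line.partition(":")
            out[key.strip()] = value.strip()
    return out
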