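"""Domain types, delimited-text readers/writers, validation and duplicate-identifier merging.

The analysis operates on three delimited-text tables sharing one opaque
patient identifier (the provincial folder number):

* a cohort table — one row per transferred adolescent with demographics,
  enrolment/ART-start/transfer-out dates and at-transfer laboratory values;
* an event table — one row per dated contact in one source stream
  (clinic visit, laboratory test, pharmacy dispensing) at one facility;
* a duplicate map — alias identifier -> canonical identifier pairs, used to
  merge event streams when one person was issued more than one identifier.

All dates are calendar dates at day resolution (ISO-8601 in files) and all
date arithmetic downstream is in integer days.  Ages derived from dates use
365.25 days per year.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

DAYS_PER_YEAR = 365.25

SOURCES = ("visit", "lab", "pharmacy")
#: tie-break rank when several streams record a contact on the same day
SOURCE_ORDER = {"visit": 0, "lab": 1, "pharmacy": 2}
ANALYTES = ("hiv_rna", "cd4", "none")
CARE_LEVELS = ("primary", "tertiary")
SEXES = ("male", "female")


class CohortDataError(Exception):
    """Base class for data-layer errors."""


class SchemaError(CohortDataError):
    """A required column is missing or a file header is malformed."""


class RowValidationError(CohortDataError):
    """One or more rows violate type invariants.

    Attributes
    ----------
    problems : list of (row_index, message)
        0-based data-row indices (header excluded) with a description of the
        offending value.
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems[:20])
        extra = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{extra}")


class ConfigurationError(CohortDataError):
    """Invalid analysis or duplicate-map configuration (e.g. a cyclic map)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PatientRecord:
    """One transferred adolescent, as recorded by the originating cohort."""

    patient_id: str
    sex: str
    enrolment_date: datetime.date
    art_start_date: datetime.date
    transfer_out_date: datetime.date
    age_at_enrolment: float
    age_at_art_start: float
    age_at_transfer: float
    origin_facility: str
    origin_level: str
    cd4_at_transfer: float | None = None
    vl_at_transfer: float | None = None
    cd4_at_art_start: float | None = None
    cd4pct_at_art_start: float | None = None

    def problems(self) -> list[str]:
        """Invariant violations for this record (empty when valid)."""
        out: list[str] = []
        if self.sex not in SEXES:
            out.append(f"sex {self.sex!r} not in {SEXES}")
        if self.origin_level not in CARE_LEVELS:
            out.append(f"origin_level {self.origin_level!r} not in {CARE_LEVELS}")
        if not (self.enrolment_date <= self.art_start_date <= self.transfer_out_date):
            out.append(
                "dates out of order: enrolment "
                f"{self.enrolment_date} / ART start {self.art_start_date} / "
                f"transfer out {self.transfer_out_date}"
            )
        if not (10.0 <= self.age_at_transfer < 20.0):
            out.append(f"age_at_transfer {self.age_at_transfer} outside [10, 20)")
        if not (self.age_at_enrolment <= self.age_at_art_start <= self.age_at_transfer):
            out.append("ages not non-decreasing in enrolment -> ART start -> transfer order")
        for name in ("cd4_at_transfer", "vl_at_transfer", "cd4_at_art_start", "cd4pct_at_art_start"):
            v = getattr(self, name)
            if v is not None and v < 0:
                out.append(f"{name} negative: {v}")
        return out


@dataclass(frozen=True)
class EventRecord:
    """One dated contact in one source stream at one facility.

    ``analyte``/``value`` are meaningful only for laboratory events; all
    other sources carry ``analyte='none'`` and no value.
    """

    patient_id: str
    facility: str
    date: datetime.date
    source: str
    analyte: str = "none"
    value: float | None = None

    def problems(self) -> list[str]:
        out: list[str] = []
        if self.source not in SOURCES:
            out.append(f"source {self.source!r} not in {SOURCES}")
        if self.analyte not in ANALYTES:
            out.append(f"analyte {self.analyte!r} not in {ANALYTES}")
        if self.source != "lab" and self.analyte != "none":
            out.append(f"non-lab event carries analyte {self.analyte!r}")
        if self.value is not None:
            if self.source != "lab" or self.analyte == "none":
                out.append("value present on an event without a lab analyte")
            elif self.value < 0:
                out.append(f"negative lab value {self.value}")
        if self.source == "lab" and self.analyte != "none" and self.value is None:
            out.append(f"lab event with analyte {self.analyte!r} but no value")
        return out


class DuplicateMap:
    """Alias -> canonical identifier map, resolved transitively.

    Chains (``C -> B``, ``B -> A``) are collapsed so every alias points at a
    canonical identifier that is not itself an alias.  A cycle anywhere in
    the map is a :class:`ConfigurationError`.
    """

    def __init__(self, pairs: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        raw = dict(pairs.items() if isinstance(pairs, Mapping) else pairs)
        for alias, canon in raw.items():
            if alias == canon:
                raise ConfigurationError(f"identifier {alias!r} maps to itself")
        self._raw = raw
        self._resolved = self._transitive_closure(raw)

    @staticmethod
    def _transitive_closure(raw: Mapping[str, str]) -> dict[str, str]:
        resolved: dict[str, str] = {}
        for alias in raw:
            seen = [alias]
            cur = alias
            while cur in raw:
                cur = raw[cur]
                if cur in seen:
                    raise ConfigurationError(
                        "cyclic duplicate map: " + " -> ".join(seen + [cur])
                    )
                seen.append(cur)
            resolved[alias] = cur
        return resolved

    def canonical(self, patient_id: str) -> str:
        return self._resolved.get(patient_id, patient_id)

    @property
    def aliases(self) -> dict[str, str]:
        """Fully resolved alias -> canonical pairs."""
        return dict(self._resolved)

    def __len__(self) -> int:
        return len(self._resolved)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DuplicateMap) and self._resolved == other._resolved


def resolve_duplicates(events: Sequence[EventRecord], duplicate_map: DuplicateMap) -> list[EventRecord]:
    """Rewrite event identifiers to their canonical form.

    Preserves event count, order and every non-identifier field; idempotent
    because canonical targets are never themselves aliases.
    """
    out = []
    for ev in events:
        canon = duplicate_map.canonical(ev.patient_id)
        out.append(ev if canon == ev.patient_id else dataclasses.replace(ev, patient_id=canon))
    return out


@dataclass
class AnalysisConfig:
    """All analysis constants and interpretation toggles.

    Defaults encode the study conventions: database closure mid-October 2016,
    6 months = 183 days, 18 months = 548 days, 1 year = 365 days, virologic
    suppression below 400 copies/ml, immunologic recovery above 500 cells/ul,
    perinatal-infection proxy = enrolment before age 13, and the 10-14 vs
    15-19 age split at transfer.
    """

    closure_date: datetime.date = datetime.date(2016, 10, 15)
    window_halfwidth_days: int = 183
    months18_days: int = 548
    year_days: int = 365
    suppression_threshold: float = 400.0
    cd4_threshold: float = 500.0
    perinatal_cutoff_years: float = 13.0
    adolescent_age_split_years: float = 15.0
    source_subset: tuple[str, ...] = SOURCES
    # interpretation toggles (defaults documented in docs/methods.md)
    same_day_qualifies: bool = False       # does a record elsewhere ON the transfer date qualify?
    retention_includes_origin: bool = False  # do return visits to the origin facility count as retained?
    cd4_threshold_inclusive: bool = False    # >500 strict (False) vs >=500 (True)
    missing_vl_grace_days: int = 183         # "shortly after" the year-3 window

    def __post_init__(self) -> None:
        for name in ("window_halfwidth_days", "months18_days", "year_days",
                     "suppression_threshold", "cd4_threshold",
                     "perinatal_cutoff_years", "adolescent_age_split_years",
                     "missing_vl_grace_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        subset = tuple(self.source_subset)
        if not subset:
            raise ConfigurationError("source_subset must be non-empty")
        for s in subset:
            if s not in SOURCES:
                raise ConfigurationError(f"unknown source {s!r} in source_subset")
        self.source_subset = subset

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "closure_date" in raw and isinstance(raw["closure_date"], str):
            raw["closure_date"] = datetime.date.fromisoformat(raw["closure_date"])
        if "source_subset" in raw:
            raw["source_subset"] = tuple(raw["source_subset"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["closure_date"] = self.closure_date.isoformat()
        d["source_subset"] = list(self.source_subset)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# delimited-text I/O

_PATIENT_REQUIRED = [
    "patient_id", "sex", "enrolment_date", "art_start_date", "transfer_out_date",
    "age_at_enrolment", "age_at_art_start", "age_at_transfer",
    "origin_facility", "origin_level",
]
_PATIENT_OPTIONAL = ["cd4_at_transfer", "vl_at_transfer", "cd4_at_art_start", "cd4pct_at_art_start"]
_PATIENT_COLUMNS = _PATIENT_REQUIRED + _PATIENT_OPTIONAL

_EVENT_REQUIRED = ["patient_id", "facility", "date", "source"]
_EVENT_COLUMNS = _EVENT_REQUIRED + ["analyte", "value"]

_DUP_COLUMNS = ["alias_id", "canonical_id"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _parse_date(value: object, column: str, row: int, problems: list[tuple[int, str]]) -> datetime.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        problems.append((row, f"{column}: missing date"))
        return None
    try:
        return datetime.date.fromisoformat(str(value).strip())
    except ValueError:
        problems.append((row, f"{column}: unparseable date {value!r}"))
        return None


def _opt_float(value: object) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read patients.csv, validating schema and per-row invariants.

    Raises :class:`SchemaError` for missing columns and
    :class:`RowValidationError` (carrying every offending 0-based row index)
    when any row is invalid.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, _PATIENT_REQUIRED, "cohort table")
    problems: list[tuple[int, str]] = []
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        dates = {c: _parse_date(d[c], c, i, problems)
                 for c in ("enrolment_date", "art_start_date", "transfer_out_date")}
        if any(v is None for v in dates.values()):
            continue
        try:
            rec = PatientRecord(
                patient_id=str(d["patient_id"]),
                sex=str(d["sex"]),
                enrolment_date=dates["enrolment_date"],
                art_start_date=dates["art_start_date"],
                transfer_out_date=dates["transfer_out_date"],
                age_at_enrolment=float(d["age_at_enrolment"]),
                age_at_art_start=float(d["age_at_art_start"]),
                age_at_transfer=float(d["age_at_transfer"]),
                origin_facility=str(d["origin_facility"]),
                origin_level=str(d["origin_level"]),
                **{c: _opt_float(d.get(c)) for c in _PATIENT_OPTIONAL},
            )
        except (TypeError, ValueError) as exc:
            problems.append((i, str(exc)))
            continue
        bad = rec.problems()
        if bad:
            problems.extend((i, msg) for msg in bad)
        else:
            records.append(rec)
    if problems:
        raise RowValidationError(problems)
    return records


def write_cohort(patients: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for p in patients:
        d = dataclasses.asdict(p)
        for c in ("enrolment_date", "art_start_date", "transfer_out_date"):
            d[c] = d[c].isoformat()
        rows.append(d)
    pd.DataFrame(rows, columns=_PATIENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list[EventRecord]:
    """Read events.csv with the same validation contract as :func:`read_cohort`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, _EVENT_REQUIRED, "event table")
    problems: list[tuple[int, str]] = []
    records: list[EventRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        date = _parse_date(d["date"], "date", i, problems)
        if date is None:
            continue
        try:
            rec = EventRecord(
                patient_id=str(d["patient_id"]),
                facility=str(d["facility"]),
                date=date,
                source=str(d["source"]),
                analyte=str(d.get("analyte") or "none"),
                value=_opt_float(d.get("value")),
            )
        except (TypeError, ValueError) as exc:
            problems.append((i, str(exc)))
            continue
        bad = rec.problems()
        if bad:
            problems.extend((i, msg) for msg in bad)
        else:
            records.append(rec)
    if problems:
        raise RowValidationError(problems)
    return records


def write_events(events: Sequence[EventRecord], path: str | Path) -> None:
    rows = []
    for e in events:
        d = dataclasses.asdict(e)
        d["date"] = e.date.isoformat()
        rows.append(d)
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_duplicates(path: str | Path) -> DuplicateMap:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, _DUP_COLUMNS, "duplicate map")
    return DuplicateMap(zip(df["alias_id"], df["canonical_id"]))


def write_duplicates(dmap: DuplicateMap | Mapping[str, str], path: str | Path) -> None:
    pairs = dmap.aliases if isinstance(dmap, DuplicateMap) else dict(dmap)
    pd.DataFrame(sorted(pairs.items()), columns=_DUP_COLUMNS).to_csv(path, index=False)


def events_by_patient(events: Sequence[EventRecord]) -> dict[str, list[EventRecord]]:
    """Group events by (canonical) identifier, each group sorted by date then
    source rank then facility — the deterministic order the classifier scans."""
    groups: dict[str, list[EventRecord]] = {}
    for ev in events:
        groups.setdefault(ev.patient_id, []).append(ev)
    for evs in groups.values():
        evs.sort(key=lambda e: (e.date, SOURCE_ORDER[e.source], e.facility))
    return groups
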