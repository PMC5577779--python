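"""Synthetic electronic-health-record cohort generator.

Emulates the data-generating process the analysis assumes: adolescents on
ART formally transferred out of four origin facilities (two tertiary, two
primary), a latent transfer-success process, a log-normal linkage delay, a
post-transfer visit/attrition process at the destination clinic, yearly
laboratory monitoring whose completeness declines over time, per-source
capture probabilities (visit / laboratory / pharmacy streams), occasional
duplicate identifiers splitting one person's record, and a fraction of
out-of-scope transfers (e.g. out of province) that leave no trace in the
observable streams.

Alongside the three observable tables the generator emits a ``truth`` table
recording each patient's latent status (in-scope, success, true delay, true
retention and suppression per year) for parameter-recovery tests.  Identical
``(config, seed)`` give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .records_io import (
    DAYS_PER_YEAR,
    SOURCES,
    ConfigurationError,
    DuplicateMap,
    EventRecord,
    PatientRecord,
    write_cohort,
    write_duplicates,
    write_events,
)

#: log-scale sd matching the reported delay IQR (27-134 d) around a 56-d median
DEFAULT_DELAY_SIGMA = math.log(134 / 27) / (2 * 0.6745)

ORIGIN_TERTIARY = ("T_RedCross", "T_Tygerberg")
ORIGIN_PRIMARY = ("P_Gugulethu", "P_Khayelitsha")
DESTINATIONS = tuple(f"C_{i:02d}" for i in range(1, 13))


@dataclass
class CohortGenConfig:
    """Every parameter of the synthetic data-generating process.

    Defaults reproduce the study conditions: cohort composition (53.3%
    female, 72.2% transferring at 10-14 y, 79.3% from tertiary care),
    transfer-out dates uniform over March 2004 - December 2014 with database
    closure 2016-10-15, ~5% out-of-scope transfers, 85% success among
    in-scope patients at a log-normal delay with median 56 days and IQR
    ~27-134, visit/lab/pharmacy capture 0.95/0.85/0.55, and laboratory
    completeness declining from ~0.89/0.87 (HIV-RNA/CD4) at year 1 to
    ~0.80/0.72 at year 3.
    """

    n_patients: int = 460
    seed: int = 0
    p_female: float = 0.533
    p_young_transfer: float = 0.722
    p_tertiary: float = 0.793
    p_out_of_scope: float = 0.05
    p_success_given_in_scope: float = 0.85
    delay_lognormal_median_days: float = 56.0
    delay_lognormal_sigma: float = DEFAULT_DELAY_SIGMA
    visit_interval_days: float = 84.0
    annual_dropout_hazard: float = 0.05
    p_vl_measured_by_year: tuple[float, float, float] = (0.89, 0.85, 0.80)
    p_cd4_measured_by_year: tuple[float, float, float] = (0.87, 0.80, 0.72)
    p_suppressed: float = 0.80
    suppression_markov: bool = False
    suppression_persistence: float = 0.9
    source_coverage: dict = field(
        default_factory=lambda: {"visit": 0.95, "lab": 0.85, "pharmacy": 0.55})
    p_duplicate_id: float = 0.02
    study_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2004, 3, 1), datetime.date(2014, 12, 31))
    closure_date: datetime.date = datetime.date(2016, 10, 15)
    # at-transfer laboratory state (cohort-table columns)
    p_vl_at_transfer: float = 0.94
    p_suppressed_at_transfer: float = 0.78
    p_cd4_at_transfer: float = 0.97

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` before any sampling happens."""
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        probs = {
            "p_female": self.p_female,
            "p_young_transfer": self.p_young_transfer,
            "p_tertiary": self.p_tertiary,
            "p_out_of_scope": self.p_out_of_scope,
            "p_success_given_in_scope": self.p_success_given_in_scope,
            "p_suppressed": self.p_suppressed,
            "suppression_persistence": self.suppression_persistence,
            "p_duplicate_id": self.p_duplicate_id,
            "p_vl_at_transfer": self.p_vl_at_transfer,
            "p_suppressed_at_transfer": self.p_suppressed_at_transfer,
            "p_cd4_at_transfer": self.p_cd4_at_transfer,
        }
        for i, p in enumerate(self.p_vl_measured_by_year):
            probs[f"p_vl_measured_by_year[{i}]"] = p
        for i, p in enumerate(self.p_cd4_measured_by_year):
            probs[f"p_cd4_measured_by_year[{i}]"] = p
        for s, p in self.source_coverage.items():
            if s not in SOURCES:
                raise ConfigurationError(f"unknown source {s!r} in source_coverage")
            probs[f"source_coverage[{s}]"] = p
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in ("delay_lognormal_median_days", "delay_lognormal_sigma",
                     "visit_interval_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.annual_dropout_hazard < 0:
            raise ConfigurationError("annual_dropout_hazard must be non-negative")
        if self.study_window[0] > self.study_window[1]:
            raise ConfigurationError("study_window start after end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortGenConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        for key in ("closure_date",):
            if key in raw and isinstance(raw[key], str):
                raw[key] = datetime.date.fromisoformat(raw[key])
        if "study_window" in raw:
            raw["study_window"] = tuple(
                datetime.date.fromisoformat(d) if isinstance(d, str) else d
                for d in raw["study_window"])
        for key in ("p_vl_measured_by_year", "p_cd4_measured_by_year"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class GeneratedCohort(NamedTuple):
    patients: list[PatientRecord]
    events: list[EventRecord]
    duplicates: DuplicateMap
    truth: pd.DataFrame


TRUTH_COLUMNS = [
    "patient_id", "in_scope", "success", "delay_days", "success_date",
    "retained_y1", "retained_y2", "retained_y3",
    "suppressed_y1", "suppressed_y2", "suppressed_y3",
]


def _lab_value(rng: np.random.Generator, suppressed: bool) -> float:
    if suppressed:
        return float(int(rng.uniform(20, 399)))
    return float(int(10 ** rng.uniform(2.7, 5.3)))


def generate(config: CohortGenConfig, seed: int | None = None) -> GeneratedCohort:
    """Sample a full synthetic cohort.

    ``seed`` overrides ``config.seed`` when given.  Pharmacy events are
    emitted only on visit dates (a dispensing implies a clinic contact), and
    every latent-success patient is guaranteed at least one captured
    post-transfer event so observed success matches latent success exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w0, w1 = config.study_window
    window_days = (w1 - w0).days

    patients: list[PatientRecord] = []
    events: list[EventRecord] = []
    dup_pairs: dict[str, str] = {}
    truth_rows: list[dict] = []

    for idx in range(config.n_patients):
        pid = f"P{idx:05d}"
        sex = "female" if rng.random() < config.p_female else "male"
        if rng.random() < config.p_young_transfer:
            age_tr = rng.uniform(10.0, 15.0)
        else:
            age_tr = rng.uniform(15.0, 20.0)
        tertiary = rng.random() < config.p_tertiary
        origin = (ORIGIN_TERTIARY if tertiary else ORIGIN_PRIMARY)[int(rng.integers(2))]

        years_on_art = min(max(rng.lognormal(math.log(5.0), 0.8), 0.25), age_tr - 1.0)
        age_art = age_tr - years_on_art
        enrol_gap = min(rng.exponential(0.25), max(age_art - 0.1, 0.0))
        age_enrol = age_art - enrol_gap

        transfer_out = w0 + datetime.timedelta(days=int(rng.integers(0, window_days + 1)))
        art_start = transfer_out - datetime.timedelta(days=round(years_on_art * DAYS_PER_YEAR))
        enrolment = transfer_out - datetime.timedelta(
            days=round((age_tr - age_enrol) * DAYS_PER_YEAR))

        s0 = rng.random() < config.p_suppressed_at_transfer
        vl_tr = _lab_value(rng, s0) if rng.random() < config.p_vl_at_transfer else None
        cd4_tr = float(int(rng.lognormal(math.log(636), 0.55))) if rng.random() < config.p_cd4_at_transfer else None
        cd4_art = float(int(rng.lognormal(math.log(289), 0.7)))
        cd4pct_art = round(min(rng.lognormal(math.log(12.8), 0.5), 60.0), 1)

        patients.append(PatientRecord(
            patient_id=pid, sex=sex,
            enrolment_date=enrolment, art_start_date=art_start,
            transfer_out_date=transfer_out,
            age_at_enrolment=round(age_enrol, 2),
            age_at_art_start=round(age_art, 2),
            age_at_transfer=round(age_tr, 2),
            origin_facility=origin,
            origin_level="tertiary" if tertiary else "primary",
            cd4_at_transfer=cd4_tr, vl_at_transfer=vl_tr,
            cd4_at_art_start=cd4_art, cd4pct_at_art_start=cd4pct_art,
        ))

        cov = config.source_coverage
        p_events: list[EventRecord] = []

        # sparse pre-transfer contacts at the origin facility, ending with a
        # final visit shortly before transfer-out (the last-contact anchor)
        t = transfer_out - datetime.timedelta(days=int(rng.integers(0, 46)))
        for _ in range(3):
            if t < enrolment:
                break
            if rng.random() < cov["visit"]:
                p_events.append(EventRecord(pid, origin, t, "visit"))
                if rng.random() < cov["pharmacy"]:
                    p_events.append(EventRecord(pid, origin, t, "pharmacy"))
            t = t - datetime.timedelta(days=int(rng.integers(60, 181)))
        if vl_tr is not None and rng.random() < cov["lab"]:
            d = transfer_out - datetime.timedelta(days=int(rng.integers(0, 61)))
            if d >= enrolment:
                p_events.append(EventRecord(pid, origin, d, "lab", "hiv_rna", vl_tr))

        in_scope = rng.random() >= config.p_out_of_scope
        success = bool(in_scope and rng.random() < config.p_success_given_in_scope)

        row: dict = {
            "patient_id": pid, "in_scope": in_scope, "success": success,
            "delay_days": np.nan, "success_date": "",
            "retained_y1": np.nan, "retained_y2": np.nan, "retained_y3": np.nan,
            "suppressed_y1": np.nan, "suppressed_y2": np.nan, "suppressed_y3": np.nan,
        }

        if success:
            mu = math.log(config.delay_lognormal_median_days)
            delay = max(1, round(rng.lognormal(mu, config.delay_lognormal_sigma)))
            success_date = transfer_out + datetime.timedelta(days=delay)
            dest = DESTINATIONS[int(rng.integers(len(DESTINATIONS)))]

            dropout_days = rng.exponential(DAYS_PER_YEAR / config.annual_dropout_hazard) \
                if config.annual_dropout_hazard > 0 else math.inf
            last_day = min((config.closure_date - success_date).days, dropout_days)

            # true (pre-capture) visit process at the destination clinic
            visit_offsets: list[int] = []
            off = 0.0
            while off <= last_day:
                visit_offsets.append(int(off))
                off += config.visit_interval_days * rng.uniform(0.5, 1.5)

            dest_events: list[EventRecord] = []
            for o in visit_offsets:
                d = success_date + datetime.timedelta(days=o)
                if rng.random() < cov["visit"]:
                    dest_events.append(EventRecord(pid, dest, d, "visit"))
                    if rng.random() < cov["pharmacy"]:
                        dest_events.append(EventRecord(pid, dest, d, "pharmacy"))

            # yearly laboratory monitoring while still in care
            sup = s0
            year_states: dict[int, bool] = {}
            t_year = 1
            while t_year * 365 <= last_day + 183:
                if config.suppression_markov:
                    stay = config.suppression_persistence
                    sup = rng.random() < (stay if sup else 1 - stay)
                else:
                    sup = rng.random() < config.p_suppressed
                year_states[t_year] = sup
                yi = min(t_year, 3) - 1
                anniv = t_year * 365 + int(rng.integers(-90, 91))
                if 0 < anniv <= last_day:
                    d = success_date + datetime.timedelta(days=anniv)
                    if rng.random() < config.p_vl_measured_by_year[yi] and rng.random() < cov["lab"]:
                        dest_events.append(EventRecord(pid, dest, d, "lab", "hiv_rna",
                                                       _lab_value(rng, sup)))
                    if rng.random() < config.p_cd4_measured_by_year[yi] and rng.random() < cov["lab"]:
                        cd4v = float(int(rng.lognormal(math.log(620), 0.5)))
                        dest_events.append(EventRecord(pid, dest, d, "lab", "cd4", cd4v))
                t_year += 1

            # guarantee the classifier can see the success at all
            if not dest_events:
                dest_events.append(EventRecord(pid, dest, success_date, "visit"))

            row["delay_days"] = delay
            row["success_date"] = success_date.isoformat()
            for y in (1, 2, 3):
                lo, hi = y * 365 - 183, y * 365 + 183
                row[f"retained_y{y}"] = float(any(lo <= o <= hi for o in visit_offsets))
                row[f"suppressed_y{y}"] = float(year_states[y]) if y in year_states else np.nan

            if rng.random() < config.p_duplicate_id:
                alias = pid + "B"
                dup_pairs[alias] = pid
                dest_events = [dataclasses.replace(e, patient_id=alias) for e in dest_events]
            p_events.extend(dest_events)

        truth_rows.append(row)
        events.extend(p_events)

    from .records_io import SOURCE_ORDER

    events.sort(key=lambda e: (e.patient_id, e.date, SOURCE_ORDER[e.source], e.facility, e.analyte))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return GeneratedCohort(patients, events, DuplicateMap(dup_pairs), truth)


def truth_summary(truth: pd.DataFrame) -> pd.DataFrame:
    """True proportions (with denominators) from the latent-truth table:
    success overall, linkage within 18 months, retention and suppression per
    year among successful transfers."""
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    rows = []

    def add(metric: str, mask_num: pd.Series, mask_den: pd.Series) -> None:
        n = int(mask_den.sum())
        k = int(mask_num.sum())
        rows.append({"metric": metric, "numerator": k, "denominator": n,
                     "proportion": k / n if n else np.nan})

    succ = truth["success"].astype(bool)
    add("success", succ, pd.Series(True, index=truth.index))
    add("success_within_18mo", succ & (truth["delay_days"] <= 548), succ)
    for y in (1, 2, 3):
        col = truth[f"retained_y{y}"]
        add(f"retained_y{y}", succ & (col == 1.0), succ & col.notna())
        sup = truth[f"suppressed_y{y}"]
        add(f"suppressed_y{y}", succ & (sup == 1.0), succ & sup.notna())
    return pd.DataFrame(rows)


def generate_to_dir(config: CohortGenConfig, outdir: str | Path, seed: int | None = None) -> GeneratedCohort:
    """Generate and write patients.csv, events.csv, duplicates.csv, truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gc = generate(config, seed=seed)
    write_cohort(gc.patients, outdir / "patients.csv")
    write_events(gc.events, outdir / "events.csv")
    write_duplicates(gc.duplicates, outdir / "duplicates.csv")
    gc.truth.to_csv(outdir / "truth.csv", index=False)
    return gc
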