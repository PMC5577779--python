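"""Transfer-success classification and windowed outcome ascertainment.

The primary outcome is *successful transfer*: existence of any record
(visit, laboratory test or pharmacy dispensing) at a facility other than the
origin facility, dated strictly after the transfer-out date.  From the first
such record (the *linkage event*) we derive two delay measures:

* ``delay_from_transfer_days`` — days from the transfer-out date to the
  linkage event;
* ``delay_from_last_contact_days`` — days from the last contact at the
  origin facility on or before the transfer-out date (falling back to the
  transfer-out date when no such contact is captured) to the linkage event.

Secondary outcomes are assessed per year t in {1, 2, 3} after the successful
transfer date, restricted to patients with at least t + 0.5 years of
potential follow-up before database closure:

* *retained* — at least one visit within +/-6 months (183 days, closed
  interval) of successful-transfer date + t*365 days;
* HIV-RNA and CD4 at year t — the measurement closest to the anniversary
  within the same +/-183-day window (equidistant tie -> earlier date), with
  suppression (<400 copies/ml) and CD4 recovery (>500 cells/ul) flags.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records_io import (
    DAYS_PER_YEAR,
    SOURCE_ORDER,
    AnalysisConfig,
    DuplicateMap,
    EventRecord,
    PatientRecord,
    resolve_duplicates,
)

YEARS = (1, 2, 3)

MISSING_VL_CATEGORIES = (
    "later_suppressed",
    "previously_continuously_suppressed",
    "later_unsuppressed",
    "no_evidence",
)


@dataclass(frozen=True)
class TransferOutcome:
    """Per-patient transfer classification."""

    patient_id: str
    success: bool
    linkage_event: EventRecord | None = None
    success_date: datetime.date | None = None
    delay_from_transfer_days: int | None = None
    delay_from_last_contact_days: int | None = None
    within_18_months: bool | None = None


@dataclass(frozen=True)
class TimepointAssessment:
    """Per patient x year retention and laboratory outcomes.

    ``retained`` (and everything downstream of it) is defined only for
    eligible patients; lab fields only where a measurement fell in-window.
    """

    patient_id: str
    year: int
    eligible: bool
    retained: bool | None = None
    vl_measurement: EventRecord | None = None
    cd4_measurement: EventRecord | None = None
    vl_suppressed: bool | None = None
    cd4_above_500: bool | None = None


def _qualifies(ev: EventRecord, patient: PatientRecord, config: AnalysisConfig) -> bool:
    if ev.facility == patient.origin_facility:
        return False
    if config.same_day_qualifies:
        return ev.date >= patient.transfer_out_date
    return ev.date > patient.transfer_out_date


def classify_transfer(
    patient: PatientRecord,
    events: Sequence[EventRecord],
    config: AnalysisConfig,
) -> TransferOutcome:
    """Classify one patient's transfer from their canonical event stream.

    Only events in ``config.source_subset`` are considered.  The linkage
    event is the earliest qualifying record; ties on date are broken by
    source (visit < lab < pharmacy) then facility name.  No events at all is
    an ordinary failure, not an error.
    """
    subset = set(config.source_subset)
    evs = [e for e in events if e.patient_id == patient.patient_id and e.source in subset]

    linkage = None
    for ev in sorted(evs, key=lambda e: (e.date, SOURCE_ORDER[e.source], e.facility)):
        if _qualifies(ev, patient, config):
            linkage = ev
            break
    if linkage is None:
        return TransferOutcome(patient_id=patient.patient_id, success=False)

    # anchor for the second delay definition: last captured contact at the
    # origin facility on or before transfer-out, within the active subset
    origin_dates = [e.date for e in evs
                    if e.facility == patient.origin_facility and e.date <= patient.transfer_out_date]
    anchor = max(origin_dates) if origin_dates else patient.transfer_out_date

    delay = (linkage.date - patient.transfer_out_date).days
    return TransferOutcome(
        patient_id=patient.patient_id,
        success=True,
        linkage_event=linkage,
        success_date=linkage.date,
        delay_from_transfer_days=delay,
        delay_from_last_contact_days=(linkage.date - anchor).days,
        within_18_months=delay <= config.months18_days,
    )


def is_eligible(success_date: datetime.date, year: int, config: AnalysisConfig) -> bool:
    """Sufficient potential follow-up: at least year + 0.5 years between the
    successful-transfer date and database closure."""
    needed = datetime.timedelta(days=(year + 0.5) * DAYS_PER_YEAR)
    return success_date + needed <= config.closure_date


def assess_retention(
    patient: PatientRecord,
    outcome: TransferOutcome,
    events: Sequence[EventRecord],
    year: int,
    config: AnalysisConfig,
) -> TimepointAssessment:
    """Retention at year ``year`` for a successfully transferred patient.

    Retained means >=1 visit-stream event inside the closed window
    [anniversary - 183, anniversary + 183]; visits at the origin facility are
    excluded unless ``config.retention_includes_origin``.
    """
    if year not in YEARS:
        raise ValueError(f"year must be one of {YEARS}, got {year}")
    if not outcome.success or outcome.success_date is None:
        raise ValueError("retention is assessed only for successful transfers")

    if not is_eligible(outcome.success_date, year, config):
        return TimepointAssessment(patient_id=patient.patient_id, year=year, eligible=False)

    target = outcome.success_date + datetime.timedelta(days=year * config.year_days)
    half = datetime.timedelta(days=config.window_halfwidth_days)
    lo, hi = target - half, target + half
    retained = any(
        e.source == "visit"
        and lo <= e.date <= hi
        and (config.retention_includes_origin or e.facility != patient.origin_facility)
        for e in events
        if e.patient_id == patient.patient_id
    )
    return TimepointAssessment(patient_id=patient.patient_id, year=year,
                               eligible=True, retained=retained)


def select_lab(
    patient: PatientRecord,
    outcome: TransferOutcome,
    events: Sequence[EventRecord],
    analyte: str,
    year: int,
    config: AnalysisConfig,
) -> EventRecord | None:
    """The measurement of ``analyte`` closest to the year-``year`` anniversary
    of successful transfer, within +/-183 days; equidistant tie -> earlier
    date; None when no measurement falls in the window."""
    if analyte not in ("hiv_rna", "cd4"):
        raise ValueError(f"analyte must be 'hiv_rna' or 'cd4', got {analyte!r}")
    if year not in YEARS:
        raise ValueError(f"year must be one of {YEARS}, got {year}")
    if not outcome.success or outcome.success_date is None:
        raise ValueError("lab selection applies only to successful transfers")

    target = outcome.success_date + datetime.timedelta(days=year * config.year_days)
    half = config.window_halfwidth_days
    best: EventRecord | None = None
    best_key: tuple[int, datetime.date] | None = None
    for ev in events:
        if ev.patient_id != patient.patient_id or ev.source != "lab" or ev.analyte != analyte:
            continue
        dist = abs((ev.date - target).days)
        if dist > half:
            continue
        key = (dist, ev.date)  # equidistant tie broken toward the earlier date
        if best_key is None or key < best_key:
            best, best_key = ev, key
    return best


def flag_suppressed(value: float, config: AnalysisConfig) -> bool:
    """HIV-RNA below the suppression threshold (default <400 copies/ml)."""
    return value < config.suppression_threshold


def flag_cd4_above(value: float, config: AnalysisConfig) -> bool:
    """CD4 above the recovery threshold (default >500 cells/ul, strict)."""
    if config.cd4_threshold_inclusive:
        return value >= config.cd4_threshold
    return value > config.cd4_threshold


def assess_timepoint(
    patient: PatientRecord,
    outcome: TransferOutcome,
    events: Sequence[EventRecord],
    year: int,
    config: AnalysisConfig,
) -> TimepointAssessment:
    """Retention plus selected HIV-RNA/CD4 measurements at one year mark."""
    base = assess_retention(patient, outcome, events, year, config)
    if not base.eligible:
        return base
    vl = select_lab(patient, outcome, events, "hiv_rna", year, config)
    cd4 = select_lab(patient, outcome, events, "cd4", year, config)
    return TimepointAssessment(
        patient_id=patient.patient_id,
        year=year,
        eligible=True,
        retained=base.retained,
        vl_measurement=vl,
        cd4_measurement=cd4,
        vl_suppressed=None if vl is None else flag_suppressed(vl.value, config),
        cd4_above_500=None if cd4 is None else flag_cd4_above(cd4.value, config),
    )


def classify_missing_vl(
    patient: PatientRecord,
    outcome: TransferOutcome,
    events: Sequence[EventRecord],
    year3_assessment: TimepointAssessment,
    config: AnalysisConfig,
) -> str:
    """Categorize a patient retained at year 3 but with no in-window HIV-RNA.

    Priority order:

    1. ``later_suppressed`` — a suppressed measurement shortly after the
       window (within ``missing_vl_grace_days`` of window end);
    2. ``previously_continuously_suppressed`` — >=1 post-transfer HIV-RNA
       before the window end, all suppressed;
    3. ``later_unsuppressed`` — an unsuppressed measurement after the window;
    4. ``no_evidence`` — otherwise.
    """
    if year3_assessment.year != 3:
        raise ValueError("classification applies to the year-3 assessment")
    if year3_assessment.vl_measurement is not None:
        raise ValueError("patient has a year-3 HIV-RNA measurement")
    if not outcome.success or outcome.success_date is None:
        raise ValueError("classification applies only to successful transfers")

    window_end = outcome.success_date + datetime.timedelta(
        days=3 * config.year_days + config.window_halfwidth_days)
    grace_end = window_end + datetime.timedelta(days=config.missing_vl_grace_days)

    vls = sorted(
        (e for e in events
         if e.patient_id == patient.patient_id and e.source == "lab" and e.analyte == "hiv_rna"),
        key=lambda e: e.date,
    )
    shortly_after = [e for e in vls if window_end < e.date <= grace_end]
    if any(flag_suppressed(e.value, config) for e in shortly_after):
        return "later_suppressed"
    prior = [e for e in vls if outcome.success_date < e.date <= window_end]
    if prior and all(flag_suppressed(e.value, config) for e in prior):
        return "previously_continuously_suppressed"
    later = [e for e in vls if e.date > window_end]
    if any(not flag_suppressed(e.value, config) for e in later):
        return "later_unsuppressed"
    return "no_evidence"


def classify_perinatal(patient: PatientRecord, config: AnalysisConfig) -> bool:
    """Perinatal-infection proxy: enrolment in HIV care before the cutoff age
    (default 13 years; sensitivity alternative 10)."""
    return patient.age_at_enrolment < config.perinatal_cutoff_years


def age_group(patient: PatientRecord, config: AnalysisConfig) -> str:
    """Age band at transfer: '10-14' below the split (default 15), else '15-19'."""
    if patient.age_at_transfer < config.adolescent_age_split_years:
        return "10-14"
    return "15-19"


# ---------------------------------------------------------------------------
# whole-cohort driver


def run_pipeline(
    patients: Sequence[PatientRecord],
    events: Sequence[EventRecord],
    duplicate_map: DuplicateMap | None,
    config: AnalysisConfig,
) -> tuple[dict[str, TransferOutcome], dict[str, dict[int, TimepointAssessment]]]:
    """Canonicalize identifiers, then classify every patient and assess every
    year mark.  Returns outcomes and assessments keyed by patient identifier."""
    if duplicate_map is not None:
        events = resolve_duplicates(events, duplicate_map)
    groups: dict[str, list[EventRecord]] = {}
    for ev in events:
        groups.setdefault(ev.patient_id, []).append(ev)

    outcomes: dict[str, TransferOutcome] = {}
    assessments: dict[str, dict[int, TimepointAssessment]] = {}
    for p in patients:
        evs = groups.get(p.patient_id, [])
        oc = classify_transfer(p, evs, config)
        outcomes[p.patient_id] = oc
        if oc.success:
            assessments[p.patient_id] = {
                y: assess_timepoint(p, oc, evs, y, config) for y in YEARS
            }
    return outcomes, assessments


def outcomes_frame(
    patients: Sequence[PatientRecord],
    outcomes: dict[str, TransferOutcome],
    assessments: dict[str, dict[int, TimepointAssessment]],
) -> pd.DataFrame:
    """Long-format per-patient results: one 'transfer' row per patient plus
    one row per assessed year, suitable for outcomes.csv."""
    rows = []
    for p in patients:
        oc = outcomes[p.patient_id]
        rows.append({
            "patient_id": p.patient_id,
            "row_type": "transfer",
            "year": pd.NA,
            "success": oc.success,
            "success_date": oc.success_date.isoformat() if oc.success_date else pd.NA,
            "linkage_facility": oc.linkage_event.facility if oc.linkage_event else pd.NA,
            "linkage_source": oc.linkage_event.source if oc.linkage_event else pd.NA,
            "delay_from_transfer_days": oc.delay_from_transfer_days,
            "delay_from_last_contact_days": oc.delay_from_last_contact_days,
            "within_18_months": oc.within_18_months,
        })
        for y, a in sorted(assessments.get(p.patient_id, {}).items()):
            rows.append({
                "patient_id": p.patient_id,
                "row_type": "year",
                "year": y,
                "eligible": a.eligible,
                "retained": a.retained,
                "vl_value": a.vl_measurement.value if a.vl_measurement else pd.NA,
                "vl_date": a.vl_measurement.date.isoformat() if a.vl_measurement else pd.NA,
                "cd4_value": a.cd4_measurement.value if a.cd4_measurement else pd.NA,
                "cd4_date": a.cd4_measurement.date.isoformat() if a.cd4_measurement else pd.NA,
                "vl_suppressed": a.vl_suppressed,
                "cd4_above_500": a.cd4_above_500,
            })
    return pd.DataFrame(rows)
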