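"""Independent brute-force oracles for the ascertainment classifiers.

Deliberately written as plain exhaustive scans over the event list, kept
separate from the library implementations they check.
"""

import datetime

SOURCE_RANK = {"visit": 0, "lab": 1, "pharmacy": 2}


def brute_force_linkage(patient, events, config):
    """Earliest qualifying record by exhaustive comparison of every pair."""
    candidates = []
    for e in events:
        if e.patient_id != patient.patient_id or e.source not in config.source_subset:
            continue
        if e.facility == patient.origin_facility:
            continue
        after = (e.date >= patient.transfer_out_date if config.same_day_qualifies
                 else e.date > patient.transfer_out_date)
        if after:
            candidates.append(e)
    best = None
    for c in candidates:
        if best is None:
            best = c
            continue
        key_c = (c.date, SOURCE_RANK[c.source], c.facility)
        key_b = (best.date, SOURCE_RANK[best.source], best.facility)
        if key_c < key_b:
            best = c
    return best


def brute_force_retained(patient, success_date, events, year, config):
    """Exhaustive interval-membership check over every event."""
    target = success_date + datetime.timedelta(days=year * config.year_days)
    for e in events:
        if e.patient_id != patient.patient_id or e.source != "visit":
            continue
        if not config.retention_includes_origin and e.facility == patient.origin_facility:
            continue
        if abs((e.date - target).days) <= config.window_halfwidth_days:
            return True
    return False


def brute_force_select(patient, success_date, events, analyte, year, config):
    """Argmin over in-window candidates, earlier date on equidistant ties."""
    target = success_date + datetime.timedelta(days=year * config.year_days)
    best = None
    for e in events:
        if e.patient_id != patient.patient_id or e.source != "lab" or e.analyte != analyte:
            continue
        if abs((e.date - target).days) > config.window_halfwidth_days:
            continue
        if best is None:
            best = e
        else:
            db, de = abs((best.date - target).days), abs((e.date - target).days)
            if de < db or (de == db and e.date < best.date):
                best = e
    return best
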