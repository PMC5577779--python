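"""Descriptive tables, exact intervals and tests, the transfer-success
logistic model, and report generation.

Statistical conventions
-----------------------
* Binomial proportions get exact Clopper-Pearson 95% intervals.
* Within-patient comparisons of suppression at transfer vs. a later year use
  the exact McNemar test (two-sided binomial with p=1/2 on the discordant
  pairs); CD4 medians use the Wilcoxon signed-rank test (exact for n <= 25
  without ties, otherwise normal approximation with Pratt zero handling).
* Between-age-group comparisons use Pearson chi-square on the 2x2 table
  without continuity correction.
* Predictors of successful transfer: maximum-likelihood logistic regression,
  complete case on the five a-priori covariates (perinatal-infection proxy,
  sex, age band at transfer, virologic suppression at transfer, origin care
  level), with Wald 95% CIs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .ascertainment import (
    TimepointAssessment,
    TransferOutcome,
    YEARS,
    age_group,
    classify_perinatal,
    flag_cd4_above,
    flag_suppressed,
)
from .records_io import DAYS_PER_YEAR, AnalysisConfig, PatientRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# intervals and tests


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its exact 95% interval, on the % scale."""

    numerator: int
    denominator: int
    point: float
    lower: float
    upper: float


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> ProportionCI:
    """Exact (Clopper-Pearson) interval for a binomial proportion, in %."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"numerator {k} outside [0, {n}]")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return ProportionCI(k, n, 100.0 * k / n, 100.0 * lo, 100.0 * hi)


def mcnemar_exact(n_only_before: int, n_only_after: int) -> float:
    """Exact McNemar p-value from the two discordant counts.

    Two-sided binomial test with p = 1/2 on the smaller discordant count;
    no discordant pairs -> p = 1.
    """
    if n_only_before < 0 or n_only_after < 0:
        raise ValueError("discordant counts must be non-negative")
    m = n_only_before + n_only_after
    if m == 0:
        return 1.0
    return float(st.binomtest(min(n_only_before, n_only_after), m, 0.5).pvalue)


def paired_proportion_test(before: Sequence[bool], after: Sequence[bool]) -> float:
    """Exact McNemar test for paired binary outcomes (e.g. suppression at
    transfer vs. at year t, limited to patients measured at both points)."""
    b = np.asarray(before, dtype=bool)
    a = np.asarray(after, dtype=bool)
    if b.shape != a.shape:
        raise ValueError("paired sequences must have equal length")
    return mcnemar_exact(int(np.sum(b & ~a)), int(np.sum(~b & a)))


def paired_median_test(before: Sequence[float], after: Sequence[float],
                       exact_max_n: int = 25) -> float:
    """Wilcoxon signed-rank p-value for paired continuous values.

    Exact null distribution when there are at most ``exact_max_n`` non-zero
    differences and no tied absolute differences; otherwise the normal
    approximation with Pratt handling of zeros.  All-zero differences give
    p = 1 (no evidence of a shift).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired sequences must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    if nz.size <= exact_max_n and np.unique(np.abs(nz)).size == nz.size:
        return float(st.wilcoxon(nz, method="exact").pvalue)
    return float(st.wilcoxon(d, zero_method="pratt", method="approx", correction=False).pvalue)


def group_compare(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) comparing two binomial
    proportions; returns (statistic, p).  A degenerate margin (all successes
    or all failures pooled) has statistic 0 and p = 1."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n or n <= 0:
            raise ValueError("invalid 2x2 cell counts")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = st.chi2_contingency(table, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# logistic model of successful transfer


@dataclass(frozen=True)
class AdjustedORRow:
    covariate: str
    level: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation_flag: bool = False


_MODEL_TERMS = [
    ("female", "Sex", "Female", "Male"),
    ("primary", "Original cohort", "Primary care", "Tertiary care"),
    ("vl_suppressed", "VL at transfer", "<400 copies/ml", ">=400 copies/ml"),
    ("perinatal", "Age at enrolment", "<13 years", ">=13 years"),
]


def fit_success_model(
    patients: Sequence[PatientRecord],
    outcomes: Mapping[str, TransferOutcome],
    config: AnalysisConfig,
    age_coding: str = "binary",
) -> list[AdjustedORRow]:
    """Adjusted odds ratios for successful transfer.

    Complete-case on HIV-RNA at transfer (the only a-priori covariate with
    missingness).  ``age_coding`` selects the age-at-transfer term: "binary"
    contrasts 15-19 vs 10-14 years; "continuous" is a per-year effect.
    Quasi-separated covariates are flagged rather than silently reported.
    """
    if age_coding not in ("binary", "continuous"):
        raise ValueError("age_coding must be 'binary' or 'continuous'")
    rows = []
    for p in patients:
        if p.vl_at_transfer is None:
            continue
        rows.append({
            "success": int(outcomes[p.patient_id].success),
            "female": int(p.sex == "female"),
            "primary": int(p.origin_level == "primary"),
            "vl_suppressed": int(flag_suppressed(p.vl_at_transfer, config)),
            "perinatal": int(classify_perinatal(p, config)),
            "older": int(age_group(p, config) == "15-19"),
            "age_years": p.age_at_transfer,
        })
    df = pd.DataFrame(rows)
    if len(df) < 10:
        raise ValueError(f"too few complete cases ({len(df)}) to fit the model")

    age_col = "older" if age_coding == "binary" else "age_years"
    cols = [t[0] for t in _MODEL_TERMS] + [age_col]
    X = sm.add_constant(df[cols].astype(float))
    y = df["success"].astype(float)

    separated = False
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
        res = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=0)

    params, bse, pvals = res.params, res.bse, res.pvalues
    conf = res.conf_int()
    terms = list(_MODEL_TERMS)
    if age_coding == "binary":
        terms.append(("older", "Age at transfer", "15-19 years", "10-14 years"))
    else:
        terms.append(("age_years", "Age at transfer", "per additional year", "-"))

    out = []
    for col, covariate, level, ref in terms:
        flag = not np.isfinite(bse[col]) or bse[col] > 50 or abs(params[col]) > 10
        flag = flag or (separated and bse[col] > 5)
        if flag:
            logger.warning("possible separation in covariate %r (coef %.3g, se %.3g)",
                           col, params[col], bse[col])
        out.append(AdjustedORRow(
            covariate=covariate, level=level, reference=ref,
            odds_ratio=float(np.exp(params[col])),
            ci_low=float(np.exp(conf.loc[col, 0])),
            ci_high=float(np.exp(conf.loc[col, 1])),
            p_value=float(pvals[col]),
            separation_flag=bool(flag),
        ))
    return out


def model_frame(rows: Sequence[AdjustedORRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# descriptive tables


def _median_iqr(values: list[float]) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def build_table1(
    patients: Sequence[PatientRecord],
    outcomes: Mapping[str, TransferOutcome],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Characteristics at transfer, stratified by transfer success.

    Long format: one row per variable x level x stratum with numerator /
    denominator / % for categorical rows and median / Q1 / Q3 for
    continuous rows, so every printed percentage is recomputable.
    """
    strata = {
        "transferred": [p for p in patients if outcomes[p.patient_id].success],
        "not_transferred": [p for p in patients if not outcomes[p.patient_id].success],
        "all": list(patients),
    }
    rows: list[dict] = []

    def cat(variable: str, level: str, pred) -> None:
        for name, group in strata.items():
            vals = [pred(p) for p in group]
            vals = [v for v in vals if v is not None]
            n = len(vals)
            k = sum(vals)
            rows.append({"variable": variable, "level": level, "stratum": name,
                         "numerator": k, "denominator": n,
                         "pct": 100.0 * k / n if n else np.nan})

    def cont(variable: str, getter) -> None:
        for name, group in strata.items():
            vals = [getter(p) for p in group]
            vals = [v for v in vals if v is not None]
            if vals:
                med, q1, q3 = _median_iqr(vals)
            else:
                med = q1 = q3 = np.nan
            rows.append({"variable": variable, "level": "median_iqr", "stratum": name,
                         "denominator": len(vals), "median": med, "q1": q1, "q3": q3})

    split = config.adolescent_age_split_years
    cut = config.perinatal_cutoff_years
    cat("n", "patients", lambda p: True)
    cat("sex", "male", lambda p: p.sex == "male")
    cat("sex", "female", lambda p: p.sex == "female")
    cat("age_at_enrolment", f"<{cut:g} years", lambda p: p.age_at_enrolment < cut)
    cat("age_at_enrolment", f">={cut:g} years", lambda p: p.age_at_enrolment >= cut)
    cat("age_at_transfer", f"<{split:g} years", lambda p: p.age_at_transfer < split)
    cat("age_at_transfer", f"{split:g}-19 years", lambda p: p.age_at_transfer >= split)
    cat("origin_level", "primary", lambda p: p.origin_level == "primary")
    cat("origin_level", "tertiary", lambda p: p.origin_level == "tertiary")
    cat("vl_at_transfer", f"<{config.suppression_threshold:g} copies/ml",
        lambda p: None if p.vl_at_transfer is None else flag_suppressed(p.vl_at_transfer, config))
    cat("cd4_at_transfer", f">{config.cd4_threshold:g} cells/ul",
        lambda p: None if p.cd4_at_transfer is None else flag_cd4_above(p.cd4_at_transfer, config))
    cont("age_at_art_start_years", lambda p: p.age_at_art_start)
    cont("cd4_at_art_start", lambda p: p.cd4_at_art_start)
    cont("cd4pct_at_art_start", lambda p: p.cd4pct_at_art_start)
    cont("age_at_transfer_years", lambda p: p.age_at_transfer)
    cont("years_on_art_at_transfer",
         lambda p: (p.transfer_out_date - p.art_start_date).days / DAYS_PER_YEAR)
    cont("cd4_at_transfer_cells", lambda p: p.cd4_at_transfer)
    return pd.DataFrame(rows)


_FIG2_METRICS = (
    "retained",
    "vl_suppressed_of_assessed",
    "vl_suppressed_of_retained",
    "cd4_above_of_assessed",
    "cd4_above_of_retained",
    "vl_missing_of_retained",
    "cd4_missing_of_retained",
)


def build_figure2(
    patients: Sequence[PatientRecord],
    assessments: Mapping[str, Mapping[int, TimepointAssessment]],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Retention and laboratory outcomes per year overall and by age band.

    Every percentage carries its numerator and denominator.  Laboratory
    percentages are emitted against both candidate denominators (patients
    assessed, i.e. with an in-window measurement, and all retained
    patients); missingness is among retained.  ``chi2_p`` compares the two
    age bands for each metric x year.
    """
    by_group: dict[str, list[PatientRecord]] = {"all": [], "10-14": [], "15-19": []}
    for p in patients:
        if p.patient_id not in assessments:
            continue
        by_group["all"].append(p)
        by_group[age_group(p, config)].append(p)

    def counts(group: list[PatientRecord], year: int, metric: str) -> tuple[int, int]:
        elig = [assessments[p.patient_id][year] for p in group
                if assessments[p.patient_id][year].eligible]
        retained = [a for a in elig if a.retained]
        if metric == "retained":
            return sum(1 for a in elig if a.retained), len(elig)
        vl_assessed = [a for a in retained if a.vl_measurement is not None]
        cd4_assessed = [a for a in retained if a.cd4_measurement is not None]
        if metric == "vl_suppressed_of_assessed":
            return sum(1 for a in vl_assessed if a.vl_suppressed), len(vl_assessed)
        if metric == "vl_suppressed_of_retained":
            return sum(1 for a in vl_assessed if a.vl_suppressed), len(retained)
        if metric == "cd4_above_of_assessed":
            return sum(1 for a in cd4_assessed if a.cd4_above_500), len(cd4_assessed)
        if metric == "cd4_above_of_retained":
            return sum(1 for a in cd4_assessed if a.cd4_above_500), len(retained)
        if metric == "vl_missing_of_retained":
            return len(retained) - len(vl_assessed), len(retained)
        if metric == "cd4_missing_of_retained":
            return len(retained) - len(cd4_assessed), len(retained)
        raise ValueError(metric)

    rows = []
    for year in YEARS:
        for metric in _FIG2_METRICS:
            k_y, n_y = counts(by_group["10-14"], year, metric)
            k_o, n_o = counts(by_group["15-19"], year, metric)
            if n_y and n_o:
                _, p_between = group_compare(k_y, n_y, k_o, n_o)
            else:
                p_between = np.nan
            for group in ("all", "10-14", "15-19"):
                k, n = counts(by_group[group], year, metric)
                rows.append({
                    "year": year, "metric": metric, "group": group,
                    "numerator": k, "denominator": n,
                    "pct": 100.0 * k / n if n else np.nan,
                    "chi2_p": p_between,
                })
    return pd.DataFrame(rows)


def paired_outcome_tests(
    patients: Sequence[PatientRecord],
    assessments: Mapping[str, Mapping[int, TimepointAssessment]],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """At-transfer vs. year-t paired comparisons among retained patients with
    measurements at both points: exact McNemar for suppression, Wilcoxon
    signed-rank for median CD4."""
    rows = []
    pmap = {p.patient_id: p for p in patients}
    for year in YEARS:
        vl_pairs: list[tuple[bool, bool]] = []
        cd4_pairs: list[tuple[float, float]] = []
        for pid, yearly in assessments.items():
            a = yearly.get(year)
            if a is None or not a.eligible or not a.retained:
                continue
            p = pmap[pid]
            if p.vl_at_transfer is not None and a.vl_measurement is not None:
                vl_pairs.append((flag_suppressed(p.vl_at_transfer, config), a.vl_suppressed))
            if p.cd4_at_transfer is not None and a.cd4_measurement is not None:
                cd4_pairs.append((p.cd4_at_transfer, a.cd4_measurement.value))
        if vl_pairs:
            before, after = zip(*vl_pairs)
            rows.append({
                "year": year, "outcome": "vl_suppressed", "n_pairs": len(vl_pairs),
                "value_at_transfer": 100.0 * sum(before) / len(before),
                "value_at_year": 100.0 * sum(after) / len(after),
                "p_value": paired_proportion_test(before, after),
            })
        if cd4_pairs:
            before, after = zip(*cd4_pairs)
            rows.append({
                "year": year, "outcome": "cd4_median", "n_pairs": len(cd4_pairs),
                "value_at_transfer": float(np.median(before)),
                "value_at_year": float(np.median(after)),
                "p_value": paired_median_test(before, after),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for report tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def df_to_markdown(df: pd.DataFrame, ndigits: int = 1) -> str:
    """Minimal pipe-table rendering (floats rounded half away from zero)."""

    def fmt(v: object) -> str:
        if isinstance(v, float):
            if np.isnan(v):
                return ""
            return f"{round_half_away(v, ndigits):.{ndigits}f}"
        return "" if v is pd.NA or v is None else str(v)

    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def summarize_cohort(
    patients: Sequence[PatientRecord],
    outcomes: Mapping[str, TransferOutcome],
    assessments: Mapping[str, Mapping[int, TimepointAssessment]],
    config: AnalysisConfig,
) -> dict:
    """Headline quantities with exact CIs, as a JSON-serializable dict."""
    n = len(patients)
    successes = [oc for oc in outcomes.values() if oc.success]
    k = len(successes)
    ci = proportion_ci(k, n) if n else None
    delays = sorted(oc.delay_from_transfer_days for oc in successes)
    within18 = sum(1 for oc in successes if oc.within_18_months)
    out: dict = {"n_patients": n, "n_success": k}
    if ci:
        out["success"] = dataclasses.asdict(ci)
    if successes:
        med, q1, q3 = _median_iqr(delays)
        out["delay_from_transfer_days"] = {"median": med, "q1": q1, "q3": q3}
        out["success_within_18mo"] = dataclasses.asdict(proportion_ci(within18, k))
    for year in YEARS:
        elig = [a[year] for a in assessments.values() if a[year].eligible]
        if elig:
            kk = sum(1 for a in elig if a.retained)
            out[f"retained_year{year}"] = dataclasses.asdict(proportion_ci(kk, len(elig)))
            logger.info("year %d retention denominator: %d eligible of %d successes",
                        year, len(elig), k)
    return out


def build_report(
    patients: Sequence[PatientRecord],
    outcomes: Mapping[str, TransferOutcome],
    assessments: Mapping[str, Mapping[int, TimepointAssessment]],
    source_rows: pd.DataFrame | None,
    config: AnalysisConfig,
    outdir: str | Path,
    fmt: str = "csv",
) -> dict:
    """Write table1/table2/figure2 (and table3 when source rows are given)
    plus summary.json to ``outdir``; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {
        "table1": build_table1(patients, outcomes, config),
        "figure2": build_figure2(patients, assessments, config),
        "paired_tests": paired_outcome_tests(patients, assessments, config),
    }
    try:
        tables["table2"] = model_frame(fit_success_model(patients, outcomes, config))
    except ValueError as exc:
        logger.warning("logistic model not fitted: %s", exc)
    if source_rows is not None:
        tables["table3"] = source_rows

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
        if fmt == "markdown":
            (outdir / f"{name}.md").write_text(df_to_markdown(df))

    summary = summarize_cohort(patients, outcomes, assessments, config)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def plot_figure2(figure2: pd.DataFrame, path: str | Path, group: str = "all") -> None:
    """Convenience bar plot of retention/suppression/CD4 percentages by year."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["retained", "vl_suppressed_of_assessed", "cd4_above_of_assessed"]
    sub = figure2[(figure2["group"] == group) & figure2["metric"].isin(metrics)]
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.25
    years = sorted(sub["year"].unique())
    for i, metric in enumerate(metrics):
        vals = [sub[(sub.year == y) & (sub.metric == metric)]["pct"].iloc[0] for y in years]
        ax.bar([y + (i - 1) * width for y in years], vals, width, label=metric)
    ax.set_xlabel("years after successful transfer")
    ax.set_ylabel("%")
    ax.set_xticks(years)
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
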