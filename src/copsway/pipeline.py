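"""Full study analysis: reliability, validity, responsiveness, condition
effects, heel distance and demographic screens.

The pipeline consumes a long-format trial table (one row per subject x
session x condition x trial, with the nine COP parameters, clinical scale
scores and heel distance) and emits the study's analysis tables:

* per-condition coefficient-of-variation table (within-session test-retest
  repeatability over the repeated trials);
* per-condition ICC(3,1)/SEM/MDC95/%MDC table over the first pair of
  consecutive sessions no more than ``max_gap_days`` apart (intrarater
  across-session reliability), plus the same bundle for the clinical
  scales;
* per-condition Spearman validity correlations of every parameter against
  BBS, Tinetti (total, equilibrium, locomotion) and WISCI, with a
  criterion-validity flag for |r| > 0.70 against the BBS;
* per-condition responsiveness effect sizes between the paired sessions;
* a two-way vision x support ANOVA on mean velocity;
* heel-distance correlations with the scales and a per-subject
  longitudinal fit of heel distance over calendar time;
* a demographic null screen (first session only).

Every analysis keeps an exclusion ledger so that
records_in = records_used + records_excluded is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError, UndefinedStatisticError
from .metrics import METRIC_NAMES
from .psychometrics import (
    MDC95_DEFAULT_Z,
    AnovaResult,
    ReliabilityResult,
    anova_vision_support,
    coefficient_of_variation,
    correlate,
    effect_size,
    reliability_bundle,
)

__all__ = [
    "CONDITION_LABELS",
    "CV_METRICS",
    "SCALES",
    "ExclusionLog",
    "EvaluationReport",
    "normalize_condition",
    "condition_label",
    "significance_stars",
    "table_with_margins",
    "build_records",
    "session_table",
    "pair_consecutive_sessions",
    "reliability_analysis",
    "validity_analysis",
    "responsiveness_analysis",
    "condition_effects",
    "heel_distance_analysis",
    "demographic_screen",
    "evaluate_study",
]

#: condition labels in table order (support-vision, as printed in reports)
CONDITION_LABELS = ("OF-OE", "OF-CE", "CF-OE", "CF-CE")

#: parameters with a CV (mean-position X/Y excluded: their ideal mean is 0)
CV_METRICS = ("A", "L", "SA1", "SA2", "V", "V_LL", "V_AP")

SCALES = ("bbs", "ts", "ts_e", "ts_l", "wisci")

_VISION_ALIASES = {"OE": "OE", "CE": "CE"}
# FA (feet apart) / FT (feet together) are accepted aliases of OF / CF
_SUPPORT_ALIASES = {"OF": "OF", "CF": "CF", "FA": "OF", "FT": "CF"}

_REQUIRED_COLUMNS = (
    "subject_id",
    "session_index",
    "session_day",
    "vision",
    "support",
    "trial_index",
    *METRIC_NAMES,
    *SCALES,
    "heel_distance_cm",
)


def normalize_condition(vision: str, support: str) -> tuple[str, str]:
    """Canonical (vision, support) codes; accepts FA/FT support aliases."""
    v = _VISION_ALIASES.get(str(vision).upper())
    s = _SUPPORT_ALIASES.get(str(support).upper())
    if v is None or s is None:
        raise InvalidArgumentError(f"unknown condition ({vision!r}, {support!r})")
    return v, s


def condition_label(vision: str, support: str) -> str:
    v, s = normalize_condition(vision, support)
    return f"{s}-{v}"


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def table_with_margins(cells: pd.DataFrame) -> pd.DataFrame:
    """Append row_mean/row_sd columns and col_mean/col_sd rows to a
    parameter x condition cell block (margins are plain arithmetic means
    and sample SDs of the finite cells, recomputable from the block)."""
    out = cells.copy()
    out["row_mean"] = cells.mean(axis=1)
    out["row_sd"] = cells.std(axis=1, ddof=1)
    col_mean = cells.mean(axis=0)
    col_sd = cells.std(axis=0, ddof=1)
    out.loc["col_mean", cells.columns] = col_mean
    out.loc["col_sd", cells.columns] = col_sd
    return out


class ExclusionLog:
    """Per-analysis accounting of included vs excluded records."""

    def __init__(self) -> None:
        self.messages: list[str] = []
        self._counts: list[dict] = []

    def note(self, message: str) -> None:
        self.messages.append(message)

    def account(self, analysis: str, n_in: int, n_used: int, detail: str = "") -> None:
        self._counts.append(
            {
                "analysis": analysis,
                "records_in": n_in,
                "records_used": n_used,
                "records_excluded": n_in - n_used,
                "detail": detail,
            }
        )
        if n_in != n_used:
            self.messages.append(
                f"{analysis}: excluded {n_in - n_used} of {n_in} ({detail})"
            )

    def to_frame(self) -> pd.DataFrame:
        cols = ["analysis", "records_in", "records_used", "records_excluded", "detail"]
        return pd.DataFrame(self._counts, columns=cols)


@dataclass
class ConditionEffects:
    anova: AnovaResult
    mean_v_by_condition: pd.DataFrame  # columns: condition, mean_v, sd_v, n


@dataclass
class HDResults:
    scale_correlations: pd.DataFrame  # scale, spearman/pearson r and p
    per_subject: pd.DataFrame  # subject_id, n_sessions, pearson_r, slope_cm_per_day
    mean_correlation: float
    mean_slope_cm_per_day: float
    n_subjects_longitudinal: int


@dataclass
class EvaluationReport:
    """All tables of one study evaluation (analysis-table analogues)."""

    cv_table: pd.DataFrame
    reliability_table: pd.DataFrame
    scales_reliability: pd.DataFrame
    validity_table: pd.DataFrame
    validity_summary: pd.DataFrame
    responsiveness_table: pd.DataFrame
    scales_responsiveness: pd.DataFrame
    condition_effects: ConditionEffects | None
    hd_results: HDResults | None
    demographics: pd.DataFrame | None
    exclusions: ExclusionLog = field(default_factory=ExclusionLog)


# ---------------------------------------------------------------------------
# record construction


def _validate_study(study: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in study.columns]
    if missing:
        raise SchemaError(f"study table missing columns: {missing}")
    out = study.copy()
    norm = [normalize_condition(v, s) for v, s in zip(out["vision"], out["support"])]
    out["vision"] = [v for v, _ in norm]
    out["support"] = [s for _, s in norm]
    out["condition"] = [f"{s}-{v}" for v, s in norm]
    return out


def build_records(
    study: pd.DataFrame, log: ExclusionLog | None = None
) -> pd.DataFrame:
    """Trial-averaged records: one row per subject x session x condition.

    Metrics are arithmetic means over the recorded trials; a CV column is
    added for every parameter except X and Y.  Groups with fewer than two
    trials are excluded and logged.
    """
    log = log if log is not None else ExclusionLog()
    study = _validate_study(study)
    keys = ["subject_id", "session_index", "vision", "support"]
    rows = []
    n_groups = 0
    for key, g in study.groupby(keys, sort=True):
        n_groups += 1
        if len(g) < 2:
            log.note(f"record {key}: only {len(g)} trial(s), excluded")
            continue
        row = dict(zip(keys, key))
        row["condition"] = condition_label(row["vision"], row["support"])
        row["session_day"] = float(g["session_day"].iloc[0])
        row["n_trials"] = len(g)
        for m in METRIC_NAMES:
            row[m] = float(g[m].mean())
        for m in CV_METRICS:
            try:
                row[f"cv_{m}"] = coefficient_of_variation(g[m].to_numpy())
            except UndefinedStatisticError:
                row[f"cv_{m}"] = np.nan
        for sc in SCALES:
            row[sc] = float(g[sc].iloc[0])
        row["heel_distance_cm"] = float(g["heel_distance_cm"].iloc[0])
        rows.append(row)
    records = pd.DataFrame(rows)
    log.account(
        "aggregate_trials", n_groups, len(records), "groups with < 2 trials dropped"
    )
    return records


def session_table(records: pd.DataFrame) -> pd.DataFrame:
    """One row per subject x session: day, scale scores, heel distance.

    Scales are administered once per session, so the per-condition copies
    are identical; heel distance exists only for feet-apart conditions.
    """
    rows = []
    for (sid, sidx), g in records.groupby(["subject_id", "session_index"], sort=True):
        row = {
            "subject_id": sid,
            "session_index": sidx,
            "session_day": float(g["session_day"].iloc[0]),
        }
        for sc in SCALES:
            row[sc] = float(g[sc].iloc[0])
        hd = g.loc[g["support"] == "OF", "heel_distance_cm"].dropna()
        row["heel_distance_cm"] = float(hd.iloc[0]) if len(hd) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pair_consecutive_sessions(
    records: pd.DataFrame,
    max_gap_days: float = 15.0,
    log: ExclusionLog | None = None,
) -> pd.DataFrame:
    """First pair of consecutive sessions with gap <= max_gap_days per subject.

    Returns columns subject_id, session_first, session_second, gap_days;
    subjects without an eligible pair are excluded and logged.
    """
    log = log if log is not None else ExclusionLog()
    sess = (
        records[["subject_id", "session_index", "session_day"]]
        .drop_duplicates()
        .sort_values(["subject_id", "session_index"])
    )
    pairs = []
    subjects = sess["subject_id"].unique()
    for sid, g in sess.groupby("subject_id", sort=True):
        days = g["session_day"].to_numpy()
        idx = g["session_index"].to_numpy()
        found = None
        for i in range(len(idx) - 1):
            if days[i + 1] - days[i] <= max_gap_days:
                found = (idx[i], idx[i + 1], days[i + 1] - days[i])
                break
        if found is None:
            log.note(
                f"subject {sid}: no consecutive sessions within "
                f"{max_gap_days} days, excluded from paired analyses"
            )
            continue
        pairs.append(
            {
                "subject_id": sid,
                "session_first": found[0],
                "session_second": found[1],
                "gap_days": found[2],
            }
        )
    out = pd.DataFrame(
        pairs, columns=["subject_id", "session_first", "session_second", "gap_days"]
    )
    log.account(
        "pair_consecutive_sessions",
        len(subjects),
        len(out),
        f"subjects without a session pair within {max_gap_days} days",
    )
    return out


def _paired_values(
    records: pd.DataFrame, pairs: pd.DataFrame, condition: str, column: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (first, second) values of one column in one condition;
    subjects missing the condition in either session are dropped."""
    sub = records[records["condition"] == condition]
    lut = {
        (r.subject_id, r.session_index): getattr(r, column)
        for r in sub.itertuples()
    }
    first, second = [], []
    for p in pairs.itertuples():
        a = lut.get((p.subject_id, p.session_first))
        b = lut.get((p.subject_id, p.session_second))
        if a is None or b is None or np.isnan(a) or np.isnan(b):
            continue
        first.append(a)
        second.append(b)
    return np.asarray(first), np.asarray(second)


# ---------------------------------------------------------------------------
# analyses


def reliability_analysis(
    records: pd.DataFrame,
    pairs: pd.DataFrame,
    mdc_z: float = MDC95_DEFAULT_Z,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CV table, COP reliability table, and clinical-scale reliability.

    The CV table averages the within-session trial CV over every record of
    each condition.  The reliability table runs ICC(3,1)/SEM/MDC95/%MDC per
    parameter x condition on the paired sessions' trial-averaged values
    (%MDC baseline = cohort mean of the first session's values).
    """
    log = log if log is not None else ExclusionLog()

    cv_rows = []
    for m in CV_METRICS:
        row = {"parameter": m}
        for cond in CONDITION_LABELS:
            vals = records.loc[records["condition"] == cond, f"cv_{m}"].dropna()
            row[cond] = float(vals.mean()) if len(vals) else np.nan
        cv_rows.append(row)
    cv_table = pd.DataFrame(cv_rows).set_index("parameter")

    rel_rows = []
    for m in METRIC_NAMES:
        for cond in CONDITION_LABELS:
            first, second = _paired_values(records, pairs, cond, m)
            if len(first) < 3:
                log.note(
                    f"reliability {m} {cond}: only {len(first)} paired subjects, skipped"
                )
                continue
            matrix = np.column_stack([first, second])
            try:
                res = reliability_bundle(matrix, mdc_z=mdc_z)
            except UndefinedStatisticError as exc:
                log.note(f"reliability {m} {cond}: {exc}")
                continue
            rel_rows.append(_rel_row(m, cond, res))
    reliability_table = pd.DataFrame(rel_rows, columns=_REL_COLUMNS)

    sess = session_table(records)
    scale_rows = []
    for sc in SCALES:
        lut = {
            (r.subject_id, r.session_index): getattr(r, sc) for r in sess.itertuples()
        }
        first, second = [], []
        for p in pairs.itertuples():
            a = lut.get((p.subject_id, p.session_first))
            b = lut.get((p.subject_id, p.session_second))
            if a is None or b is None:
                continue
            first.append(a)
            second.append(b)
        if len(first) < 3:
            log.note(f"scale reliability {sc}: too few pairs, skipped")
            continue
        res = reliability_bundle(np.column_stack([first, second]), mdc_z=mdc_z)
        scale_rows.append(_rel_row(sc, "", res))
    scales_reliability = pd.DataFrame(scale_rows, columns=_REL_COLUMNS)
    return cv_table, reliability_table, scales_reliability


_REL_COLUMNS = (
    "parameter", "condition", "icc", "icc_ci_low", "icc_ci_high",
    "sem", "mdc95", "pct_mdc", "n_subjects",
)


def _rel_row(measure: str, condition: str, res: ReliabilityResult) -> dict:
    return {
        "parameter": measure,
        "condition": condition,
        "icc": res.icc,
        "icc_ci_low": res.icc_ci_low,
        "icc_ci_high": res.icc_ci_high,
        "sem": res.sem,
        "mdc95": res.mdc95,
        "pct_mdc": res.pct_mdc,
        "n_subjects": res.n_subjects,
    }


def validity_analysis(
    records: pd.DataFrame,
    method: str = "spearman",
    criterion_threshold: float = 0.70,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations of every parameter x condition against the five scales.

    Returns (long table, per-row summary).  The summary's mean_abs_r
    averages |r| over the scales with a defined correlation; the criterion
    flag marks |r vs BBS| > 0.70.  Raw p-values are kept and a
    Holm-adjusted column is added within each parameter x condition family.
    """
    from statsmodels.stats.multitest import multipletests

    log = log if log is not None else ExclusionLog()
    long_rows = []
    summary_rows = []
    for m in METRIC_NAMES:
        for cond in CONDITION_LABELS:
            sub = records[records["condition"] == cond]
            if len(sub) < 3:
                continue
            fam = []
            for sc in SCALES:
                try:
                    res = correlate(sub[m].to_numpy(), sub[sc].to_numpy(), method)
                    fam.append(
                        {
                            "parameter": m,
                            "condition": cond,
                            "scale": sc,
                            "r": res.coefficient,
                            "p": res.p_value,
                            "stars": significance_stars(res.p_value),
                            "munro_class": res.munro_class,
                            "n": res.n,
                        }
                    )
                except UndefinedStatisticError:
                    log.note(f"validity {m} {cond} vs {sc}: undefined (constant input)")
                    fam.append(
                        {
                            "parameter": m,
                            "condition": cond,
                            "scale": sc,
                            "r": np.nan,
                            "p": np.nan,
                            "stars": "",
                            "munro_class": "",
                            "n": len(sub),
                        }
                    )
            ps = np.array([f["p"] for f in fam])
            ok = ~np.isnan(ps)
            holm = np.full(len(ps), np.nan)
            if ok.any():
                holm[ok] = multipletests(ps[ok], method="holm")[1]
            for f, h in zip(fam, holm):
                f["p_holm"] = h
            long_rows.extend(fam)
            abs_r = np.array([abs(f["r"]) for f in fam])
            bbs_r = next(f["r"] for f in fam if f["scale"] == "bbs")
            summary_rows.append(
                {
                    "parameter": m,
                    "condition": cond,
                    "mean_abs_r": float(np.nanmean(abs_r)) if ok.any() else np.nan,
                    "criterion_validity": bool(
                        not np.isnan(bbs_r) and abs(bbs_r) > criterion_threshold
                    ),
                }
            )
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)


def responsiveness_analysis(
    records: pd.DataFrame,
    pairs: pd.DataFrame,
    log: ExclusionLog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect sizes between the paired sessions, per parameter x condition
    and per clinical scale."""
    log = log if log is not None else ExclusionLog()
    rows = []
    for m in METRIC_NAMES:
        row = {"parameter": m}
        for cond in CONDITION_LABELS:
            first, second = _paired_values(records, pairs, cond, m)
            if len(first) < 2:
                row[cond] = np.nan
                log.note(f"responsiveness {m} {cond}: too few pairs")
                continue
            try:
                row[cond] = effect_size(first, second)
            except UndefinedStatisticError:
                row[cond] = np.nan
        rows.append(row)
    es_table = pd.DataFrame(rows).set_index("parameter")

    sess = session_table(records)
    scale_rows = []
    for sc in SCALES:
        lut = {
            (r.subject_id, r.session_index): getattr(r, sc) for r in sess.itertuples()
        }
        first, second = [], []
        for p in pairs.itertuples():
            a = lut.get((p.subject_id, p.session_first))
            b = lut.get((p.subject_id, p.session_second))
            if a is not None and b is not None:
                first.append(a)
                second.append(b)
        es = np.nan
        if len(first) >= 2:
            try:
                es = effect_size(np.asarray(first), np.asarray(second))
            except UndefinedStatisticError:
                pass
        scale_rows.append({"scale": sc, "es": es, "n_subjects": len(first)})
    return es_table, pd.DataFrame(scale_rows)


def condition_effects(records: pd.DataFrame) -> ConditionEffects:
    """Two-way vision x support ANOVA on mean velocity V, plus the mean V
    per condition (direction summary)."""
    anova = anova_vision_support(
        records["V"].to_numpy(), records["vision"], records["support"]
    )
    means = (
        records.groupby("condition", sort=False)["V"]
        .agg(mean_v="mean", sd_v="std", n="count")
        .reindex([c for c in CONDITION_LABELS if c in records["condition"].unique()])
        .reset_index()
    )
    return ConditionEffects(anova=anova, mean_v_by_condition=means)


def heel_distance_analysis(
    records: pd.DataFrame, log: ExclusionLog | None = None
) -> HDResults:
    """Heel-distance (feet-apart stance width) analyses.

    Cross-sectional: HD against BBS and the Tinetti scores (Spearman and
    Pearson).  Longitudinal: per-subject Pearson correlation and
    least-squares slope of HD against calendar day for subjects with at
    least 3 HD sessions; the cohort mean correlation and mean slope
    summarise the time trend.
    """
    log = log if log is not None else ExclusionLog()
    sess = session_table(records)
    hd = sess.dropna(subset=["heel_distance_cm"])

    corr_rows = []
    for sc in ("bbs", "ts", "ts_e", "ts_l"):
        row = {"scale": sc}
        for method in ("spearman", "pearson"):
            try:
                res = correlate(
                    hd["heel_distance_cm"].to_numpy(), hd[sc].to_numpy(), method
                )
                row[f"{method}_r"], row[f"{method}_p"] = res.coefficient, res.p_value
            except (UndefinedStatisticError, InvalidArgumentError):
                row[f"{method}_r"] = row[f"{method}_p"] = np.nan
        corr_rows.append(row)

    subj_rows = []
    n_subjects_hd = hd["subject_id"].nunique()
    for sid, g in hd.groupby("subject_id", sort=True):
        if len(g) < 3:
            log.note(f"HD longitudinal: subject {sid} has {len(g)} HD sessions, skipped")
            continue
        days = g["session_day"].to_numpy()
        vals = g["heel_distance_cm"].to_numpy()
        slope = float(np.polyfit(days, vals, 1)[0])
        if np.ptp(vals) == 0:
            r = np.nan
            log.note(f"HD longitudinal: subject {sid} constant HD, correlation undefined")
        else:
            r = correlate(days, vals, "pearson").coefficient
        subj_rows.append(
            {
                "subject_id": sid,
                "n_sessions": len(g),
                "pearson_r": r,
                "slope_cm_per_day": slope,
            }
        )
    per_subject = pd.DataFrame(
        subj_rows, columns=["subject_id", "n_sessions", "pearson_r", "slope_cm_per_day"]
    )
    log.account(
        "heel_distance_longitudinal",
        n_subjects_hd,
        len(per_subject),
        "subjects with < 3 HD sessions",
    )
    mean_r = float(per_subject["pearson_r"].mean()) if len(per_subject) else np.nan
    mean_slope = (
        float(per_subject["slope_cm_per_day"].mean()) if len(per_subject) else np.nan
    )
    return HDResults(
        scale_correlations=pd.DataFrame(corr_rows),
        per_subject=per_subject,
        mean_correlation=mean_r,
        mean_slope_cm_per_day=mean_slope,
        n_subjects_longitudinal=len(per_subject),
    )


def demographic_screen(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    log: ExclusionLog | None = None,
) -> pd.DataFrame:
    """Correlations of each COP parameter against age, height, weight and
    sex, per condition, on first-session data only.

    Sex enters as a point-biserial correlation (Pearson against a 0/1
    coding); a single-sex cohort leaves it undefined and flagged.
    """
    log = log if log is not None else ExclusionLog()
    first = records.loc[
        records.groupby("subject_id")["session_index"].transform("min")
        == records["session_index"]
    ]
    merged = first.merge(subjects, on="subject_id", how="inner")
    merged = merged.assign(sex01=(merged["sex"] == "M").astype(float))
    rows = []
    for cond in CONDITION_LABELS:
        sub = merged[merged["condition"] == cond]
        if len(sub) < 3:
            continue
        for m in METRIC_NAMES:
            for cov, method in (
                ("age", "spearman"),
                ("height", "spearman"),
                ("weight", "spearman"),
                ("sex01", "pearson"),
            ):
                try:
                    res = correlate(sub[m].to_numpy(), sub[cov].to_numpy(), method)
                    r, p = res.coefficient, res.p_value
                except UndefinedStatisticError:
                    r = p = np.nan
                    if cov == "sex01":
                        log.note(f"demographics {m} {cond}: single-sex cohort, sex undefined")
                rows.append(
                    {
                        "parameter": m,
                        "condition": cond,
                        "covariate": "sex" if cov == "sex01" else cov,
                        "method": "pointbiserial" if cov == "sex01" else method,
                        "r": r,
                        "p": p,
                        "stars": significance_stars(p) if not np.isnan(p) else "",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def evaluate_study(
    study: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    mdc_z: float = MDC95_DEFAULT_Z,
    max_gap_days: float = 15.0,
    validity_method: str = "spearman",
) -> EvaluationReport:
    """Run the complete analysis on a long-format trial table.

    Deterministic: the report is a pure function of its inputs.
    """
    log = ExclusionLog()
    records = build_records(study, log)
    if records.empty:
        raise InvalidArgumentError("no usable records after trial aggregation")
    pairs = pair_consecutive_sessions(records, max_gap_days, log)

    cv_table, reliability_table, scales_reliability = reliability_analysis(
        records, pairs, mdc_z=mdc_z, log=log
    )
    validity_table, validity_summary = validity_analysis(
        records, method=validity_method, log=log
    )
    responsiveness_table, scales_responsiveness = responsiveness_analysis(
        records, pairs, log=log
    )

    effects = None
    if records["vision"].nunique() == 2 and records["support"].nunique() == 2:
        effects = condition_effects(records)
    else:
        log.note("condition_effects: needs both vision and support levels, skipped")

    hd = None
    if records["heel_distance_cm"].notna().any():
        hd = heel_distance_analysis(records, log)
    else:
        log.note("heel_distance_analysis: no HD data, skipped")

    demo = None
    if subjects is not None:
        demo = demographic_screen(records, subjects, log)

    return EvaluationReport(
        cv_table=cv_table,
        reliability_table=reliability_table,
        scales_reliability=scales_reliability,
        validity_table=validity_table,
        validity_summary=validity_summary,
        responsiveness_table=responsiveness_table,
        scales_responsiveness=scales_responsiveness,
        condition_effects=effects,
        hd_results=hd,
        demographics=demo,
        exclusions=log,
    )
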