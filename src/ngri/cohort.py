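"""From raw examination + laboratory tables to the analysis cohort.

Deterministic same-day linkage on (person_id, date), de-duplication (latest
record overall for training, one per calendar year for validation), value
sanitization ("<"/">" stripped, non-parsable or non-positive -> missing),
eligibility filtering (age 18-80, sex present, complete key variables,
normal BMI, normal blood pressure, no recorded history), and winsorization
at the 0.5th/99.5th percentiles before modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CBC_ANALYTES = ["WBC", "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "PLT"]

EXAM_COLUMNS = ["person_id", "exam_date", "age", "sex", "bmi", "sbp", "dbp", "history_flags"]
LAB_COLUMNS = ["person_id", "receipt_date"] + CBC_ANALYTES

# first-failing-criterion order for the exclusion tally
CRITERIA_ORDER = ["age", "sex", "completeness", "bmi", "bp", "history"]


@dataclass(frozen=True)
class FilterConfig:
    """Eligibility thresholds defining the presumed-healthy reference cohort.

    Defaults: age 18-80 y; normal BMI [18.5, 24.0) kg/m^2 (Chinese adult
    criteria); normotension SBP < 140 and DBP < 90 mmHg; no recorded
    disease-history flags; BMI, SBP, DBP and all CBC indices present.
    """

    age_range: tuple[int, int] = (18, 80)
    bmi_range: tuple[float, float] = (18.5, 24.0)  # [low, high)
    sbp_max: float = 140.0  # exclusive
    dbp_max: float = 90.0  # exclusive
    require_no_history: bool = True
    required_analytes: tuple[str, ...] = tuple(CBC_ANALYTES)

    def __post_init__(self) -> None:
        if self.age_range[0] > self.age_range[1] or self.bmi_range[0] >= self.bmi_range[1]:
            raise ValueError("ill-ordered filter ranges")


@dataclass(frozen=True)
class WinsorSpec:
    """Winsorization quantiles; 'linear' is numpy's type-7 interpolation rule."""

    lower_q: float = 0.005
    upper_q: float = 0.995
    quantile_rule: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.lower_q < self.upper_q < 1:
            raise ValueError("need 0 < lower_q < upper_q < 1")


def link_records(exams: pd.DataFrame, labs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Inner-join exams and labs on exact (person_id, date); tally the rest.

    Returns (linked rows, {"exam_only": n, "lab_only": n}).  Rows sharing a
    (person_id, date) key within one table are all retained here; the de-dup
    step downstream resolves them (tie-break logged there).
    """
    e = exams.copy()
    l = labs.copy()
    e["_date"] = pd.to_datetime(e["exam_date"]).dt.normalize()
    l["_date"] = pd.to_datetime(l["receipt_date"]).dt.normalize()
    merged = e.merge(l.drop(columns=["receipt_date"]), on=["person_id", "_date"], how="inner")
    exam_keys = set(zip(e["person_id"], e["_date"]))
    lab_keys = set(zip(l["person_id"], l["_date"]))
    tally = {
        "exam_only": sum(1 for k in zip(e["person_id"], e["_date"]) if k not in lab_keys),
        "lab_only": sum(1 for k in zip(l["person_id"], l["_date"]) if k not in exam_keys),
    }
    merged = merged.rename(columns={"_date": "date"}).drop(columns=["exam_date"])
    log.info("linked %d rows (%d exam-only, %d lab-only)", len(merged), tally["exam_only"], tally["lab_only"])
    return merged, tally


def dedup(records: pd.DataFrame, strategy: str = "latest_overall") -> pd.DataFrame:
    """One record per person (latest date) or per person-year (latest in year).

    Same-date ties keep the row with the larger original ordinal, so the
    result is deterministic under stable input ordering.
    """
    if strategy not in ("latest_overall", "one_per_year"):
        raise ValueError(f"unknown strategy {strategy!r}")
    df = records.copy()
    df["_ord"] = np.arange(len(df))
    df = df.sort_values(["date", "_ord"], kind="stable")
    if strategy == "latest_overall":
        keys = ["person_id"]
    else:
        df["_year"] = pd.to_datetime(df["date"]).dt.year
        keys = ["person_id", "_year"]
    n_ties = int(df.duplicated(subset=keys + ["date"], keep=False).sum())
    if n_ties:
        log.info("dedup: %d same-date duplicate rows resolved by row ordinal", n_ties)
    out = df.groupby(keys, as_index=False, sort=False).tail(1)
    out = out.sort_values("_ord", kind="stable").drop(columns=["_ord", "_year"], errors="ignore")
    return out.reset_index(drop=True)


def clean_value(raw) -> float:
    """Sanitize one raw lab value string; returns a positive float or NaN.

    Strips "<"/">" qualifiers and whitespace; anything non-parsable, zero
    or negative becomes missing.  Total function: never raises.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip().replace("<", "").replace(">", "").strip()
    try:
        v = float(s)
    except ValueError:
        return np.nan
    return v if v > 0 and np.isfinite(v) else np.nan


def clean_lab_values(records: pd.DataFrame, analytes=CBC_ANALYTES) -> pd.DataFrame:
    df = records.copy()
    for a in analytes:
        if a in df.columns:
            df[a] = df[a].map(clean_value)
    return df


def apply_eligibility(records: pd.DataFrame, config: FilterConfig = FilterConfig()) -> tuple[pd.DataFrame, dict]:
    """Keep rows passing all criteria; tally the first failing criterion.

    Criteria are checked in the fixed order age -> sex -> completeness ->
    BMI -> BP -> history, so the tally is reproducible and sums to the
    number of excluded rows.
    """
    df = records.copy()
    n = len(df)
    age = pd.to_numeric(df.get("age"), errors="coerce")
    fail_age = age.isna() | (age < config.age_range[0]) | (age > config.age_range[1])
    sex = df.get("sex", pd.Series([None] * n, index=df.index))
    fail_sex = sex.isna() | (~sex.astype(str).str.lower().isin(["female", "male", "f", "m"]))
    need = ["bmi", "sbp", "dbp"] + [a for a in config.required_analytes if a in df.columns]
    missing_any = pd.Series(False, index=df.index)
    for c in ["bmi", "sbp", "dbp"]:
        missing_any |= pd.to_numeric(df.get(c), errors="coerce").isna()
    for a in config.required_analytes:
        missing_any |= df[a].isna() if a in df.columns else True
    bmi = pd.to_numeric(df.get("bmi"), errors="coerce")
    fail_bmi = (bmi < config.bmi_range[0]) | (bmi >= config.bmi_range[1])
    sbp = pd.to_numeric(df.get("sbp"), errors="coerce")
    dbp = pd.to_numeric(df.get("dbp"), errors="coerce")
    fail_bp = (sbp >= config.sbp_max) | (dbp >= config.dbp_max)
    hist = df.get("history_flags", pd.Series([""] * n, index=df.index)).fillna("")
    fail_hist = config.require_no_history & (hist.astype(str).str.strip() != "")

    reason = pd.Series("", index=df.index)
    for name, mask in [
        ("age", fail_age),
        ("sex", fail_sex),
        ("completeness", missing_any),
        ("bmi", fail_bmi.fillna(False)),
        ("bp", fail_bp.fillna(False)),
        ("history", fail_hist),
    ]:
        reason = reason.mask((reason == "") & mask, name)
    kept = df[reason == ""].reset_index(drop=True)
    tally = {c: int((reason == c).sum()) for c in CRITERIA_ORDER}
    tally["kept"] = len(kept)
    log.info("eligibility: kept %d of %d (%s)", len(kept), n,
             ", ".join(f"{c}={tally[c]}" for c in CRITERIA_ORDER))
    return kept, tally


def winsorize(values, spec: WinsorSpec = WinsorSpec()) -> np.ndarray:
    """Clip values below/above the configured empirical percentiles.

    Missing entries pass through untouched; quantiles are computed on the
    non-missing subset with the pinned linear-interpolation rule.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("winsorize needs at least 2 non-missing values")
    q_lo, q_hi = np.quantile(finite, [spec.lower_q, spec.upper_q], method=spec.quantile_rule)
    out = arr.copy()
    mask = np.isfinite(arr)
    out[mask] = np.clip(arr[mask], q_lo, q_hi)
    return out


def build_cohort(
    exams: pd.DataFrame,
    labs: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    dedup_strategy: str = "latest_overall",
) -> tuple[pd.DataFrame, dict]:
    """Full cleaning pipeline: link -> dedup -> clean values -> eligibility."""
    linked, link_tally = link_records(exams, labs)
    deduped = dedup(linked, dedup_strategy)
    cleaned = clean_lab_values(deduped, config.required_analytes)
    kept, tally = apply_eligibility(cleaned, config)
    tally["link"] = link_tally
    tally["after_dedup"] = len(deduped)
    return kept, tally
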