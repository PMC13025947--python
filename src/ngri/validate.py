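"""Temporal validation: L/N/U classification against reference limits.

Each observation is compared with the 2.5th/97.5th percentile limits of a
reference table at its (floored, clamped) integer age: L below the lower
limit, U above the upper, N otherwise, with boundary values counted as N.
Year x sex strata summarize counts and percentages; a stratum "passes" the
stability check when L% + U% stays below a threshold (default 10%).
The z-index maps a value to a dimensionless normal-equivalent deviate
through the fitted model's CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ngri.bootstrap import ReferenceTable
from ngri.centile import CentileModel

log = logging.getLogger(__name__)

CLASSES = ["L", "N", "U"]


def classify(value: float, age: float, sex: str, table: ReferenceTable) -> str:
    """L/N/U label for one observation; boundary-equal values are N."""
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"value must be positive and finite, got {value}")
    if sex != table.sex:
        raise ValueError(f"table is for sex={table.sex!r}, record has {sex!r}")
    lower, upper = table.limits(age)
    if value < lower:
        return "L"
    if value > upper:
        return "U"
    return "N"


@dataclass
class ValidationReport:
    """Table of (year, sex, class, n, total, percent) rows plus skip count."""

    frame: pd.DataFrame
    skipped_missing: int = 0

    def percent(self, year, sex: str, cls: str) -> float:
        sub = self.frame[
            (self.frame["year"] == year) & (self.frame["sex"] == sex) & (self.frame["class"] == cls)
        ]
        return float(sub["percent"].iloc[0])


def validation_report(records: pd.DataFrame, table: ReferenceTable,
                      year_field: str = "year", value_field: str | None = None) -> ValidationReport:
    """Classify every record and tabulate counts/percentages per year x sex.

    ``records`` needs columns year, sex, age and the analyte value (column
    named by ``value_field``, defaulting to the table's analyte).  Rows with
    missing values are skipped and counted separately.  Percentages are kept
    as raw fractions internally and rounded (2 dp, half-even) for display.
    """
    value_field = value_field or table.analyte
    df = records[records["sex"] == table.sex]
    vals = pd.to_numeric(df[value_field], errors="coerce")
    ok = vals.notna() & (vals > 0)
    skipped = int((~ok).sum())
    df = df[ok]
    vals = vals[ok]
    rows = []
    jl = int(np.argmin(np.abs(table.percentiles - 0.025)))
    ju = int(np.argmin(np.abs(table.percentiles - 0.975)))
    for year, sub in df.groupby(year_field, sort=True):
        v = vals.loc[sub.index].to_numpy()
        a = np.clip(np.floor(sub["age"].to_numpy(float)), table.ages[0], table.ages[-1])
        idx = np.searchsorted(table.ages, a.astype(int))
        lower = table.point[idx, jl]
        upper = table.point[idx, ju]
        n_l = int((v < lower).sum())
        n_u = int((v > upper).sum())
        total = len(v)
        if total == 0:
            continue
        counts = {"L": n_l, "N": total - n_l - n_u, "U": n_u}
        for cls in CLASSES:
            rows.append(dict(year=year, sex=table.sex, **{"class": cls},
                             n=counts[cls], total=total,
                             percent=round(100.0 * counts[cls] / total, 2)))
    return ValidationReport(frame=pd.DataFrame(rows), skipped_missing=skipped)


def flag_rate_check(report: ValidationReport, threshold_percent: float = 10.0) -> dict:
    """Pass/fail per stratum and overall: stratum passes iff L% + U% < threshold."""
    if report.frame.empty:
        log.warning("flag_rate_check on empty report: vacuous pass")
        return {"overall": True, "strata": {}}
    strata = {}
    for (year, sex), sub in report.frame.groupby(["year", "sex"]):
        out = 100.0 * sub[sub["class"].isin(["L", "U"])]["n"].sum() / sub["total"].iloc[0]
        strata[(year, sex)] = bool(out < threshold_percent)
    return {"overall": all(strata.values()), "strata": strata}


def z_index(value, age, sex: str, model: CentileModel):
    """Dimensionless index: Phi^-1 of the model CDF at the observed value.

    Zero at the model median (lms mode); +/-1.96 at the 97.5th/2.5th
    centiles; unit-free, so comparable across analytes.
    """
    if sex != model.sex:
        raise ValueError(f"model is for sex={model.sex!r}, got {sex!r}")
    v = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("value must be positive and finite")
    mu = np.atleast_1d(model.mu(age))
    sigma = np.atleast_1d(model.sigma(age))
    nu = model.nu
    if abs(nu) < 1e-8:
        z = np.log(v / mu) / sigma
    else:
        z = (np.power(v / mu, nu) - 1.0) / (nu * sigma)
        if model.mode == "exact":
            c = stats.norm.cdf(1.0 / (sigma * abs(nu)))
            p = stats.norm.cdf(z)
            p = (p - 1.0 + c) / c if nu > 0 else p / c
            z = stats.norm.ppf(np.clip(p, 1e-300, 1 - 1e-16))
    return z if np.ndim(value) else float(z[0] if np.ndim(z) else z)
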