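"""Descriptive and comparative statistics for cohort reporting.

Median/IQR group summaries, one-sample Kolmogorov-Smirnov normality
assessment (against a normal with sample-estimated moments — conservative,
and flagged as such), Wilcoxon rank-sum comparisons, and Benjamini-Hochberg
adjustment.  All empirical quantiles use the same linear-interpolation
(type-7) rule as the rest of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

# age dichotomy used for non-elderly vs elderly group comparisons
AGE_GROUPS = {"18-59": (18, 59), "60+": (60, 200)}


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def median_iqr(values, label: str = "") -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return GroupSummary(label=label, n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS statistic and asymptotic p against N(mean, sd).

    Moments are estimated from the same sample, which makes the plain KS
    p-value conservative (the Lilliefors effect); that caveat is logged
    rather than silently corrected, matching common reporting practice.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 5:
        raise ValueError("need at least 5 observations")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    log.info("KS test with sample-estimated parameters: p-value is conservative")
    res = sps.kstest(arr, "norm", args=(arr.mean(), sd), mode="asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Mann-Whitney U (relative to x) with two-sided p.

    Exact enumeration when n_x + n_y <= 12 with no ties, otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def summary_table(cohort: pd.DataFrame, analytes, by=("sex",)) -> pd.DataFrame:
    """Median (IQR) per group and analyte — the baseline-characteristics shape."""
    rows = []
    for keys, sub in cohort.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = "/".join(str(k) for k in keys)
        for a in analytes:
            vals = pd.to_numeric(sub[a], errors="coerce").dropna()
            if vals.empty:
                continue
            s = median_iqr(vals, label=f"{label}:{a}")
            rows.append(dict(group=label, analyte=a, n=s.n, median=s.median, q1=s.q1, q3=s.q3))
    return pd.DataFrame(rows)


def group_comparisons(cohort: pd.DataFrame, analytes) -> pd.DataFrame:
    """Sex comparisons within each age band, BH-adjusted across all tests."""
    cohort = cohort.copy()
    rows = []
    for a in analytes:
        for band, (lo, hi) in AGE_GROUPS.items():
            sub = cohort[(cohort["age"] >= lo) & (cohort["age"] <= hi)]
            xf = pd.to_numeric(sub[sub["sex"] == "female"][a], errors="coerce").dropna()
            xm = pd.to_numeric(sub[sub["sex"] == "male"][a], errors="coerce").dropna()
            if xf.empty or xm.empty:
                continue
            u, p = wilcoxon_rank_sum(xf, xm)
            rows.append(dict(analyte=a, age_band=band, comparison="female_vs_male",
                             U=u, p_raw=p))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    return out
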