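"""Synthetic health-examination cohorts with known ground truth.

The study data behind continuous hematology reference intervals are not
public, so tests and calibration runs use generated stand-ins: (a) clean
model-based cohorts drawn from a declared BCCG age trend (for parameter
recovery and coverage checks), and (b) messy raw examination + laboratory
tables with planted duplicates, malformed strings and ineligible rows (to
exercise the cleaning pipeline), each carrying a ledger of the exact truth.

Default trends emulate adult red-cell counts: the female median starts near
4.50 x10^12/L at age 18, dips through the thirties and rises slightly around
the menopausal transition before declining, while the male median declines
gradually from about 5.19; the age distribution is right-skewed with median
~35 y and IQR ~30-44, mimicking a working-age health-exam population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from ngri.cohort import CBC_ANALYTES

Z975 = stats.norm.ppf(0.975)

# (age, median) control points for red-cell count, x10^12/L
_FEMALE_RBC_MEDIANS = [
    (18, 4.50), (25, 4.47), (30, 4.46), (35, 4.44), (40, 4.41), (43, 4.41),
    (46, 4.42), (50, 4.44), (55, 4.45), (60, 4.44), (65, 4.41), (70, 4.37),
    (75, 4.33), (80, 4.30),
]
_MALE_RBC_MEDIANS = [
    (18, 5.19), (25, 5.15), (30, 5.12), (35, 5.08), (40, 5.04), (45, 5.00),
    (50, 4.95), (55, 4.90), (60, 4.84), (65, 4.79), (70, 4.74), (75, 4.68),
    (80, 4.63),
]
# age-18 (Q2.5, Q50, Q97.5) anchors from which sigma and nu are solved
_RBC_ANCHORS = {"female": (3.99, 4.50, 5.10), "male": (4.65, 5.19, 5.84)}

# constant BCCG parameters for the remaining CBC indices, per sex:
# (mu, sigma, nu) in the units WBC x10^9/L, HGB g/L, HCT %, MCV fL, MCH pg,
# MCHC g/L, PLT x10^9/L
_OTHER_CBC = {
    "female": {
        "WBC": (5.8, 0.22, 0.0), "HGB": (132.0, 0.055, 0.8), "HCT": (40.0, 0.05, 0.8),
        "MCV": (90.0, 0.042, 1.0), "MCH": (30.0, 0.05, 0.8), "MCHC": (335.0, 0.02, 1.0),
        "PLT": (245.0, 0.22, 0.3),
    },
    "male": {
        "WBC": (6.1, 0.22, 0.0), "HGB": (152.0, 0.05, 0.8), "HCT": (45.0, 0.045, 0.8),
        "MCV": (90.0, 0.04, 1.0), "MCH": (30.5, 0.045, 0.8), "MCHC": (340.0, 0.02, 1.0),
        "PLT": (225.0, 0.22, 0.3),
    },
}


def solve_sigma_nu(q_lo: float, median: float, q_hi: float, z: float = Z975) -> tuple[float, float]:
    """Invert the LMS quantile formulas: find (sigma, nu) matching both
    outer quantiles given the median.

    Uses y_p = mu*(1 + nu*sigma*z_p)^(1/nu); symmetric-in-log anchors
    degenerate to the lognormal (nu = 0).
    """
    if not 0 < q_lo < median < q_hi:
        raise ValueError("need q_lo < median < q_hi, all positive")
    lr_u = np.log(q_hi / median)
    lr_l = np.log(q_lo / median)
    if abs(lr_u + lr_l) < 1e-12:  # symmetric on the log scale -> lognormal
        return lr_u / z, 0.0

    def g(x):  # x = z * nu * sigma
        return np.log1p(x) * lr_l - np.log1p(-x) * lr_u

    # g(0) = 0 is the spurious root; the nonzero root sits at x ~ -2(lr_u+lr_l)/(lr_u-lr_l)
    lo, hi = (-0.999999, -1e-9) if lr_u + lr_l > 0 else (1e-9, 0.999999)
    x = brentq(g, lo, hi, xtol=1e-14)
    nu = np.log1p(x) / lr_u
    sigma = x / (z * nu)
    return float(sigma), float(nu)


def default_age_weights(ages: np.ndarray | None = None) -> np.ndarray:
    """Right-skewed discrete age sampler, median 35 y, IQR 30-44 y.

    A shifted-lognormal bulk mimics the working-age concentration of
    health-exam attendees; a 10% uniform floor keeps every adult age
    represented (a few dozen per age at n = 20000), as real check-up
    populations do.
    """
    if ages is None:
        ages = np.arange(18, 81)
    w = 0.9 * stats.lognorm.pdf(ages - 17.0, s=0.5, scale=18.0)
    w = w / w.sum() * 0.9 + 0.1 / len(ages)
    return w / w.sum()


@dataclass(frozen=True)
class TrendSpec:
    """Declared ground truth: BCCG parameters as functions of age, one sex."""

    sex: str
    analyte: str
    mu_ctrl: tuple[tuple[float, float], ...]  # (age, mu) control points
    sigma: float  # constant relative scale
    nu: float  # constant Box-Cox power
    ages: tuple[int, int] = (18, 80)
    age_weights: tuple[float, ...] | None = None  # defaults to the skewed sampler

    def __post_init__(self) -> None:
        if self.sigma <= 0 or any(m <= 0 for _, m in self.mu_ctrl):
            raise ValueError("mu and sigma must be positive everywhere")
        if self.age_weights is not None:
            w = np.asarray(self.age_weights)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("age weights must be nonnegative and sum to 1")

    def _interp(self) -> PchipInterpolator:
        pts = np.asarray(self.mu_ctrl, dtype=float)
        return PchipInterpolator(pts[:, 0], pts[:, 1], extrapolate=True)

    def mu(self, age) -> np.ndarray:
        return self._interp()(np.asarray(age, dtype=float))

    def age_grid(self) -> np.ndarray:
        return np.arange(self.ages[0], self.ages[1] + 1)

    def weights(self) -> np.ndarray:
        if self.age_weights is not None:
            return np.asarray(self.age_weights)
        return default_age_weights(self.age_grid())

    def quantile(self, p, age) -> np.ndarray:
        """True quantile Q(p, age) under the trend (LMS closed form)."""
        mu = self.mu(age)
        z = stats.norm.ppf(p)
        if abs(self.nu) < 1e-8:
            return mu * np.exp(self.sigma * z)
        return mu * np.power(1.0 + self.nu * self.sigma * z, 1.0 / self.nu)


def default_trend(sex: str, analyte: str = "RBC") -> TrendSpec:
    """Red-cell-count trend per sex; other analytes get flat BCCG trends."""
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if analyte == "RBC":
        ctrl = _FEMALE_RBC_MEDIANS if sex == "female" else _MALE_RBC_MEDIANS
        sigma, nu = solve_sigma_nu(*_RBC_ANCHORS[sex])
        return TrendSpec(sex=sex, analyte="RBC", mu_ctrl=tuple(ctrl), sigma=sigma, nu=nu)
    mu, sigma, nu = _OTHER_CBC[sex][analyte]
    return TrendSpec(sex=sex, analyte=analyte, mu_ctrl=((18.0, mu), (80.0, mu)),
                     sigma=sigma, nu=nu)


def _draw_values(u: np.ndarray, trend: TrendSpec, ages: np.ndarray,
                 mu_factor: float = 1.0) -> np.ndarray:
    mu = trend.mu(ages) * mu_factor
    z = stats.norm.ppf(u)
    if abs(trend.nu) < 1e-8:
        return mu * np.exp(trend.sigma * z)
    base = 1.0 + trend.nu * trend.sigma * z
    # the LMS form truncates an O(1e-7) tail; resample-free clip keeps y > 0
    return mu * np.power(np.maximum(base, 1e-12), 1.0 / trend.nu)


def gen_model_cohort(n: int, sex: str, trend: TrendSpec | None = None, seed=None):
    """Clean cohort drawn from a declared trend.

    Returns (ages, values, truth) where ``truth(p, age)`` is the generator's
    exact quantile function.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    trend = trend or default_trend(sex)
    rng = np.random.default_rng(seed)
    grid = trend.age_grid()
    ages = rng.choice(grid, size=n, p=trend.weights())
    u = rng.uniform(size=n)
    values = _draw_values(u, trend, ages)
    return ages.astype(float), values, trend.quantile


@dataclass(frozen=True)
class MessSpec:
    """Rates of the planted pathologies in the raw-table generator."""

    duplicate_visit_rate: float = 0.10
    offday_lab_rate: float = 0.03  # lab specimen dated off the exam day
    missing_rate: float = 0.05  # a required field left blank
    string_noise_rate: float = 0.08  # value rendered as "<x", ">x", "NA", junk
    bmi_ineligible_rate: float = 0.15
    bp_ineligible_rate: float = 0.08
    history_rate: float = 0.10

    def __post_init__(self) -> None:
        rates = [self.duplicate_visit_rate, self.offday_lab_rate, self.missing_rate,
                 self.string_noise_rate, self.bmi_ineligible_rate,
                 self.bp_ineligible_rate, self.history_rate]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        total = (self.offday_lab_rate + self.missing_rate + self.string_noise_rate
                 + self.bmi_ineligible_rate + self.bp_ineligible_rate + self.history_rate)
        if total > 1:
            raise ValueError("pathology rates must sum to <= 1")


_FATAL_NOISE = ["", "NA", "err", "hemolyzed"]


def gen_messy_cohort(n_people: int, mess: MessSpec = MessSpec(),
                     trends: dict[str, TrendSpec] | None = None, seed=None):
    """Raw exam + lab tables with planted pathologies and a truth ledger.

    Each person gets at most one pathology (drawn by cumulative rates in a
    fixed order), so the ledger's eligibility labels are exact: a person is
    planted-eligible iff their pathology is none or a recoverable "<x"/">x"
    string.  Duplicate earlier visits are added independently (never for
    off-day-lab persons, whose only visit must stay unlinked).
    """
    rng = np.random.default_rng(seed)
    trends = trends or {s: default_trend(s) for s in ("female", "male")}
    exam_rows, lab_rows, ledger_rows = [], [], []
    base = pd.Timestamp("2014-01-01")
    span_days = (pd.Timestamp("2018-12-31") - base).days
    cuts = np.cumsum([mess.offday_lab_rate, mess.missing_rate, mess.string_noise_rate,
                      mess.bmi_ineligible_rate, mess.bp_ineligible_rate, mess.history_rate])
    cat_names = ["offday_lab", "missing_field", "string_noise", "bmi", "bp", "history", "clean"]

    for i in range(n_people):
        pid = f"P{i:06d}"
        sex = "female" if rng.uniform() < 0.678 else "male"
        trend = trends[sex]
        age = int(rng.choice(trend.age_grid(), p=trend.weights()))
        date = base + pd.Timedelta(days=int(rng.integers(0, span_days)))
        cat = cat_names[int(np.searchsorted(cuts, rng.uniform(), side="right"))]

        bmi = float(np.round(rng.uniform(18.6, 23.9), 1))
        sbp = int(rng.integers(95, 139))
        dbp = int(rng.integers(58, 89))
        history = ""
        if cat == "bmi":
            bmi = float(np.round(rng.choice([rng.uniform(15.0, 18.4), rng.uniform(24.0, 35.0)]), 1))
        elif cat == "bp":
            sbp, dbp = int(rng.integers(140, 180)), int(rng.integers(90, 110))
        elif cat == "history":
            history = rng.choice(["HTN", "DM", "anemia", "CHD"])

        values = {}
        for a in CBC_ANALYTES:
            t = trends.get(a) if a in trends else default_trend(sex, a)
            values[a] = float(_draw_values(np.array([rng.uniform()]), t, np.array([age]))[0])
        raw = {a: f"{v:.2f}" for a, v in values.items()}
        noise_kind = None
        recoverable = False
        if cat == "missing_field":
            raw[str(rng.choice(CBC_ANALYTES))] = ""
        elif cat == "string_noise":
            target = str(rng.choice(CBC_ANALYTES))
            recoverable = bool(rng.uniform() < 0.5)
            if recoverable:
                noise_kind = str(rng.choice(["<", ">"]))
                raw[target] = f"{noise_kind}{values[target]:.2f}"
            else:
                noise_kind = str(rng.choice(_FATAL_NOISE))
                raw[target] = noise_kind

        exam_rows.append(dict(person_id=pid, exam_date=date.date().isoformat(), age=age,
                              sex=sex, bmi=bmi, sbp=sbp, dbp=dbp, history_flags=history))
        lab_date = date + pd.Timedelta(days=int(rng.integers(1, 30))) if cat == "offday_lab" else date
        lab_rows.append(dict(person_id=pid, receipt_date=lab_date.date().isoformat(), **raw))

        # duplicate earlier visit: fully-formed, same-day-linked, superseded by dedup
        if cat != "offday_lab" and rng.uniform() < mess.duplicate_visit_rate:
            ddate = date - pd.Timedelta(days=int(rng.integers(30, 400)))
            dup_raw = {a: f"{float(_draw_values(np.array([rng.uniform()]), default_trend(sex, a) if a != 'RBC' else trend, np.array([age]))[0]):.2f}"
                       for a in CBC_ANALYTES}
            exam_rows.append(dict(person_id=pid, exam_date=ddate.date().isoformat(), age=age,
                                  sex=sex, bmi=bmi, sbp=sbp, dbp=dbp, history_flags=history))
            lab_rows.append(dict(person_id=pid, receipt_date=ddate.date().isoformat(), **dup_raw))

        eligible = cat == "clean" or (cat == "string_noise" and recoverable)
        ledger_rows.append(dict(person_id=pid, category=cat, eligible=eligible,
                                sex=sex, age=age, **values))

    exams = pd.DataFrame(exam_rows, columns=["person_id", "exam_date", "age", "sex",
                                             "bmi", "sbp", "dbp", "history_flags"])
    labs = pd.DataFrame(lab_rows, columns=["person_id", "receipt_date"] + CBC_ANALYTES)
    ledger = pd.DataFrame(ledger_rows)
    return exams, labs, ledger


def gen_annual_cohorts(years, n_per_year: int, trends: dict[str, TrendSpec] | None = None,
                       drift: float = 0.0, seed=None, female_frac: float = 0.60) -> pd.DataFrame:
    """Independent per-year validation cohorts for one analyte.

    ``drift`` applies a cumulative multiplicative shift to mu per year:
    year j (0-based) uses mu * (1 + drift)^(j+1), so any nonzero drift moves
    the whole distribution immediately and compounds over years.
    """
    if abs(drift) >= 0.5:
        raise ValueError("drift must be bounded (|drift| < 0.5)")
    trends = trends or {s: default_trend(s) for s in ("female", "male")}
    analyte = next(iter(trends.values())).analyte
    frames = []
    for j, year in enumerate(years):
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, j]))
        factor = (1.0 + drift) ** (j + 1)
        n_f = int(round(n_per_year * female_frac))
        for sex, n_s in (("female", n_f), ("male", n_per_year - n_f)):
            trend = trends[sex]
            ages = rng.choice(trend.age_grid(), size=n_s, p=trend.weights())
            u = rng.uniform(size=n_s)
            vals = _draw_values(u, trend, ages, mu_factor=factor)
            frames.append(pd.DataFrame({"year": year, "sex": sex,
                                        "age": ages.astype(float), analyte: vals}))
    return pd.concat(frames, ignore_index=True)
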