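"""Reproducible simulation studies over the full pipeline.

Each study generates its own cohorts from the declared ground-truth trends,
runs the estimation pipeline exactly as a real analysis would, and measures
one headline quantity: temporal flag-rate stability, lower-tail calibration,
or bootstrap-band coverage of the true median.  All randomness flows from a
single master seed through numbered SeedSequence streams, so results are
bit-reproducible and the studies are independent of each other.
"""

from __future__ import annotations

import numpy as np

from ngri.bootstrap import BootstrapSpec, bootstrap_reference_table
from ngri.centile import FitControl, fit_centile_model, predict_centiles
from ngri.cohort import WinsorSpec, winsorize
from ngri.pspline import SplineSpec
from ngri.synthetic import default_trend, gen_annual_cohorts, gen_model_cohort
from ngri.validate import validation_report


def _stream(master_seed: int, k: int) -> int:
    """Independent 31-bit child seed #k of the master seed."""
    return int(np.random.SeedSequence([int(master_seed), k]).generate_state(1)[0] % (2**31))


def temporal_stability_study(
    seed: int,
    n_train_per_sex: int = 20_000,
    n_per_year: int = 20_000,
    B: int = 100,
    years: tuple[int, ...] = (2019, 2020, 2021, 2022, 2023),
) -> dict:
    """Train bootstrap reference tables and classify drift-free annual cohorts.

    Mirrors the full study design: per-sex training cohorts are winsorized at
    the 0.5/99.5 percentiles, modelled with the B-iteration bootstrap, and the
    resulting 2.5th/97.5th limits are applied to independent yearly cohorts.
    Returns the out-of-range percentage (L% + U%) per year x sex stratum and
    its maximum.
    """
    tables = {}
    for k, sex in enumerate(("female", "male")):
        ages, values, _ = gen_model_cohort(n_train_per_sex, sex, seed=_stream(seed, k))
        values = winsorize(values, WinsorSpec())
        tables[sex] = bootstrap_reference_table(
            ages, values, sex, "RBC", SplineSpec(),
            BootstrapSpec(B=B, seed=_stream(seed, 10 + k)), FitControl())
    annual = gen_annual_cohorts(list(years), n_per_year, drift=0.0, seed=_stream(seed, 20))
    out_of_range = {}
    for sex in ("female", "male"):
        rep = validation_report(annual, tables[sex])
        for year in years:
            frac_l = rep.percent(year, sex, "L")
            frac_u = rep.percent(year, sex, "U")
            out_of_range[(year, sex)] = frac_l + frac_u
    return {
        "out_of_range_percent": out_of_range,
        "max_out_of_range_percent": max(out_of_range.values()),
        "tables": tables,
    }


def lower_tail_calibration_study(
    seed: int,
    n_fit: int = 20_000,
    n_fresh: int = 50_000,
    sex: str = "female",
    percentile: float = 0.025,
) -> dict:
    """Percentage of a fresh model-drawn sample below the fitted lower curve.

    A well-calibrated 2.5th-percentile curve should leave 2.5% of new draws
    from the same population strictly below it.
    """
    ages, values, _ = gen_model_cohort(n_fit, sex, seed=_stream(seed, 30))
    model = fit_centile_model(ages, values, analyte="RBC", sex=sex)
    fresh_ages, fresh_values, _ = gen_model_cohort(n_fresh, sex, seed=_stream(seed, 31))
    q_lo = predict_centiles(model, fresh_ages, [percentile])[:, 0]
    pct = 100.0 * float(np.mean(fresh_values < q_lo))
    return {"percent_below": pct, "n_fresh": n_fresh}


def median_coverage_study(
    seed: int,
    n_replicates: int = 60,
    n: int = 500,
    B: int = 60,
    age: float = 40.0,
    sex: str = "female",
) -> dict:
    """Coverage of the 90% bootstrap band for the median curve at one age.

    Each replicate draws a fresh cohort, runs the full bootstrap, and records
    whether the 5th-95th percentile band at ``age`` contains the generator's
    true median.  Nominal coverage is 90%; at this replicate count the
    binomial noise is about +/- 4 percentage points (1 SE).
    """
    trend = default_trend(sex)
    true_median = float(trend.mu(age))
    covered = 0
    for r in range(n_replicates):
        ages, values, _ = gen_model_cohort(n, sex, seed=_stream(seed, 100 + r))
        table = bootstrap_reference_table(
            ages, values, sex, "RBC", SplineSpec(),
            BootstrapSpec(B=B, seed=_stream(seed, 500 + r)), FitControl())
        i = int(np.searchsorted(table.ages, int(age)))
        j = int(np.argmin(np.abs(table.percentiles - 0.5)))
        if table.ci_low[i, j] <= true_median <= table.ci_high[i, j]:
            covered += 1
    return {
        "coverage_percent": 100.0 * covered / n_replicates,
        "n_replicates": n_replicates,
        "true_median": true_median,
    }
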