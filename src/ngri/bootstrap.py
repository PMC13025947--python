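"""Bootstrap percentile-curve estimation for reference tables.

The cohort is resampled with replacement B times (default 100); each
resample is refit and its centile curves evaluated on the integer age grid.
Point estimates are the mean over successful iterations; 90% confidence
bands come from the 5th/95th percentiles of the bootstrap distribution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ngri.centile import ConvergenceError, FitControl, fit_centile_model, predict_centiles
from ngri.pspline import SplineSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapSpec:
    B: int = 100
    ci_quantiles: tuple[float, float] = (0.05, 0.95)
    age_grid: tuple[int, int] = (18, 80)
    percentiles: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975)
    seed: int = 0
    max_failure_frac: float = 0.10
    resample: bool = True  # False: refit the identical data each iteration

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not self.ci_quantiles[0] < self.ci_quantiles[1]:
            raise ValueError("ci quantiles must be ordered")

    def ages(self) -> np.ndarray:
        return np.arange(self.age_grid[0], self.age_grid[1] + 1)


@dataclass
class ReferenceTable:
    """Age x percentile grid of point estimates with 90% bootstrap CI bounds."""

    sex: str
    analyte: str
    ages: np.ndarray
    percentiles: np.ndarray
    point: np.ndarray  # (n_ages, n_percentiles)
    ci_low: np.ndarray
    ci_high: np.ndarray
    provenance: dict = field(default_factory=dict)

    def limits(self, age: float, lower_p: float = 0.025, upper_p: float = 0.975) -> tuple[float, float]:
        """Reference limits at integer age (floored, clamped to the grid)."""
        a = int(np.clip(np.floor(age), self.ages[0], self.ages[-1]))
        i = int(np.searchsorted(self.ages, a))
        jl = int(np.argmin(np.abs(self.percentiles - lower_p)))
        ju = int(np.argmin(np.abs(self.percentiles - upper_p)))
        return float(self.point[i, jl]), float(self.point[i, ju])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ages):
            for j, p in enumerate(self.percentiles):
                rows.append(
                    dict(sex=self.sex, analyte=self.analyte, age=int(a), percentile=float(p),
                         point=self.point[i, j], ci_low=self.ci_low[i, j], ci_high=self.ci_high[i, j])
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str, analyte: str) -> "ReferenceTable":
        sub = df[(df["sex"] == sex) & (df["analyte"] == analyte)]
        ages = np.sort(sub["age"].unique())
        ps = np.sort(sub["percentile"].unique())
        piv = lambda col: (
            sub.pivot(index="age", columns="percentile", values=col).loc[ages, ps].to_numpy()
        )
        return cls(sex=sex, analyte=analyte, ages=ages, percentiles=ps,
                   point=piv("point"), ci_low=piv("ci_low"), ci_high=piv("ci_high"))


def _config_hash(model_spec, control, boot_spec) -> str:
    blob = json.dumps(
        {"spec": asdict(model_spec) if isinstance(model_spec, SplineSpec) else [asdict(s) for s in model_spec],
         "control": asdict(control), "boot": asdict(boot_spec)},
        sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def bootstrap_reference_table(
    ages,
    values,
    sex: str,
    analyte: str,
    model_spec: SplineSpec | tuple[SplineSpec, SplineSpec] = SplineSpec(),
    boot_spec: BootstrapSpec = BootstrapSpec(),
    control: FitControl = FitControl(),
) -> ReferenceTable:
    """Resample-refit-aggregate.  Iteration b draws its RNG from
    SeedSequence([seed, b]) so runs are reproducible and order-independent;
    non-converged iterations are dropped and counted, erroring if more than
    ``max_failure_frac`` of B fail.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) == 0:
        raise ValueError("empty input cohort")
    grid = boot_spec.ages()
    curves = []
    n_failed = 0
    for b in range(boot_spec.B):
        if boot_spec.resample:
            rng = np.random.default_rng(np.random.SeedSequence([boot_spec.seed, b]))
            idx = rng.integers(0, len(ages), size=len(ages))
            a_b, y_b = ages[idx], values[idx]
        else:
            a_b, y_b = ages, values
        try:
            model = fit_centile_model(a_b, y_b, model_spec, control, analyte=analyte, sex=sex)
            curves.append(predict_centiles(model, grid, boot_spec.percentiles))
        except (ConvergenceError, ValueError) as err:
            n_failed += 1
            log.warning("bootstrap iteration %d failed: %s", b, err)
    if n_failed > boot_spec.max_failure_frac * boot_spec.B:
        raise RuntimeError(
            f"{n_failed}/{boot_spec.B} bootstrap iterations failed "
            f"(ceiling {boot_spec.max_failure_frac:.0%})"
        )
    stack = np.stack(curves)  # (B_ok, n_ages, n_percentiles)
    point = stack.mean(axis=0)
    ci_low = np.quantile(stack, boot_spec.ci_quantiles[0], axis=0, method="linear")
    ci_high = np.quantile(stack, boot_spec.ci_quantiles[1], axis=0, method="linear")
    return ReferenceTable(
        sex=sex, analyte=analyte, ages=grid,
        percentiles=np.asarray(boot_spec.percentiles),
        point=point, ci_low=ci_low, ci_high=ci_high,
        provenance={
            "boot_spec": asdict(boot_spec),
            "config_hash": _config_hash(model_spec, control, boot_spec),
            "n_failed": n_failed,
            "n": int(len(ages)),
        },
    )


def format_reference_table(table: ReferenceTable) -> str:
    """Human-readable table: one row per age, cells 'point [lo-hi]' at 2 dp.

    Rounding is round-half-even (banker's), the behaviour of Python float
    formatting.
    """
    header = ["Age"] + [f"Q{100 * p:g}" for p in table.percentiles]
    lines = [f"# sex={table.sex} analyte={table.analyte}", "\t".join(header)]
    for i, a in enumerate(table.ages):
        cells = [
            f"{table.point[i, j]:.2f} [{table.ci_low[i, j]:.2f}–{table.ci_high[i, j]:.2f}]"
            for j in range(len(table.percentiles))
        ]
        lines.append("\t".join([str(int(a))] + cells))
    return "\n".join(lines) + "\n"


_CELL_RE = re.compile(r"([\d.]+) \[([\d.]+)–([\d.]+)\]")


def parse_formatted_table(text: str) -> pd.DataFrame:
    """Round-trip parser for :func:`format_reference_table` output."""
    lines = [ln for ln in text.strip().splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        age = int(parts[0])
        for name, cell in zip(header, parts[1:]):
            m = _CELL_RE.fullmatch(cell)
            if not m:
                raise ValueError(f"malformed cell {cell!r}")
            rows.append(dict(age=age, percentile=float(name[1:]) / 100.0,
                             point=float(m.group(1)), ci_low=float(m.group(2)),
                             ci_high=float(m.group(3))))
    return pd.DataFrame(rows)
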