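"""Baseline summaries and sex comparisons of the training cohort.

Median (IQR) per sex for age, anthropometrics and the red-cell count;
normality assessment; Wilcoxon rank-sum female-vs-male comparisons within
age bands (18-59, 60+) with Benjamini-Hochberg adjustment.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngri.stats import group_comparisons, ks_normality, summary_table  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    summary = summary_table(cohort, ["age", "bmi", "sbp", "dbp", "RBC"])
    summary.to_csv(OUT / "summary_table.csv", index=False)
    for _, row in summary[summary.analyte.isin(["age", "RBC"])].iterrows():
        print(f"{row.group:6s} {row.analyte:4s}: {row['median']:.2f} "
              f"({row.q1:.2f}, {row.q3:.2f}), n={row.n}")

    rbc = pd.to_numeric(cohort["RBC"]).dropna()
    stat, p = ks_normality(rbc)
    print(f"KS normality of pooled RBC: D={stat:.4f}, p={p:.2e}")

    comp = group_comparisons(cohort, ["RBC"])
    comp.to_csv(OUT / "group_comparisons.csv", index=False)
    for _, row in comp.iterrows():
        print(f"female vs male, ages {row.age_band}: U={row.U:.0f}, "
              f"BH-adjusted p={row.p_adjusted:.2e}")


if __name__ == "__main__":
    main()
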