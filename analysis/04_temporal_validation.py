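"""Temporal validation: classify annual cohorts against the fitted limits.

Applies the stored 2.5th/97.5th reference curves to each yearly cohort,
tabulates L/N/U counts and percentages per year x sex, and checks the
<10% out-of-range stability criterion.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngri.bootstrap import ReferenceTable  # noqa: E402
from ngri.validate import flag_rate_check, validation_report  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tables = pd.read_csv(OUT / "reference_tables.csv")
    annual = pd.read_csv(OUT / "data" / "validation.csv")
    frames = []
    all_pass = True
    for sex in ("female", "male"):
        table = ReferenceTable.from_frame(tables, sex, "RBC")
        rep = validation_report(annual, table)
        frames.append(rep.frame)
        check = flag_rate_check(rep)
        all_pass &= check["overall"]
        for (year, s), ok in sorted(check["strata"].items()):
            sub = rep.frame[(rep.frame.year == year)]
            out = sum(sub[sub["class"] == c]["percent"].iloc[0] for c in ("L", "U"))
            print(f"{year} {s:6s}: out-of-range {out:5.2f}% -> {'pass' if ok else 'FAIL'}")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "validation_report.csv", index=False)
    print(f"overall stability check: {'pass (<10% everywhere)' if all_pass else 'FAIL'}")


if __name__ == "__main__":
    main()
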