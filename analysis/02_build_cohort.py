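"""Clean the raw tables into the training cohort.

Links exams to same-day labs, keeps each person's latest record, sanitizes
value strings, applies the eligibility filter (age 18-80, normal BMI and
blood pressure, no history, complete CBC), and reports the exclusion tally
against the generator's ledger.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngri.cohort import build_cohort  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    exams = pd.read_csv(DATA / "exams.csv", dtype={"person_id": str}, keep_default_na=False)
    labs = pd.read_csv(DATA / "labs.csv", dtype=str, keep_default_na=False)
    kept, tally = build_cohort(exams, labs)
    kept.to_csv(OUT / "cohort.csv", index=False)
    (OUT / "exclusion_tally.json").write_text(json.dumps(tally, indent=1, default=str))

    ledger = pd.read_csv(DATA / "ledger.csv")
    planted = int(ledger["eligible"].sum())
    print(f"kept {len(kept)} records; exclusions: " +
          ", ".join(f"{k}={tally[k]}" for k in ("age", "sex", "completeness", "bmi", "bp", "history")))
    print(f"ledger check: planted eligible = {planted} -> "
          f"{'exact match' if planted == len(kept) else 'MISMATCH'}")


if __name__ == "__main__":
    main()
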