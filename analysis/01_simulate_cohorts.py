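"""Generate the synthetic study data: messy raw tables and annual cohorts.

Writes raw examination + laboratory CSVs with planted duplicates, malformed
value strings and ineligible rows (plus the ground-truth ledger), and five
drift-free annual validation cohorts, under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ngri.synthetic import MessSpec, gen_annual_cohorts, gen_messy_cohort  # noqa: E402

SEED = 20260926
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exams, labs, ledger = gen_messy_cohort(8000, MessSpec(), seed=SEED)
    exams.to_csv(OUT / "exams.csv", index=False)
    labs.to_csv(OUT / "labs.csv", index=False)
    ledger.to_csv(OUT / "ledger.csv", index=False)
    n_eligible = int(ledger["eligible"].sum())
    print(f"raw tables: {len(exams)} exam rows, {len(labs)} lab rows, "
          f"{n_eligible} planted-eligible of 8000 people")

    annual = gen_annual_cohorts([2019, 2020, 2021, 2022, 2023], 10_000, seed=SEED + 1)
    annual.to_csv(OUT / "validation.csv", index=False)
    print(f"annual validation cohorts: {len(annual)} rows over 5 years")


if __name__ == "__main__":
    main()
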