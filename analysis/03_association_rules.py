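"""Mine co-reported-ADE and DDI candidate rules from the simulated cohort.

For each statin, reports the ADE terms whose lift with the target event
clears 1.5 and the co-medication rules pointing at the event; the planted
dependencies (acute kidney injury co-reporting within simvastatin, the
simvastatin x furosemide interaction) should surface at the top.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from rhabdosignal import arm
from rhabdosignal.faers_io import STATINS, deduplicate, parse_reports

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = SCRATCH / "cohort.csv"
    if not cohort.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_cohort.py")],
                       check=True)
    clean = deduplicate(parse_reports(cohort))
    outdir = RESULTS / "03_rules"
    outdir.mkdir(parents=True, exist_ok=True)

    for statin in STATINS:
        co = arm.co_reported_ades(clean, statin, k=5)
        ddi = arm.ddi_rules(clean, statin, k=10)
        pd.DataFrame(arm.rules_to_records(co)).to_csv(
            outdir / f"co_ades_{statin}.csv", index=False)
        pd.DataFrame(arm.rules_to_records(ddi)).to_csv(
            outdir / f"ddi_{statin}.csv", index=False)
        co_terms = [f"{next(iter(r.consequent))[4:]} (lift {r.lift:.2f})"
                    for r in co]
        ddi_terms = [
            f"{next(iter(r.antecedent - {arm.drug_item(statin)}))[5:]} "
            f"(lift {r.lift:.2f})" for r in ddi
        ]
        print(f"{statin}: co-reported ADEs past cutoff: "
              f"{', '.join(co_terms) or 'none'}")
        print(f"{statin}: DDI candidates: {', '.join(ddi_terms) or 'none'}")


if __name__ == "__main__":
    main()
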