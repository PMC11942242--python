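"""Generate the synthetic FAERS-style cohort used by the downstream analyses.

Writes the full dashboard-dialect CSV and the planted-truth record to
scratch/ (bulk, regenerated on demand) and a small per-statin summary
table to results/.
"""

from pathlib import Path

import pandas as pd

from rhabdosignal.synthetic_data import CohortConfig, generate_cohort, write_faers_csv

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 20_250_101


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    config = CohortConfig(n_reports=50_000, seed=SEED)
    reports, truth = generate_cohort(config)
    write_faers_csv(reports, SCRATCH / "cohort.csv")
    truth.to_json(SCRATCH / "cohort_truth.json")

    rows = [
        {
            "statin": statin,
            "reports": truth.statin_counts[statin],
            "with_event": truth.contingency[statin][0],
            "monotherapy_reports": sum(truth.monotherapy[statin]),
        }
        for statin in config.statins
    ]
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "01_cohort_summary.csv", index=False)
    print(f"emitted {truth.n_rows_emitted} rows "
          f"({truth.n_literature} literature-flagged, "
          f"{truth.n_duplicate_rows} duplicate case IDs); "
          f"{truth.n_unique_nonliterature} unique analysable reports")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
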