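"""Run the complete study pipeline from CSV files to a report bundle.

Simulates a cohort, writes the three input CSVs (baseline, follow-up tests,
functional status), validates and re-reads them, runs the full analysis
under all three normative datasets, and writes the report bundle.
"""

import tempfile
from pathlib import Path

from moca_psci import SimulationConfig, run_study_from_csv, simulate_study, write_report
from moca_psci.io import write_baseline_csv, write_followup_csvs

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    records, assessments, _ = simulate_study(SimulationConfig(seed=42, n=500))
    write_baseline_csv(records, tmp / "baseline.csv")
    write_followup_csvs(assessments, tmp / "followup_tests.csv", tmp / "functional.csv")

    report = run_study_from_csv(tmp / "baseline.csv", tmp / "followup_tests.csv",
                                tmp / "functional.csv")
    write_report(report, tmp / "report")

    print((tmp / "report" / "report.md").read_text("utf-8"))
    print("bundle files:", sorted(p.name for p in (tmp / "report").iterdir()))
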