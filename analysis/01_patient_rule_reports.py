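#!/usr/bin/env python
"""Evaluate each of the five GAD patients against the normative rule set.

Writes results/patient_reports.json (machine) and
results/patient_reports.md (human verdicts), and prints a one-line summary
per patient.

Finding: every patient violates several amplitude-relationship norms; the
calm-state rule (beta <= theta/2) is broken by all five, and each patient's
narrated abnormality (e.g. AD's alpha asymmetry, GG's alpha-over-theta
excess, SK's beta asymmetries) appears in their report.
"""

import json
from pathlib import Path

from qeegkit import NormativeLimits, evaluate, fixture_patients
from qeegkit.reports import report_to_dict, report_to_markdown

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    limits = NormativeLimits()
    reports = [evaluate(p.profile, limits) for p in fixture_patients()]

    for report in reports:
        flagged = sorted({f.rule_id for f in report.violated()})
        print(f"{report.patient_id}: {report.n_violations} violations "
              f"({', '.join(flagged)})")

    (RESULTS / "patient_reports.json").write_text(
        json.dumps([report_to_dict(r) for r in reports], indent=2) + "\n"
    )
    (RESULTS / "patient_reports.md").write_text(
        "\n".join(report_to_markdown(r) for r in reports)
    )
    print(f"\nwrote {RESULTS / 'patient_reports.json'}")
    print(f"wrote {RESULTS / 'patient_reports.md'}")


if __name__ == "__main__":
    main()
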