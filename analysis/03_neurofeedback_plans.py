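#!/usr/bin/env python
"""Derive per-patient neurofeedback protocol plans at C3 and C4.

Writes results/neurofeedback_plans.json and prints each plan.

Finding: every patient's plan inhibits beta2 in both hemispheres (the
calm-state beta <= theta/2 ceiling is universally exceeded), and most
plans amplify alpha toward a 16% contribution and SMR toward 12% — the
standard anxiety-protocol direction of training at the sensorimotor strip.
"""

import json
from pathlib import Path

from qeegkit import NormativeLimits, fixture_patients, plan_neurofeedback
from qeegkit.reports import plan_to_dict

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    limits = NormativeLimits()
    plans = []
    for patient in fixture_patients():
        for channel in ("C3", "C4"):
            plan = plan_neurofeedback(patient.profile, channel, limits)
            plans.append(plan_to_dict(plan))
            actions = {
                band: bp.direction
                for band, bp in plan.bands.items()
                if bp.direction != "none"
            }
            print(f"{patient.patient_id} {channel}: {actions}")

    (RESULTS / "neurofeedback_plans.json").write_text(
        json.dumps(plans, indent=2) + "\n"
    )
    print(f"\nwrote {RESULTS / 'neurofeedback_plans.json'}")


if __name__ == "__main__":
    main()
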