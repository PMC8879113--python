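#!/usr/bin/env python
"""Validate the pipeline end to end on synthetic recordings.

For each patient profile, generate a 60 s, 250 Hz recording whose band
amplitudes match the printed values (tones over a 1 uV 1/f background),
quantify it back, and compare both amplitudes and rule verdicts.
Writes results/synthetic_recovery.json.

Finding: every amplitude is recovered within a few percent, and the
violated-rule sets match the direct fixture evaluation for all patients
except GP, whose printed C4 SMR and beta1 amplitudes are exactly equal
(4.24 uV) — a tie on a non-strict rule boundary that re-estimation
necessarily resolves at random.
"""

import json
from pathlib import Path

from qeegkit import (
    NormativeLimits,
    evaluate,
    fixture_patients,
    profile_to_spec,
    quantify,
)
from qeegkit.synthetic import generate

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 5


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    limits = NormativeLimits()
    rows = []
    for patient in fixture_patients():
        reference = evaluate(patient.profile, limits).violation_keys()
        worst_err = 0.0
        matches = 0
        for seed in range(N_SEEDS):
            spec = profile_to_spec(patient.profile, noise_scale=1.0, seed=seed)
            recovered = quantify(generate(spec))
            for (ch, band), target in patient.profile.entries.items():
                err = abs(recovered.amplitude(ch, band) / target - 1.0) * 100.0
                worst_err = max(worst_err, err)
            matches += evaluate(recovered, limits).violation_keys() == reference
        rows.append(
            {
                "patient_id": patient.patient_id,
                "n_seeds": N_SEEDS,
                "max_amplitude_error_pct": round(worst_err, 3),
                "rule_set_matches": matches,
            }
        )
        print(
            f"{patient.patient_id}: worst amplitude error {worst_err:.2f}%, "
            f"rule set reproduced in {matches}/{N_SEEDS} seeds"
        )

    (RESULTS / "synthetic_recovery.json").write_text(json.dumps(rows, indent=2) + "\n")
    print(f"\nwrote {RESULTS / 'synthetic_recovery.json'}")


if __name__ == "__main__":
    main()
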