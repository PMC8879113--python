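"""Built-in five-patient GAD amplitude fixture.

The package ships the published resting eyes-open C3/C4 band amplitudes of
five adults with a generalized-anxiety-disorder diagnosis, as printed in
the source case series.  The source tables label amplitudes "mV";
physiological scalp EEG amplitudes are microvolts, so all values here are
interpreted as uV.

For patient GP the theta row is stated without its band name in the source
narrative ("amplitude contributions ... higher than delta"); the values
11.59/10.21 uV are theta, consistent with the cohort discussion of GP's
theta-over-delta excess.
"""

from __future__ import annotations

from .profiles import AmplitudeProfile, PatientRecord

_SCHEME_ID = "nf-standard-0.5-30"

# patient_id -> (sex, age, {band: (C3, C4)})
_FIXTURE: dict[str, tuple[str, int, dict[str, tuple[float, float]]]] = {
    "AD": ("F", 47, {
        "delta": (8.73, 8.42),
        "theta": (9.62, 9.53),
        "alpha": (7.94, 11.1),
        "smr": (5.75, 6.62),
        "beta1": (8.95, 8.05),
        "beta2": (10.27, 11.39),
    }),
    "GG": ("F", 45, {
        "delta": (10.15, 9.96),
        "theta": (8.53, 7.81),
        "alpha": (8.72, 9.03),
        "smr": (6.71, 6.50),
        "beta1": (8.86, 7.17),
        "beta2": (8.52, 8.17),
    }),
    "SK": ("F", 50, {
        "delta": (10.46, 8.99),
        "theta": (7.26, 6.21),
        "alpha": (7.53, 7.21),
        "smr": (5.86, 8.57),
        "beta1": (6.61, 10.61),
        "beta2": (11.38, 19.75),
    }),
    "TD": ("F", 48, {
        "delta": (11.96, 11.60),
        "theta": (9.81, 9.21),
        "alpha": (5.87, 5.39),
        "smr": (3.51, 3.27),
        "beta1": (4.73, 4.30),
        "beta2": (7.2, 6.06),
    }),
    "GP": ("M", 33, {
        "delta": (10.93, 8.87),
        "theta": (11.59, 10.21),
        "alpha": (6.85, 6.45),
        "smr": (4.86, 4.24),
        "beta1": (4.51, 4.24),
        "beta2": (6.63, 5.75),
    }),
}


def fixture_patients() -> list[PatientRecord]:
    """The five published patients, in publication order (AD, GG, SK, TD, GP).

    Returns fresh objects on every call; the underlying table is module
    state and never mutated.
    """
    records = []
    for pid, (sex, age, bands) in _FIXTURE.items():
        entries = {}
        for band, (c3, c4) in bands.items():
            entries[("C3", band)] = c3
            entries[("C4", band)] = c4
        records.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age=age,
                profile=AmplitudeProfile(
                    patient_id=pid, scheme_id=_SCHEME_ID, entries=entries
                ),
            )
        )
    return records
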