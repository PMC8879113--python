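"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from qeegkit import (
    AmplitudeProfile,
    DEFAULT_SCHEME,
    NormativeLimits,
    Recording,
    fixture_patients,
)

FS = 250.0
DURATION = 60.0


@pytest.fixture(scope="session")
def patients():
    return fixture_patients()


@pytest.fixture(scope="session")
def patients_by_id(patients):
    return {p.patient_id: p for p in patients}


@pytest.fixture
def ad_profile(patients_by_id):
    return patients_by_id["AD"].profile


@pytest.fixture
def limits():
    return NormativeLimits()


@pytest.fixture
def conforming_profile():
    """A profile satisfying every normative rule in both hemispheres."""
    bands = {"delta": 12.0, "theta": 9.0, "alpha": 8.0, "smr": 7.0,
             "beta1": 4.2, "beta2": 4.1}
    entries = {(ch, b): v for ch in ("C3", "C4") for b, v in bands.items()}
    return AmplitudeProfile(patient_id="OK", scheme_id=DEFAULT_SCHEME.scheme_id,
                            entries=entries)


def make_tone(freq: float, peak_uv: float, fs: float = FS,
              duration: float = DURATION, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return peak_uv * np.sin(2 * np.pi * freq * t + phase)


def make_recording(channel_signals: dict[str, np.ndarray], fs: float = FS,
                   reference: str = "CZ") -> Recording:
    labels = list(channel_signals)
    return Recording(
        channel_labels=labels,
        sampling_rate=fs,
        samples=np.vstack([channel_signals[c] for c in labels]),
        reference_label=reference,
    )


def time_domain_band_amplitude(x: np.ndarray, f_lo: float, f_hi: float,
                               fs: float = FS, n_taps: int = 1025) -> float:
    """Independent oracle: sqrt(2) * RMS of a zero-phase band-passed copy.

    A steep linear-phase FIR band-pass run forward and backward — a purely
    time-domain route sharing nothing with the Welch estimator.  One filter
    length is trimmed from each end before taking the RMS, because the
    padding transients of filtfilt ring through narrow low-frequency bands.
    """
    taps = sps.firwin(n_taps, [f_lo, f_hi], pass_zero=False, fs=fs)
    filtered = sps.filtfilt(taps, [1.0], x)[n_taps:-n_taps]
    return float(np.sqrt(2.0) * np.std(filtered))
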