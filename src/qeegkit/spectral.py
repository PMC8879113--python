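"""Spectral band quantification.

A recording is reduced to an :class:`~qeegkit.profiles.AmplitudeProfile`
in three steps:

1. re-reference every channel to the vertex electrode Cz (referential
   Cz montage, the convention for central-strip QEEG);
2. estimate a one-sided power spectral density per channel by Hann-windowed
   segment averaging (Welch);
3. integrate the PSD over each band ``[f_lo, f_hi)`` and convert the band
   power ``P`` to an *equivalent-sine peak amplitude* ``sqrt(2 P)`` — the
   peak amplitude a single sinusoid would need to carry that power.  A pure
   tone of peak amplitude ``A`` inside a band therefore yields a band
   amplitude of ``A``, which pins the unit (uV) to the normative tables.

Defaults: 4 s Hann windows with 50% overlap (0.25 Hz resolution), no
artifact rejection.  An optional peak-amplitude epoch-rejection switch is
available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BandDefinition, BandScheme, DEFAULT_SCHEME
from .errors import ConfigurationError, InputError, ValidationError
from .profiles import AmplitudeProfile, normalize_channel
from .recording import Recording

DEFAULT_WINDOW_SECONDS = 4.0
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided Welch PSD for a single channel.

    ``power_density`` is in uV^2/Hz on a frequency grid from 0 to Nyquist;
    integrating it over a band gives the band power in uV^2.
    """

    channel: str
    frequencies: np.ndarray
    power_density: np.ndarray
    window_seconds: float
    overlap_fraction: float
    n_segments: int

    @property
    def df(self) -> float:
        """Frequency-grid spacing in Hz."""
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])


def rereference_to_cz(recording: Recording) -> Recording:
    """Referential Cz montage: subtract Cz from every channel, drop Cz.

    A recording already referenced to Cz is returned unchanged with a
    warning (the operation is idempotent through the reference bookkeeping).

    Raises
    ------
    ConfigurationError
        If the recording has no Cz channel.
    """
    if recording.reference_label == "CZ":
        warnings.warn("recording is already Cz-referenced; no-op", stacklevel=2)
        return recording
    try:
        cz_idx = recording.channel_index("CZ")
    except ValidationError:
        raise ConfigurationError(
            "Cz re-referencing requires a CZ channel; "
            f"recording has {recording.channel_labels}"
        ) from None
    cz = recording.samples[cz_idx]
    keep = [i for i in range(recording.n_channels) if i != cz_idx]
    return Recording(
        channel_labels=[recording.channel_labels[i] for i in keep],
        sampling_rate=recording.sampling_rate,
        samples=recording.samples[keep] - cz,
        reference_label="CZ",
    )


def amplitude_spectrum(
    samples: np.ndarray,
    fs: float,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    overlap_fraction: float = DEFAULT_OVERLAP,
    channel: str = "",
) -> SpectrumEstimate:
    """Welch PSD of one channel (uV in, uV^2/Hz out).

    Hann window, mean detrending per segment, density scaling: summing the
    PSD times the bin width over all frequencies recovers the signal
    variance (Parseval), and integrating over a band isolates that band's
    power.

    Raises
    ------
    InputError
        If the signal is shorter than one window, ``fs`` is non-positive,
        or the overlap is outside ``[0, 1)``.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise InputError("amplitude_spectrum expects a single channel")
    if fs <= 0:
        raise InputError(f"sampling rate must be > 0, got {fs}")
    if not 0 <= overlap_fraction < 1:
        raise InputError(f"overlap fraction must be in [0, 1), got {overlap_fraction}")
    nperseg = int(round(window_seconds * fs))
    if nperseg < 2 or x.size < nperseg:
        raise InputError(
            f"signal ({x.size} samples) shorter than one {window_seconds} s "
            f"window ({nperseg} samples)"
        )
    noverlap = int(round(nperseg * overlap_fraction))
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    step = nperseg - noverlap
    n_segments = 1 + (x.size - nperseg) // step
    return SpectrumEstimate(
        channel=channel,
        frequencies=freqs,
        power_density=psd,
        window_seconds=window_seconds,
        overlap_fraction=overlap_fraction,
        n_segments=n_segments,
    )


def band_power(spectrum: SpectrumEstimate, band: BandDefinition) -> float:
    """Integrated power (uV^2) over ``[f_lo, f_hi)``."""
    if band.f_hi > spectrum.nyquist + 1e-9:
        raise InputError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}) exceeds the "
            f"spectrum's Nyquist frequency {spectrum.nyquist} Hz"
        )
    mask = (spectrum.frequencies >= band.f_lo) & (spectrum.frequencies < band.f_hi)
    return float(np.sum(spectrum.power_density[mask]) * spectrum.df)


def band_amplitude(spectrum: SpectrumEstimate, band: BandDefinition) -> float:
    """Equivalent-sine peak amplitude ``sqrt(2 * band power)`` in uV."""
    return float(np.sqrt(2.0 * band_power(spectrum, band)))


def _reject_epochs(x: np.ndarray, nperseg: int, peak_uv: float) -> np.ndarray:
    """Drop non-overlapping epochs whose absolute peak exceeds ``peak_uv``."""
    n_epochs = x.size // nperseg
    epochs = x[: n_epochs * nperseg].reshape(n_epochs, nperseg)
    keep = np.max(np.abs(epochs), axis=1) <= peak_uv
    if not np.any(keep):
        raise InputError(
            f"all epochs exceed the +/-{peak_uv} uV artifact threshold"
        )
    return epochs[keep].ravel()


def quantify(
    recording: Recording,
    scheme: BandScheme = DEFAULT_SCHEME,
    channels: tuple[str, ...] = ("C3", "C4"),
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    overlap_fraction: float = DEFAULT_OVERLAP,
    reject_peak_uv: float | None = None,
) -> AmplitudeProfile:
    """Quantify a recording into a per-channel, per-band amplitude profile.

    If the recording is not yet Cz-referenced and contains a Cz channel it
    is re-referenced first.  The result is deterministic for fixed inputs
    and independent of channel order.

    Parameters
    ----------
    reject_peak_uv
        Optional artifact switch: drop non-overlapping analysis epochs
        whose absolute peak exceeds this many uV.  Off (``None``) by
        default — resting recordings are analysed whole.

    Raises
    ------
    InputError
        If a requested channel is missing after the montage, or the
        recording is shorter than one analysis window.
    ValidationError
        If any band amplitude is not strictly positive (e.g. an all-zero
        recording).
    """
    if recording.sampling_rate <= 2 * scheme.f_max:
        raise InputError(
            f"sampling rate {recording.sampling_rate} Hz cannot resolve the "
            f"scheme's top edge {scheme.f_max} Hz"
        )
    if recording.reference_label != "CZ" and "CZ" in recording.channel_labels:
        recording = rereference_to_cz(recording)

    wanted = [normalize_channel(c) for c in channels]
    missing = [c for c in wanted if c not in recording.channel_labels]
    if missing:
        raise InputError(
            f"channels missing after montage: {missing} "
            f"(have {recording.channel_labels})"
        )

    entries: dict[tuple[str, str], float] = {}
    for ch in sorted(wanted):
        x = recording.channel(ch)
        if reject_peak_uv is not None:
            nperseg = int(round(window_seconds * recording.sampling_rate))
            x = _reject_epochs(x, nperseg, reject_peak_uv)
        spec = amplitude_spectrum(
            x,
            recording.sampling_rate,
            window_seconds=window_seconds,
            overlap_fraction=overlap_fraction,
            channel=ch,
        )
        for band in scheme:
            entries[(ch, band.name)] = band_amplitude(spec, band)

    try:
        return AmplitudeProfile(
            patient_id="", scheme_id=scheme.scheme_id, entries=entries
        )
    except ValidationError as exc:
        raise ValidationError(
            f"quantification produced a degenerate profile: {exc}"
        ) from exc
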