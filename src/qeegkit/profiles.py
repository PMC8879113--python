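"""Amplitude profiles: the central object exchanged between stages.

An :class:`AmplitudeProfile` holds one equivalent-sine peak amplitude in
microvolts per (channel, band) pair, for a fixed band scheme.  Profiles are
produced either by spectral quantification of a recording
(:mod:`qeegkit.spectral`) or read from amplitude tables
(:mod:`qeegkit.io`), and are consumed by the normative rule engine and the
anxiety-signature screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .bands import BAND_NAMES, normalize_band
from .errors import ValidationError


def normalize_channel(label: str) -> str:
    """Upper-case, whitespace-stripped 10-20 electrode label."""
    out = label.strip().upper()
    if not out:
        raise ValidationError("empty channel label")
    return out


@dataclass(frozen=True)
class AmplitudeProfile:
    """Per-channel, per-band amplitudes (uV) for one subject.

    Parameters
    ----------
    patient_id
        Short subject code.
    scheme_id
        Identifier of the band scheme the amplitudes were computed under.
    entries
        Mapping ``(channel, band) -> amplitude_uV``.  Keys are normalised
        on construction; every declared channel must carry all six bands
        and every amplitude must be finite and strictly positive.
    """

    patient_id: str
    scheme_id: str
    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[tuple[str, str], float] = {}
        for (channel, band), amp in self.entries.items():
            key = (normalize_channel(channel), normalize_band(band))
            if key in norm:
                raise ValidationError(f"duplicate entry for {key}")
            amp = float(amp)
            if not math.isfinite(amp) or amp <= 0:
                raise ValidationError(
                    f"amplitude for {key} must be finite and > 0, got {amp}"
                )
            norm[key] = amp
        if not norm:
            raise ValidationError("profile has no entries")
        for channel in {c for c, _ in norm}:
            missing = [b for b in BAND_NAMES if (channel, b) not in norm]
            if missing:
                raise ValidationError(
                    f"channel {channel} is missing bands: {', '.join(missing)}"
                )
        object.__setattr__(self, "entries", norm)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.entries}))

    def amplitude(self, channel: str, band: str) -> float:
        """Amplitude in uV for one (channel, band) pair."""
        key = (normalize_channel(channel), normalize_band(band))
        try:
            return self.entries[key]
        except KeyError:
            raise ValidationError(f"profile has no entry for {key}") from None

    def has_channels(self, *channels: str) -> bool:
        present = set(self.channels)
        return all(normalize_channel(c) in present for c in channels)

    def scaled(self, factor: float) -> "AmplitudeProfile":
        """Profile with every amplitude multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be > 0")
        return AmplitudeProfile(
            patient_id=self.patient_id,
            scheme_id=self.scheme_id,
            entries={k: v * factor for k, v in self.entries.items()},
        )


@dataclass(frozen=True)
class PatientRecord:
    """One subject: id, sex, age and their amplitude profile.

    The rule engine and cohort statistics need both central electrodes, so
    the profile must contain C3 and C4 with all six bands.
    """

    patient_id: str
    sex: str
    age: float
    profile: AmplitudeProfile

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not self.age > 0:
            raise ValidationError(f"age must be > 0, got {self.age}")
        if not self.profile.has_channels("C3", "C4"):
            raise ValidationError(
                f"patient {self.patient_id}: profile must contain C3 and C4"
            )
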