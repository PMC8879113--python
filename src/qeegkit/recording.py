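"""In-memory multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .profiles import normalize_channel

#: Sentinel reference label meaning "no single reference electrode".
COMMON_AVERAGE = "common-average"


@dataclass
class Recording:
    """Multichannel EEG samples in microvolts.

    Parameters
    ----------
    channel_labels
        10-20 electrode names, unique after normalisation (upper-case,
        stripped).
    sampling_rate
        Sampling frequency in Hz.
    samples
        ``(n_channels, n_samples)`` array in uV; finite throughout.
    reference_label
        Electrode the channels are measured against, or
        :data:`COMMON_AVERAGE`.
    """

    channel_labels: list[str]
    sampling_rate: float
    samples: np.ndarray
    reference_label: str = COMMON_AVERAGE

    def __post_init__(self) -> None:
        self.channel_labels = [normalize_channel(c) for c in self.channel_labels]
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError(
                f"duplicate channel labels: {self.channel_labels}"
            )
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{len(self.channel_labels)} labels but "
                f"{self.samples.shape[0]} sample rows"
            )
        if self.samples.shape[1] < 1:
            raise ValidationError("recording has no samples")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.reference_label != COMMON_AVERAGE:
            self.reference_label = normalize_channel(self.reference_label)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        key = normalize_channel(label)
        try:
            return self.channel_labels.index(key)
        except ValueError:
            raise ValidationError(
                f"channel {key} not in recording (have {self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """One channel's samples (uV)."""
        return self.samples[self.channel_index(label)]
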