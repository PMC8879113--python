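"""Run configuration: band edges, limits and spectral parameters from YAML.

Defaults reproduce the built-in fixture results; every report embeds the
effective configuration so results stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bands import BAND_NAMES, BandDefinition, BandScheme, DEFAULT_SCHEME
from .errors import ConfigurationError
from .rules import NormativeLimits
from .signature import DEFAULT_SIGNATURE_TOL
from .spectral import DEFAULT_OVERLAP, DEFAULT_WINDOW_SECONDS


@dataclass(frozen=True)
class RunConfig:
    scheme: BandScheme = DEFAULT_SCHEME
    limits: NormativeLimits = field(default_factory=NormativeLimits)
    dominant_side: str = "left"
    signature_tol: float = DEFAULT_SIGNATURE_TOL
    window_seconds: float = DEFAULT_WINDOW_SECONDS
    overlap_fraction: float = DEFAULT_OVERLAP
    channels: tuple[str, ...] = ("C3", "C4")

    def __post_init__(self) -> None:
        if self.dominant_side not in ("left", "right"):
            raise ConfigurationError(
                f"dominant_side must be 'left' or 'right', got {self.dominant_side!r}"
            )
        if not 0 <= self.signature_tol <= 0.5:
            raise ConfigurationError("signature_tol must be in [0, 0.5]")

    def to_dict(self) -> dict:
        """Effective configuration, embedded in every report."""
        return {
            "scheme_id": self.scheme.scheme_id,
            "bands": {b.name: [b.f_lo, b.f_hi] for b in self.scheme},
            "limits": {
                "delta_max": self.limits.delta_max,
                "theta_max": self.limits.theta_max,
                "alpha_max": self.limits.alpha_max,
                "fast_range": list(self.limits.fast_range),
                "asymmetry_threshold": self.limits.asymmetry_threshold,
                "dominance_margin": self.limits.dominance_margin,
                "calm_beta_fraction": self.limits.calm_beta_fraction,
                "smr_theta_fraction": self.limits.smr_theta_fraction,
            },
            "dominant_side": self.dominant_side,
            "signature_tol": self.signature_tol,
            "window_seconds": self.window_seconds,
            "overlap_fraction": self.overlap_fraction,
            "channels": list(self.channels),
        }


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    YAML keys mirror :meth:`RunConfig.to_dict`; unknown keys are rejected.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    kwargs: dict = {}
    if "bands" in data:
        edges = data.pop("bands")
        try:
            bands = tuple(
                BandDefinition(name, *map(float, edges[name])) for name in BAND_NAMES
            )
        except KeyError as exc:
            raise ConfigurationError(f"band edges missing for {exc}") from exc
        scheme_id = data.pop("scheme_id", "custom")
        kwargs["scheme"] = BandScheme(bands=bands, scheme_id=scheme_id)
    else:
        data.pop("scheme_id", None)

    limit_fields = {
        "delta_max", "theta_max", "alpha_max", "fast_range",
        "asymmetry_threshold", "dominance_margin",
        "calm_beta_fraction", "smr_theta_fraction",
    }
    limits_data = data.pop("limits", {})
    if not isinstance(limits_data, dict) or not set(limits_data) <= limit_fields:
        raise ConfigurationError(f"unknown limit keys in {limits_data}")
    if "fast_range" in limits_data:
        limits_data["fast_range"] = tuple(limits_data["fast_range"])
    if limits_data:
        kwargs["limits"] = NormativeLimits(**limits_data)

    for key in ("dominant_side", "signature_tol", "window_seconds", "overlap_fraction"):
        if key in data:
            kwargs[key] = data.pop(key)
    if "channels" in data:
        kwargs["channels"] = tuple(data.pop("channels"))
    if data:
        raise ConfigurationError(f"unknown config keys: {sorted(data)}")
    return RunConfig(**kwargs)
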