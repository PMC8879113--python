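"""Frequency-band definitions for central-electrode QEEG.

The six bands used throughout the package are the ones conventional in
neurofeedback practice over the sensorimotor strip: delta, theta, alpha,
SMR (sensorimotor rhythm), beta1 and beta2.  Band *edges* are a
configuration choice, not a law of nature: different acquisition systems
draw them slightly differently, so every :class:`BandScheme` carries an
identifier that is stamped into the profiles computed with it.

Intervals are half-open ``[f_lo, f_hi)`` so adjacent bands never
double-count a shared edge frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Canonical band names, slow to fast.  All APIs normalise to these.
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "smr", "beta1", "beta2")

#: Bands subject to the 4-10 uV absolute range (the "fast" waves).
FAST_BANDS: tuple[str, ...] = ("smr", "beta1", "beta2")

#: Bands expected to dominate the non-dominant hemisphere (the "slow" waves).
SLOW_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "smr")


def normalize_band(name: str) -> str:
    """Map a band label to its canonical lower-case name.

    Raises
    ------
    ValidationError
        If the label is not one of the six bands in the scheme.
    """
    key = name.strip().lower()
    if key not in BAND_NAMES:
        raise ValidationError(
            f"unknown band {name!r}; expected one of {', '.join(BAND_NAMES)}"
        )
    return key


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_band(self.name))
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(
                f"band {self.name}: need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi})"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def contains(self, freq: float) -> bool:
        return self.f_lo <= freq < self.f_hi


@dataclass(frozen=True)
class BandScheme:
    """An ordered set of exactly the six canonical bands.

    Bands must be pairwise non-overlapping and sorted by lower edge.
    ``scheme_id`` identifies the edge convention and travels with every
    amplitude profile derived under it.
    """

    bands: tuple[BandDefinition, ...]
    scheme_id: str

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if sorted(names) != sorted(BAND_NAMES):
            raise ValidationError(
                f"scheme {self.scheme_id!r} must contain exactly the bands "
                f"{BAND_NAMES}, got {tuple(names)}"
            )
        for lo, hi in zip(self.bands, self.bands[1:]):
            if hi.f_lo < lo.f_hi:
                raise ValidationError(
                    f"scheme {self.scheme_id!r}: bands {lo.name} and {hi.name} "
                    "overlap or are out of order"
                )

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, name: str) -> BandDefinition:
        key = normalize_band(name)
        for band in self.bands:
            if band.name == key:
                return band
        raise KeyError(name)  # unreachable: normalize_band already validated

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    @property
    def f_max(self) -> float:
        return max(b.f_hi for b in self.bands)


#: Default edge convention: standard neurofeedback bands over C3/Cz/C4.
DEFAULT_SCHEME = BandScheme(
    bands=(
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("smr", 12.0, 15.0),
        BandDefinition("beta1", 15.0, 20.0),
        BandDefinition("beta2", 20.0, 30.0),
    ),
    scheme_id="nf-standard-0.5-30",
)
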