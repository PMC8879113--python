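"""Normative amplitude-relationship rules for resting eyes-open QEEG.

The rule set encodes the amplitude norms used in neurotherapeutic practice
for adult central-strip recordings:

* absolute ceilings/ranges per band — delta < 20 uV, theta < 15 uV,
  alpha < 10 uV, and the fast waves (SMR, beta1, beta2) within 4-10 uV;
* the slow-to-fast ordering delta > theta > alpha > SMR >= beta1, beta2;
* ratio rules — SMR at least half of theta, alpha at least beta2, and in
  a calm resting state beta1/beta2 no more than half of theta;
* inter-hemispheric symmetry — homologous C3/C4 amplitudes should differ
  by no more than 20%;
* hemispheric dominance — fast waves may run up to 50% higher in the
  dominant hemisphere, while slow waves are expected to be the higher on
  the non-dominant side (reported informationally, not as a pathology).

The asymmetry index uses the *smaller* amplitude as denominator:
``|L - R| / min(L, R) * 100``.  It is symmetric and scale-invariant, and
with this convention the fixture cohort's published asymmetry findings are
reproduced exactly (a max-denominator variant under-flags two of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bands import BAND_NAMES, FAST_BANDS, SLOW_BANDS
from .errors import InputError
from .profiles import AmplitudeProfile, normalize_channel

PASS = "pass"
VIOLATION = "violation"
INFO = "info"

#: Strict "greater than" ordering rules: (rule_id, upper band, lower band).
_STRICT_ORDER = (
    ("ORDER_DELTA_THETA", "delta", "theta"),
    ("ORDER_THETA_ALPHA", "theta", "alpha"),
    ("ORDER_ALPHA_SMR", "alpha", "smr"),
)
#: Non-strict "greater or equal" rules: (rule_id, upper band, lower band).
_NONSTRICT_ORDER = (
    ("ORDER_SMR_BETA1", "smr", "beta1"),
    ("ORDER_SMR_BETA2", "smr", "beta2"),
    ("ALPHA_GE_BETA2", "alpha", "beta2"),
)


@dataclass(frozen=True)
class NormativeLimits:
    """Thresholds of the adult resting eyes-open norms (uV and percent)."""

    delta_max: float = 20.0
    theta_max: float = 15.0
    alpha_max: float = 10.0
    fast_range: tuple[float, float] = (4.0, 10.0)
    asymmetry_threshold: float = 20.0  # percent
    dominance_margin: float = 50.0  # percent
    calm_beta_fraction: float = 0.5  # of theta
    smr_theta_fraction: float = 0.5  # of theta

    def __post_init__(self) -> None:
        if min(self.delta_max, self.theta_max, self.alpha_max) <= 0:
            raise InputError("band ceilings must be positive")
        lo, hi = self.fast_range
        if not 0 < lo < hi:
            raise InputError(f"fast range must satisfy 0 < lo < hi, got {self.fast_range}")
        if not 0 < self.asymmetry_threshold <= 100:
            raise InputError("asymmetry threshold must be in (0, 100] percent")
        if self.dominance_margin <= 0:
            raise InputError("dominance margin must be positive")
        for frac in (self.calm_beta_fraction, self.smr_theta_fraction):
            if not 0 < frac <= 1:
                raise InputError("theta fractions must be in (0, 1]")

    def ceiling(self, band: str) -> float:
        return {"delta": self.delta_max, "theta": self.theta_max, "alpha": self.alpha_max}[band]


@dataclass(frozen=True)
class RuleFinding:
    """One rule's verdict at one scope.

    ``observed`` carries the amplitudes (or derived index) the verdict was
    based on, copied straight from the profile.
    """

    rule_id: str
    channel: str  # single channel, or "C3/C4" for hemispheric rules
    band: str  # single band, or a "x/y" pair for ordering rules
    status: str  # pass | violation | info
    observed: tuple[float, ...]
    message: str

    @property
    def is_violation(self) -> bool:
        return self.status == VIOLATION


@dataclass(frozen=True)
class RuleReport:
    """All findings for one patient's profile."""

    patient_id: str
    findings: tuple[RuleFinding, ...] = field(default_factory=tuple)

    @property
    def n_violations(self) -> int:
        return sum(f.is_violation for f in self.findings)

    def violated(self) -> tuple[RuleFinding, ...]:
        return tuple(f for f in self.findings if f.is_violation)

    def violation_keys(self) -> frozenset[tuple[str, str, str]]:
        """Hashable (rule_id, channel, band) set of violations, for comparisons."""
        return frozenset((f.rule_id, f.channel, f.band) for f in self.violated())


def asymmetry_index(a_left: float, a_right: float) -> float:
    """Percent left-right amplitude difference, smaller side as reference.

    ``|L - R| / min(L, R) * 100``; symmetric in its arguments,
    scale-invariant and zero iff the amplitudes are equal.

    Raises
    ------
    InputError
        If either amplitude is not strictly positive.
    """
    if a_left <= 0 or a_right <= 0:
        raise InputError(
            f"amplitudes must be > 0, got ({a_left}, {a_right})"
        )
    return abs(a_left - a_right) / min(a_left, a_right) * 100.0


def check_absolute_limits(
    profile: AmplitudeProfile, limits: NormativeLimits = NormativeLimits()
) -> list[RuleFinding]:
    """One ABS_LIMIT finding per (channel, band).

    Slow bands violate at or above their ceiling; fast bands violate
    outside the closed 4-10 uV range.
    """
    findings = []
    for channel in profile.channels:
        for band in BAND_NAMES:
            amp = profile.amplitude(channel, band)
            if band in FAST_BANDS:
                lo, hi = limits.fast_range
                bad = not (lo <= amp <= hi)
                msg = f"{band} {amp:.2f} uV vs range [{lo:g}, {hi:g}] uV"
            else:
                ceil = limits.ceiling(band)
                bad = amp >= ceil
                msg = f"{band} {amp:.2f} uV vs ceiling {ceil:g} uV"
            findings.append(
                RuleFinding(
                    rule_id="ABS_LIMIT",
                    channel=channel,
                    band=band,
                    status=VIOLATION if bad else PASS,
                    observed=(amp,),
                    message=f"{channel}: {msg}",
                )
            )
    return findings


def check_ordering(
    profile: AmplitudeProfile,
    channel: str,
    limits: NormativeLimits = NormativeLimits(),
) -> list[RuleFinding]:
    """The nine within-channel ordering/ratio findings.

    delta > theta > alpha > SMR (strict), SMR >= beta1, SMR >= beta2 and
    alpha >= beta2 (non-strict), SMR >= theta/2, and the calm-state rule
    beta1, beta2 <= theta/2.
    """
    channel = normalize_channel(channel)
    amp = {b: profile.amplitude(channel, b) for b in BAND_NAMES}
    findings = []
    for rule_id, hi_band, lo_band in _STRICT_ORDER:
        ok = amp[hi_band] > amp[lo_band]
        findings.append(
            RuleFinding(
                rule_id=rule_id,
                channel=channel,
                band=f"{hi_band}/{lo_band}",
                status=PASS if ok else VIOLATION,
                observed=(amp[hi_band], amp[lo_band]),
                message=(
                    f"{channel}: {hi_band} {amp[hi_band]:.2f} uV should exceed "
                    f"{lo_band} {amp[lo_band]:.2f} uV"
                ),
            )
        )
    for rule_id, hi_band, lo_band in _NONSTRICT_ORDER:
        ok = amp[hi_band] >= amp[lo_band]
        findings.append(
            RuleFinding(
                rule_id=rule_id,
                channel=channel,
                band=f"{hi_band}/{lo_band}",
                status=PASS if ok else VIOLATION,
                observed=(amp[hi_band], amp[lo_band]),
                message=(
                    f"{channel}: {hi_band} {amp[hi_band]:.2f} uV should be at "
                    f"least {lo_band} {amp[lo_band]:.2f} uV"
                ),
            )
        )
    half_theta = limits.smr_theta_fraction * amp["theta"]
    findings.append(
        RuleFinding(
            rule_id="SMR_HALF_THETA",
            channel=channel,
            band="smr/theta",
            status=PASS if amp["smr"] >= half_theta else VIOLATION,
            observed=(amp["smr"], amp["theta"]),
            message=(
                f"{channel}: SMR {amp['smr']:.2f} uV should be at least "
                f"{limits.smr_theta_fraction:g} x theta = {half_theta:.2f} uV"
            ),
        )
    )
    calm_ceiling = limits.calm_beta_fraction * amp["theta"]
    for beta in ("beta1", "beta2"):
        findings.append(
            RuleFinding(
                rule_id="CALM_BETA_HALF_THETA",
                channel=channel,
                band=beta,
                status=PASS if amp[beta] <= calm_ceiling else VIOLATION,
                observed=(amp[beta], amp["theta"]),
                message=(
                    f"{channel}: calm-state {beta} {amp[beta]:.2f} uV should "
                    f"not exceed {limits.calm_beta_fraction:g} x theta = "
                    f"{calm_ceiling:.2f} uV"
                ),
            )
        )
    return findings


def check_asymmetry(
    profile: AmplitudeProfile, limits: NormativeLimits = NormativeLimits()
) -> list[RuleFinding]:
    """One ASYMMETRY finding per band over the C3/C4 pair.

    Violation when the index strictly exceeds the threshold; a tie at
    exactly the threshold is within the "up to" norm.
    """
    if not profile.has_channels("C3", "C4"):
        raise InputError("asymmetry check needs both C3 and C4")
    findings = []
    for band in BAND_NAMES:
        left = profile.amplitude("C3", band)
        right = profile.amplitude("C4", band)
        index = asymmetry_index(left, right)
        findings.append(
            RuleFinding(
                rule_id="ASYMMETRY",
                channel="C3/C4",
                band=band,
                status=VIOLATION if index > limits.asymmetry_threshold else PASS,
                observed=(left, right, index),
                message=(
                    f"{band}: C3 {left:.2f} / C4 {right:.2f} uV, asymmetry "
                    f"{index:.2f}% vs {limits.asymmetry_threshold:g}%"
                ),
            )
        )
    return findings


def check_dominance(
    profile: AmplitudeProfile,
    dominant_side: str = "left",
    limits: NormativeLimits = NormativeLimits(),
) -> list[RuleFinding]:
    """One DOMINANCE finding per band over the C3/C4 pair.

    Fast waves (beta1, beta2) violate when the dominant hemisphere exceeds
    the non-dominant by more than the margin; a fast-wave excess on the
    *non-dominant* side is against expectation but not a stated pathology,
    so it is reported informationally.  Slow waves (delta, theta, alpha,
    SMR) are expected to run higher on the non-dominant side; a
    dominant-side excess is likewise informational and never counted as a
    violation.
    """
    if dominant_side not in ("left", "right"):
        raise InputError(f"dominant_side must be 'left' or 'right', got {dominant_side!r}")
    if not profile.has_channels("C3", "C4"):
        raise InputError("dominance check needs both C3 and C4")
    dom_ch, nondom_ch = ("C3", "C4") if dominant_side == "left" else ("C4", "C3")
    findings = []
    for band in BAND_NAMES:
        dom = profile.amplitude(dom_ch, band)
        nondom = profile.amplitude(nondom_ch, band)
        excess_pct = (dom - nondom) / nondom * 100.0
        if band in ("beta1", "beta2"):
            if excess_pct > limits.dominance_margin:
                status = VIOLATION
            elif excess_pct < 0:
                status = INFO  # fast wave higher on the non-dominant side
            else:
                status = PASS
            msg = (
                f"{band}: dominant {dom_ch} {dom:.2f} uV is {excess_pct:+.1f}% "
                f"of non-dominant {nondom_ch} {nondom:.2f} uV "
                f"(margin {limits.dominance_margin:g}%)"
            )
        else:
            status = INFO if dom > nondom else PASS
            msg = (
                f"{band}: slow wave higher on the "
                f"{'dominant' if dom > nondom else 'non-dominant'} side "
                f"({dom_ch} {dom:.2f} vs {nondom_ch} {nondom:.2f} uV)"
            )
        findings.append(
            RuleFinding(
                rule_id="DOMINANCE",
                channel="C3/C4",
                band=band,
                status=status,
                observed=(dom, nondom, excess_pct),
                message=msg,
            )
        )
    return findings


def evaluate(
    profile: AmplitudeProfile,
    limits: NormativeLimits = NormativeLimits(),
    dominant_side: str = "left",
) -> RuleReport:
    """Full rule evaluation over C3 and C4.

    For a two-channel, six-band profile the report contains exactly
    12 ABS_LIMIT + 18 ordering/ratio + 6 ASYMMETRY + 6 DOMINANCE = 42
    findings, in a deterministic (rule, channel, band) order.
    """
    findings: list[RuleFinding] = []
    findings.extend(check_absolute_limits(profile, limits))
    for channel in profile.channels:
        findings.extend(check_ordering(profile, channel, limits))
    findings.extend(check_asymmetry(profile, limits))
    findings.extend(check_dominance(profile, dominant_side, limits))
    findings.sort(key=lambda f: (f.rule_id, f.channel, f.band))
    return RuleReport(patient_id=profile.patient_id, findings=tuple(findings))
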