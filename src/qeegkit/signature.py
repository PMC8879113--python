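"""Band contributions, the GAD amplitude signature, cohort relations, and
neurofeedback protocol planning.

The signature operationalises the pattern reported at C3/C4 in adults
with generalized anxiety disorder: a depressed sensorimotor rhythm
together with beta2 amplitudes at or above the alpha amplitudes, in both
hemispheres.  Concretely, per channel:

* ``low_smr``       — SMR amplitude below beta2 (the norm expects
  SMR >= beta2);
* ``beta2_ge_alpha`` — beta2 >= (1 - tol) * alpha, where ``tol`` is an
  equivalence tolerance (default 0.10) that admits "equalised" beta/alpha
  amplitudes as the clinical reading does.

A subject is signature-positive when both components hold in both C3 and
C4.  Positivity is monotone in ``tol``.  Note the default tolerance is a
screening choice, not a validated diagnostic threshold (the source cohort
has five subjects and no controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bands import BAND_NAMES
from .errors import ConfigurationError, InputError
from .profiles import AmplitudeProfile, PatientRecord, normalize_channel
from .rules import NormativeLimits, check_asymmetry

DEFAULT_SIGNATURE_TOL = 0.10

#: Neurofeedback amplification targets, percent of the six-band amplitude sum.
ALPHA_TARGET_PCT = 16.0
SMR_TARGET_PCT = 12.0

_PLAN_NOTE = (
    "Practice guidance leaves a small residual share of activity to the "
    "beta1/beta2 range when amplifying alpha and SMR; no arithmetic "
    "adjustment is applied for it here."
)


@dataclass(frozen=True)
class ChannelSignature:
    """Per-channel components of the signature."""

    low_smr: bool
    beta2_ge_alpha: bool


@dataclass(frozen=True)
class SignatureResult:
    patient_id: str
    channels: dict[str, ChannelSignature]
    tolerance_used: float
    positive: bool


@dataclass(frozen=True)
class CohortSummary:
    """Counts of amplitude relations across a patient cohort.

    All relation counts require the relation to hold strictly in *both*
    hemispheres; ``n_asymmetry_flagged`` counts patients with at least one
    band whose C3/C4 asymmetry index exceeds the threshold.
    """

    n_patients: int
    n_beta2_gt_alpha_both: int
    n_theta_gt_delta_both: int
    n_alpha_gt_theta_both: int
    n_asymmetry_flagged: int
    n_signature_positive: int

    def __post_init__(self) -> None:
        for name in (
            "n_beta2_gt_alpha_both",
            "n_theta_gt_delta_both",
            "n_alpha_gt_theta_both",
            "n_asymmetry_flagged",
            "n_signature_positive",
        ):
            count = getattr(self, name)
            if not 0 <= count <= self.n_patients:
                raise InputError(f"{name}={count} outside [0, {self.n_patients}]")


@dataclass(frozen=True)
class BandPlan:
    direction: str  # amplify | inhibit | none
    target_contribution_pct: float | None = None


@dataclass(frozen=True)
class NeurofeedbackPlan:
    patient_id: str
    channel: str
    bands: dict[str, BandPlan]
    contributions_pct: dict[str, float]
    notes: str = field(default=_PLAN_NOTE)


def band_contributions(profile: AmplitudeProfile, channel: str) -> dict[str, float]:
    """Percent contribution of each band to the channel's six-band sum.

    Sums to 100 (within floating-point round-off) and is invariant to a
    uniform rescaling of the profile.
    """
    channel = normalize_channel(channel)
    amps = {b: profile.amplitude(channel, b) for b in BAND_NAMES}
    total = sum(amps.values())
    return {b: a / total * 100.0 for b, a in amps.items()}


def detect_signature(
    profile: AmplitudeProfile, tol: float = DEFAULT_SIGNATURE_TOL
) -> SignatureResult:
    """Screen a profile for the low-SMR / high-beta2 anxiety signature.

    Raises
    ------
    ConfigurationError
        If ``tol`` is outside [0, 0.5].
    InputError
        If the profile lacks C3 or C4.
    """
    if not 0 <= tol <= 0.5:
        raise ConfigurationError(f"signature tolerance must be in [0, 0.5], got {tol}")
    if not profile.has_channels("C3", "C4"):
        raise InputError("signature detection needs both C3 and C4")
    channels: dict[str, ChannelSignature] = {}
    for ch in ("C3", "C4"):
        smr = profile.amplitude(ch, "smr")
        beta2 = profile.amplitude(ch, "beta2")
        alpha = profile.amplitude(ch, "alpha")
        channels[ch] = ChannelSignature(
            low_smr=smr < beta2,
            beta2_ge_alpha=beta2 >= (1.0 - tol) * alpha,
        )
    positive = all(c.low_smr and c.beta2_ge_alpha for c in channels.values())
    return SignatureResult(
        patient_id=profile.patient_id,
        channels=channels,
        tolerance_used=tol,
        positive=positive,
    )


def _holds_both(profile: AmplitudeProfile, hi: str, lo: str) -> bool:
    return all(
        profile.amplitude(ch, hi) > profile.amplitude(ch, lo) for ch in ("C3", "C4")
    )


def cohort_relations(
    patients: list[PatientRecord],
    limits: NormativeLimits = NormativeLimits(),
    tol: float = DEFAULT_SIGNATURE_TOL,
) -> CohortSummary:
    """Cohort-level amplitude-relation counts over C3/C4 profiles.

    Raises
    ------
    InputError
        If the cohort is empty.
    """
    if not patients:
        raise InputError("cohort_relations needs at least one patient")
    n_beta2_gt_alpha = sum(_holds_both(p.profile, "beta2", "alpha") for p in patients)
    n_theta_gt_delta = sum(_holds_both(p.profile, "theta", "delta") for p in patients)
    n_alpha_gt_theta = sum(_holds_both(p.profile, "alpha", "theta") for p in patients)
    n_asym = sum(
        any(f.is_violation for f in check_asymmetry(p.profile, limits))
        for p in patients
    )
    n_pos = sum(detect_signature(p.profile, tol=tol).positive for p in patients)
    return CohortSummary(
        n_patients=len(patients),
        n_beta2_gt_alpha_both=n_beta2_gt_alpha,
        n_theta_gt_delta_both=n_theta_gt_delta,
        n_alpha_gt_theta_both=n_alpha_gt_theta,
        n_asymmetry_flagged=n_asym,
        n_signature_positive=n_pos,
    )


def plan_neurofeedback(
    profile: AmplitudeProfile,
    channel: str,
    limits: NormativeLimits = NormativeLimits(),
) -> NeurofeedbackPlan:
    """Derive a per-band training plan for one channel.

    Alpha is amplified toward a 16% contribution and SMR toward 12% when
    their current contribution is below the target; beta1/beta2 are
    inhibited when they break the calm-state ceiling of half the theta
    amplitude.  Contributions exactly at a target are not amplified.
    """
    channel = normalize_channel(channel)
    contrib = band_contributions(profile, channel)
    theta = profile.amplitude(channel, "theta")
    calm_ceiling = limits.calm_beta_fraction * theta
    bands: dict[str, BandPlan] = {}
    for band in BAND_NAMES:
        if band == "alpha" and contrib["alpha"] < ALPHA_TARGET_PCT:
            bands[band] = BandPlan("amplify", ALPHA_TARGET_PCT)
        elif band == "smr" and contrib["smr"] < SMR_TARGET_PCT:
            bands[band] = BandPlan("amplify", SMR_TARGET_PCT)
        elif band in ("beta1", "beta2") and profile.amplitude(channel, band) > calm_ceiling:
            bands[band] = BandPlan("inhibit")
        else:
            bands[band] = BandPlan("none")
    return NeurofeedbackPlan(
        patient_id=profile.patient_id,
        channel=channel,
        bands=bands,
        contributions_pct=contrib,
    )
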