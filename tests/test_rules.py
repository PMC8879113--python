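"""Normative rule engine: asymmetry index, limits, orderings, dominance."""

import pytest
from hypothesis import given, settings, strategies as st

from qeegkit import AmplitudeProfile, DEFAULT_SCHEME, NormativeLimits, asymmetry_index, evaluate
from qeegkit.errors import InputError
from qeegkit.rules import (
    INFO,
    check_absolute_limits,
    check_asymmetry,
    check_dominance,
    check_ordering,
)

amplitudes = st.floats(min_value=0.1, max_value=100.0, allow_nan=False)


def _by_key(findings):
    return {(f.rule_id, f.channel, f.band): f for f in findings}


class TestAsymmetryIndex:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            (7.94, 11.1, 39.80),   # AD alpha, flagged
            (5.86, 8.57, 46.25),   # SK SMR, flagged
            (11.38, 19.75, 73.55), # SK beta2, flagged
            (10.93, 8.87, 23.22),  # GP delta, flagged
        ],
    )
    def test_hand_computed_fixture_indices(self, left, right, expected):
        assert asymmetry_index(left, right) == pytest.approx(expected, abs=0.005)

    def test_zero_at_equality(self):
        assert asymmetry_index(6.283, 6.283) == 0.0

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(InputError):
            asymmetry_index(0.0, 5.0)
        with pytest.raises(InputError):
            asymmetry_index(5.0, -1.0)

    @settings(derandomize=True, max_examples=200)
    @given(a=amplitudes, b=amplitudes)
    def test_symmetric(self, a, b):
        assert asymmetry_index(a, b) == asymmetry_index(b, a)

    @settings(derandomize=True, max_examples=200)
    @given(a=amplitudes, b=amplitudes, c=st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_invariant(self, a, b, c):
        assert asymmetry_index(a * c, b * c) == pytest.approx(
            asymmetry_index(a, b), rel=1e-9, abs=1e-9
        )


class TestAbsoluteLimits:
    def test_ad_beta2_exceeds_fast_ceiling(self, ad_profile, limits):
        findings = _by_key(check_absolute_limits(ad_profile, limits))
        assert findings[("ABS_LIMIT", "C3", "beta2")].is_violation
        assert findings[("ABS_LIMIT", "C4", "beta2")].is_violation
        assert findings[("ABS_LIMIT", "C4", "alpha")].is_violation  # 11.1 >= 10
        assert not findings[("ABS_LIMIT", "C3", "delta")].is_violation

    def test_td_smr_below_fast_floor(self, patients_by_id, limits):
        findings = _by_key(check_absolute_limits(patients_by_id["TD"].profile, limits))
        assert findings[("ABS_LIMIT", "C3", "smr")].is_violation  # 3.51 < 4
        assert findings[("ABS_LIMIT", "C4", "smr")].is_violation

    def test_in_range_profile_has_no_violations(self, conforming_profile, limits):
        assert not any(
            f.is_violation for f in check_absolute_limits(conforming_profile, limits)
        )


class TestOrdering:
    def test_ad_theta_over_delta_is_flagged(self, ad_profile, limits):
        findings = _by_key(check_ordering(ad_profile, "C3", limits))
        assert findings[("ORDER_DELTA_THETA", "C3", "delta/theta")].is_violation

    def test_gg_alpha_over_theta_is_flagged(self, patients_by_id, limits):
        findings = _by_key(check_ordering(patients_by_id["GG"].profile, "C3", limits))
        assert findings[("ORDER_THETA_ALPHA", "C3", "theta/alpha")].is_violation

    def test_conforming_profile_passes_all_nine(self, conforming_profile, limits):
        findings = check_ordering(conforming_profile, "C3", limits)
        assert len(findings) == 9
        assert not any(f.is_violation for f in findings)

    def test_calm_state_boundary_is_inclusive(self, conforming_profile, limits):
        # beta1 = 4.2 <= theta/2 = 4.5 passes; a profile at 4.5 exactly passes too
        entries = dict(conforming_profile.entries)
        entries[("C3", "beta1")] = 4.5
        prof = AmplitudeProfile("X", conforming_profile.scheme_id, entries)
        findings = _by_key(check_ordering(prof, "C3", limits))
        assert not findings[("CALM_BETA_HALF_THETA", "C3", "beta1")].is_violation


class TestAsymmetryCheck:
    def test_ad_alpha_asymmetry_flagged(self, ad_profile, limits):
        findings = _by_key(check_asymmetry(ad_profile, limits))
        assert findings[("ASYMMETRY", "C3/C4", "alpha")].is_violation

    def test_sk_smr_and_beta_flagged(self, patients_by_id, limits):
        findings = _by_key(check_asymmetry(patients_by_id["SK"].profile, limits))
        assert findings[("ASYMMETRY", "C3/C4", "smr")].is_violation
        assert findings[("ASYMMETRY", "C3/C4", "beta2")].is_violation
        assert findings[("ASYMMETRY", "C3/C4", "beta2")].observed[2] == pytest.approx(
            73.55, abs=0.005
        )

    def test_td_has_no_asymmetry_violations(self, patients_by_id, limits):
        findings = check_asymmetry(patients_by_id["TD"].profile, limits)
        assert not any(f.is_violation for f in findings)
        assert max(f.observed[2] for f in findings) == pytest.approx(18.81, abs=0.01)

    def test_tie_at_threshold_is_not_flagged(self, limits):
        entries = {("C3", b): 10.0 for b in DEFAULT_SCHEME.names}
        entries.update({("C4", b): 12.0 for b in DEFAULT_SCHEME.names})  # exactly 20%
        prof = AmplitudeProfile("T", DEFAULT_SCHEME.scheme_id, entries)
        assert not any(f.is_violation for f in check_asymmetry(prof, limits))


class TestDominance:
    def _two_channel(self, c3_beta1, c4_beta1):
        bands = {"delta": 12.0, "theta": 9.0, "alpha": 8.0, "smr": 7.0,
                 "beta1": None, "beta2": 4.1}
        entries = {}
        for ch, b1 in (("C3", c3_beta1), ("C4", c4_beta1)):
            for b, v in bands.items():
                entries[(ch, b)] = b1 if b == "beta1" else v
        return AmplitudeProfile("D", DEFAULT_SCHEME.scheme_id, entries)

    def test_above_margin_fast_excess_is_violation(self, limits):
        findings = _by_key(check_dominance(self._two_channel(9.0, 5.0), "left", limits))
        assert findings[("DOMINANCE", "C3/C4", "beta1")].is_violation  # +80%

    def test_within_margin_fast_excess_passes(self, limits):
        findings = _by_key(check_dominance(self._two_channel(7.0, 5.0), "left", limits))
        assert not findings[("DOMINANCE", "C3/C4", "beta1")].is_violation  # +40%

    def test_sk_beta2_nondominant_excess_is_informational(self, patients_by_id, limits):
        findings = _by_key(check_dominance(patients_by_id["SK"].profile, "left", limits))
        f = findings[("DOMINANCE", "C3/C4", "beta2")]
        assert f.status == INFO and not f.is_violation

    def test_bad_side_rejected(self, conforming_profile, limits):
        with pytest.raises(InputError):
            check_dominance(conforming_profile, "up", limits)


class TestEvaluate:
    def test_report_has_complete_finding_counts(self, ad_profile, limits):
        report = evaluate(ad_profile, limits)
        counts = {}
        for f in report.findings:
            counts[f.rule_id] = counts.get(f.rule_id, 0) + 1
        assert counts["ABS_LIMIT"] == 12
        assert counts["ASYMMETRY"] == 6
        assert counts["DOMINANCE"] == 6
        ordering = sum(v for k, v in counts.items()
                       if k not in ("ABS_LIMIT", "ASYMMETRY", "DOMINANCE"))
        assert ordering == 18
        assert len(report.findings) == 42

    def test_ad_report_matches_case_narrative(self, ad_profile, limits):
        keys = evaluate(ad_profile, limits).violation_keys()
        assert ("ORDER_DELTA_THETA", "C3", "delta/theta") in keys
        assert ("ORDER_DELTA_THETA", "C4", "delta/theta") in keys
        assert ("ASYMMETRY", "C3/C4", "alpha") in keys
        assert ("ABS_LIMIT", "C3", "beta2") in keys
        assert ("ABS_LIMIT", "C4", "beta2") in keys

    def test_gp_report_matches_case_narrative(self, patients_by_id, limits):
        keys = evaluate(patients_by_id["GP"].profile, limits).violation_keys()
        assert ("ORDER_DELTA_THETA", "C3", "delta/theta") in keys
        assert ("ORDER_DELTA_THETA", "C4", "delta/theta") in keys
        asym = [k for k in keys if k[0] == "ASYMMETRY"]
        assert asym == [("ASYMMETRY", "C3/C4", "delta")]

    def test_conforming_profile_has_zero_violations(self, conforming_profile, limits):
        report = evaluate(conforming_profile, limits)
        assert report.n_violations == 0

    def test_evaluation_is_pure(self, ad_profile, limits):
        assert evaluate(ad_profile, limits) == evaluate(ad_profile, limits)

    def test_findings_are_deterministically_ordered(self, ad_profile, limits):
        report = evaluate(ad_profile, limits)
        keys = [(f.rule_id, f.channel, f.band) for f in report.findings]
        assert keys == sorted(keys)
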