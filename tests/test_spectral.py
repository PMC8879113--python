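"""Spectral quantification: montage, Welch spectra, band amplitudes."""

import numpy as np
import pytest

from qeegkit import DEFAULT_SCHEME, Recording, quantify, rereference_to_cz
from qeegkit.errors import ConfigurationError, InputError, ValidationError
from qeegkit.spectral import amplitude_spectrum, band_amplitude, band_power

from conftest import FS, make_recording, make_tone, time_domain_band_amplitude


class TestRereference:
    def test_channel_equal_to_cz_becomes_zero(self):
        s = make_tone(10.0, 5.0)
        rec = make_recording({"C3": s.copy(), "CZ": s.copy()}, reference="common-average")
        out = rereference_to_cz(rec)
        assert out.channel_labels == ["C3"]
        assert np.allclose(out.channel("C3"), 0.0)
        assert out.reference_label == "CZ"

    def test_additive_identity(self):
        cz = make_tone(3.0, 2.0)
        s = make_tone(10.0, 5.0)
        rec = make_recording({"C3": cz + s, "CZ": cz}, reference="common-average")
        out = rereference_to_cz(rec)
        assert np.allclose(out.channel("C3"), s)

    def test_idempotent_with_warning(self):
        rec = make_recording({"C3": make_tone(10.0, 5.0)}, reference="CZ")
        with pytest.warns(UserWarning, match="already Cz-referenced"):
            out = rereference_to_cz(rec)
        assert out is rec

    def test_missing_cz_is_configuration_error(self):
        rec = make_recording({"C3": make_tone(10.0, 5.0)}, reference="common-average")
        with pytest.raises(ConfigurationError, match="CZ"):
            rereference_to_cz(rec)


class TestAmplitudeSpectrum:
    def test_tone_mass_concentrates_at_tone_frequency(self):
        spec = amplitude_spectrum(make_tone(10.0, 10.0), FS, window_seconds=4.0)
        peak_freq = spec.frequencies[np.argmax(spec.power_density)]
        assert peak_freq == pytest.approx(10.0, abs=spec.df)
        near = np.abs(spec.frequencies - 10.0) <= 1.0
        total = np.sum(spec.power_density) * spec.df
        assert np.sum(spec.power_density[near]) * spec.df / total > 0.99

    def test_zero_signal_gives_zero_spectrum(self):
        spec = amplitude_spectrum(np.zeros(int(60 * FS)), FS)
        assert np.all(spec.power_density == 0.0)

    def test_parseval_total_power_matches_time_domain_variance(self):
        rng = np.random.default_rng(11)
        x = make_tone(6.0, 5.0) + make_tone(22.0, 3.0) + rng.standard_normal(int(60 * FS))
        spec = amplitude_spectrum(x, FS)
        total_power = float(np.sum(spec.power_density) * spec.df)
        assert total_power == pytest.approx(np.var(x), rel=0.02)

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputError, match="shorter than"):
            amplitude_spectrum(np.zeros(100), FS, window_seconds=4.0)

    def test_bad_sampling_rate_rejected(self):
        with pytest.raises(InputError):
            amplitude_spectrum(np.zeros(1000), 0.0)

    def test_bad_overlap_rejected(self):
        with pytest.raises(InputError):
            amplitude_spectrum(np.zeros(int(60 * FS)), FS, overlap_fraction=1.0)


class TestBandAmplitude:
    @pytest.mark.parametrize("band", DEFAULT_SCHEME.names)
    def test_mid_band_tone_is_recovered(self, band):
        bdef = DEFAULT_SCHEME[band]
        spec = amplitude_spectrum(make_tone(bdef.center, 10.0), FS)
        assert band_amplitude(spec, bdef) == pytest.approx(10.0, rel=0.05)

    def test_out_of_band_tone_contributes_nothing(self):
        spec = amplitude_spectrum(make_tone(10.0, 10.0), FS)
        assert band_amplitude(spec, DEFAULT_SCHEME["beta2"]) < 0.5

    def test_two_tone_split_against_time_domain_oracle(self):
        x = make_tone(2.0, 6.0) + make_tone(25.0, 8.0, phase=1.1)
        spec = amplitude_spectrum(x, FS)
        delta, beta2 = DEFAULT_SCHEME["delta"], DEFAULT_SCHEME["beta2"]
        assert band_amplitude(spec, delta) == pytest.approx(6.0, rel=0.05)
        assert band_amplitude(spec, beta2) == pytest.approx(8.0, rel=0.05)
        assert band_amplitude(spec, delta) == pytest.approx(
            time_domain_band_amplitude(x, delta.f_lo, delta.f_hi), rel=0.05
        )
        assert band_amplitude(spec, beta2) == pytest.approx(
            time_domain_band_amplitude(x, beta2.f_lo, beta2.f_hi), rel=0.05
        )

    def test_amplitude_is_linear_in_signal_scale(self):
        x = make_tone(10.0, 5.0) + make_tone(17.0, 3.0)
        spec1 = amplitude_spectrum(x, FS)
        spec2 = amplitude_spectrum(2.0 * x, FS)
        for band in DEFAULT_SCHEME:
            a1, a2 = band_amplitude(spec1, band), band_amplitude(spec2, band)
            if a1 > 1e-12:
                assert a2 == pytest.approx(2.0 * a1, rel=0.01)

    def test_band_beyond_nyquist_rejected(self):
        spec = amplitude_spectrum(make_tone(5.0, 1.0, fs=50.0), 50.0)
        with pytest.raises(InputError, match="Nyquist"):
            band_power(spec, DEFAULT_SCHEME["beta2"])


class TestQuantify:
    def _recording(self, c3_extra=0.0):
        signals = {
            "C3": make_tone(10.0, 8.0) + make_tone(25.0, 4.0) + c3_extra,
            "C4": make_tone(6.0, 7.0) + make_tone(13.5, 5.0),
            "CZ": np.zeros(int(60 * FS)),
        }
        return make_recording(signals, reference="common-average")

    def test_profile_recovers_tone_amplitudes(self):
        prof = quantify(self._recording())
        assert prof.amplitude("C3", "alpha") == pytest.approx(8.0, rel=0.05)
        assert prof.amplitude("C3", "beta2") == pytest.approx(4.0, rel=0.05)
        assert prof.amplitude("C4", "theta") == pytest.approx(7.0, rel=0.05)
        assert prof.amplitude("C4", "smr") == pytest.approx(5.0, rel=0.05)

    def test_channel_order_does_not_matter(self):
        rec = self._recording()
        flipped = Recording(
            channel_labels=rec.channel_labels[::-1],
            sampling_rate=rec.sampling_rate,
            samples=rec.samples[::-1].copy(),
            reference_label=rec.reference_label,
        )
        assert quantify(rec).entries == quantify(flipped).entries

    def test_deterministic_across_runs(self):
        rec = self._recording()
        assert quantify(rec).entries == quantify(rec).entries

    def test_all_zero_recording_is_rejected(self):
        rec = make_recording(
            {"C3": np.zeros(int(60 * FS)), "C4": np.zeros(int(60 * FS))},
            reference="CZ",
        )
        with pytest.raises(ValidationError, match="degenerate"):
            quantify(rec)

    def test_missing_channel_is_named_in_error(self):
        rec = make_recording({"C3": make_tone(10.0, 8.0)}, reference="CZ")
        with pytest.raises(InputError, match="C4"):
            quantify(rec)

    def test_insufficient_sampling_rate_rejected(self):
        rec = make_recording({"C3": make_tone(5.0, 8.0, fs=50.0, duration=60)}, fs=50.0)
        with pytest.raises(InputError, match="sampling rate"):
            quantify(rec)

    def test_epoch_rejection_drops_artifact_epochs(self):
        x = make_tone(10.0, 8.0)
        x[1000:1010] += 500.0  # one artifact burst
        rec = make_recording({"C3": x, "C4": make_tone(10.0, 8.0)}, reference="CZ")
        clean = quantify(rec, reject_peak_uv=100.0)
        dirty = quantify(rec)
        assert clean.amplitude("C3", "alpha") == pytest.approx(8.0, rel=0.05)
        # without rejection the burst inflates broadband power
        assert dirty.amplitude("C3", "beta2") > clean.amplitude("C3", "beta2")
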