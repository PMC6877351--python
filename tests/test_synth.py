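"""Signal generators and the electrode sensing model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neuronotch as nn
from neuronotch.errors import (
    IncompatibleTraceError,
    InvalidRateError,
    InvalidSpecificationError,
)
from neuronotch.metrics import dominant_spectral_peak


class TestPulseTrain:
    def test_one_second_at_140_hz_has_140_pulses(self):
        x = nn.gen_pulse_train(nn.StimulusSpec(), fs=1e6, duration=1.0)
        padded = np.concatenate([[0.0], x.samples])
        edges = np.sum((padded[1:] > 1.5) & (padded[:-1] <= 1.5))
        assert edges == 140

    def test_pulse_width_spans_the_expected_samples(self):
        spec = nn.StimulusSpec()
        x = nn.gen_pulse_train(spec, fs=1e6, duration=1.0)
        # first pulse starts exactly at t=0: 100 us at 1 MHz = 100 samples
        assert np.all(x.samples[:100] == spec.amplitude_pp)
        assert x.samples[101] == 0.0
        # area rendering preserves each pulse's charge exactly
        period = int(1e6 / 140)
        area = np.sum(x.samples[:period]) / spec.amplitude_pp
        assert area == pytest.approx(spec.pulse_width * 1e6, abs=1e-6)

    def test_peak_to_peak_is_the_specified_amplitude(self):
        x = nn.gen_pulse_train(nn.StimulusSpec(amplitude_pp=3.0), 1e6, 0.1)
        assert np.max(x.samples) - np.min(x.samples) == pytest.approx(3.0)

    def test_on_interval_restricts_emission(self):
        spec = nn.StimulusSpec(on_interval=(0.5, 1.0))
        x = nn.gen_pulse_train(spec, fs=100_000, duration=1.5)
        assert np.all(x.samples[: int(0.5 * 100_000) - 1] == 0.0)
        assert np.max(x.samples[int(0.5 * 100_000):]) > 0.0

    def test_pulse_wider_than_period_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            nn.StimulusSpec(frequency=140.0, pulse_width=8e-3)

    def test_low_rate_warns(self):
        with pytest.warns(UserWarning, match="fewer than 2 samples"):
            nn.gen_pulse_train(nn.StimulusSpec(), fs=10_000, duration=0.05)


@pytest.fixture(scope="module")
def lfp():
    return nn.gen_lfp(nn.LFPSpec(), fs=2000.0, duration=60.0, seed=0)


class TestLFP:
    def test_beta_peak_dominates_the_spectrum(self, lfp):
        assert 13.0 <= dominant_spectral_peak(lfp) <= 30.0

    def test_rms_matches_the_target(self, lfp):
        assert lfp.rms() == pytest.approx(0.32e-6, rel=0.01)

    def test_same_seed_reproduces_bitwise(self):
        a = nn.gen_lfp(nn.LFPSpec(), 2000.0, 5.0, seed=42)
        b = nn.gen_lfp(nn.LFPSpec(), 2000.0, 5.0, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_component_above_nyquist_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            nn.gen_lfp(nn.LFPSpec(), fs=100.0, duration=2.0)


class TestNoise:
    def test_zero_density_gives_silence(self):
        x = nn.gen_noise(nn.NoiseModel(white_density=0.0), 1000.0, 1.0)
        assert np.all(x.samples == 0.0)

    def test_white_band_rms_matches_parseval(self):
        model = nn.NoiseModel(corner_hz=0.0, seed=5)
        x = nn.gen_noise(model, fs=2000.0, duration=100.0)
        f = np.fft.rfftfreq(len(x), 1 / x.fs)
        X = np.fft.rfft(x.samples)
        psd = 2 * np.abs(X) ** 2 / (len(x) * x.fs)
        band = (f >= 0.5) & (f <= 500.0)
        rms_band = np.sqrt(np.sum(psd[band]) * x.fs / len(x))
        expected = np.sqrt(model.white_density * 499.5)
        assert rms_band == pytest.approx(expected, rel=0.03)

    def test_flicker_slope_below_the_corner(self):
        x = nn.gen_noise(nn.NoiseModel(seed=1), fs=200.0, duration=400.0)
        from scipy.signal import welch

        f, p = welch(x.samples, fs=200.0, nperseg=1 << 14)
        sel = (f >= 0.05) & (f <= 1.0)
        slope, _ = nn.slope_db_per_decade(f[sel], 10 * np.log10(p[sel]))
        assert slope == pytest.approx(-10.0, abs=2.0)

    def test_energy_bookkeeping_parseval(self):
        x = nn.gen_noise(nn.NoiseModel(seed=2), fs=1000.0, duration=10.0)
        time_rms = x.rms()
        X = np.fft.rfft(x.samples)
        n = len(x)
        w = np.full(X.size, 2.0)
        w[0] = 1.0
        if n % 2 == 0:
            w[-1] = 1.0
        spec_rms = np.sqrt(np.sum(w * np.abs(X) ** 2)) / n
        assert spec_rms == pytest.approx(time_rms, rel=1e-6)

    def test_seeded_determinism(self):
        a = nn.gen_noise(nn.NoiseModel(seed=9), 1000.0, 2.0)
        b = nn.gen_noise(nn.NoiseModel(seed=9), 1000.0, 2.0)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestResample:
    def _tone(self, f, fs=1e6, duration=0.5):
        t = np.arange(int(duration * fs)) / fs
        return nn.SignalTrace(np.sin(2 * np.pi * f * t), fs)

    def test_below_nyquist_tone_is_unchanged_in_frequency(self):
        y = nn.resample_no_antialias(self._tone(9000.0), 20_000.0)
        assert dominant_spectral_peak(y, f_min=100.0) == pytest.approx(
            9000.0, abs=20.0
        )

    def test_above_nyquist_tone_folds(self):
        y = nn.resample_no_antialias(self._tone(11_000.0), 20_000.0)
        assert dominant_spectral_peak(y, f_min=100.0) == pytest.approx(
            9000.0, abs=20.0
        )

    def test_pulse_train_gains_non_harmonic_lines(self):
        x = nn.gen_pulse_train(nn.StimulusSpec(), fs=20_000.0, duration=10.0)
        y = nn.resample_no_antialias(x, 1000.0)
        spec_orig = nn.amplitude_spectrum(x)
        spec_dec = nn.amplitude_spectrum(y)
        # the 840 Hz harmonic folds to 160 Hz, which is not a multiple of 140
        assert spec_dec.level_at(160.0) > spec_orig.level_at(160.0) + 40.0

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(InvalidRateError):
            nn.resample_no_antialias(self._tone(100.0, fs=1000.0), 300.0)


class TestSense:
    def _traces(self, n=2000, fs=20_000.0, seed=0):
        rng = np.random.default_rng(seed)
        lfp = nn.SignalTrace(rng.standard_normal(n) * 1e-6, fs)
        art = nn.gen_pulse_train(nn.StimulusSpec(), fs, n / fs)
        return lfp, art

    def test_symmetric_sensing_keeps_artefact_out_of_v_diff(self):
        lfp, art = self._traces()
        spec = nn.SensingSpec(asymmetry=0.0).without_offsets()
        out = nn.sense(lfp, art, spec)
        np.testing.assert_array_equal(out.v_diff.samples, lfp.samples)

    def test_cmrr_leakage_is_exact(self):
        lfp, art = self._traces()
        spec = nn.SensingSpec(asymmetry=0.0).without_offsets()
        out = nn.sense(lfp, art, spec)
        eff = out.effective_input(130.0)
        leak = eff.samples - out.v_diff.samples
        np.testing.assert_allclose(
            leak, out.v_cm.samples * 10 ** (-130.0 / 20), rtol=1e-9, atol=1e-20
        )

    def test_bipolar_couples_more_artefact_than_unipolar(self):
        lfp, art = self._traces()
        uni = nn.sense(lfp, art, nn.UNIPOLAR_SENSING.without_offsets())
        bip = nn.sense(lfp, art, nn.BIPOLAR_SENSING.without_offsets())
        p_uni = np.mean((uni.v_diff.samples - lfp.samples) ** 2)
        p_bip = np.mean((bip.v_diff.samples - lfp.samples) ** 2)
        assert p_bip > p_uni

    def test_mode_decomposition_is_exact(self):
        lfp, art = self._traces()
        out = nn.sense(lfp, art, nn.BIPOLAR_SENSING)
        np.testing.assert_allclose(
            out.v_pos.samples - out.v_neg.samples, out.v_diff.samples,
            rtol=1e-12, atol=1e-16,
        )
        np.testing.assert_allclose(
            (out.v_pos.samples + out.v_neg.samples) / 2, out.v_cm.samples,
            rtol=1e-12, atol=1e-16,
        )

    @given(a=st.floats(0.1, 5.0), b=st.floats(0.1, 5.0))
    def test_linearity_in_both_inputs(self, a, b):
        lfp, art = self._traces(n=400)
        spec = nn.BIPOLAR_SENSING.without_offsets()
        combined = nn.sense(a * lfp, b * art, spec)
        base_lfp = nn.sense(lfp, nn.SignalTrace(np.zeros(400), lfp.fs), spec)
        base_art = nn.sense(nn.SignalTrace(np.zeros(400), lfp.fs), art, spec)
        np.testing.assert_allclose(
            combined.v_diff.samples,
            a * base_lfp.v_diff.samples + b * base_art.v_diff.samples,
            rtol=1e-12, atol=1e-18,
        )

    def test_mismatched_traces_rejected(self):
        lfp, _ = self._traces()
        art = nn.SignalTrace(np.zeros(10), 1000.0)
        with pytest.raises(IncompatibleTraceError):
            nn.sense(lfp, art, nn.SensingSpec())
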