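"""Measurement battery: transients, spectra, noise, distortion, RMSE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neuronotch as nn
from neuronotch.channel import ChannelModel
from neuronotch.errors import (
    IncompatibleTraceError,
    InsufficientLevelError,
    InvalidArgumentError,
    UndefinedNormalizationError,
)
from neuronotch.metrics import (
    SPECTRUM_FLOOR_DB,
    cubic_ip3_closed_form,
)
from neuronotch.stages import GainStageSpec, design_gain_stage, design_preamp


@pytest.fixture(scope="module")
def preamp_path_digital():
    """Isolated pre-amplifier followed by a static 20 dB stage."""
    gain = GainStageSpec(20.0)
    model = ChannelModel(
        "no_notch",
        (design_preamp(), design_gain_stage(gain)),
        60.0,
        gain,
    )
    return nn.discretize(model, 20_000.0)


class TestAnalyticFormulas:
    def test_rise_and_settling_closed_forms(self):
        assert nn.analytic_rise_time(1e6, 270e-9) == pytest.approx(0.594,
                                                                   abs=1e-12)
        assert nn.analytic_settling_time(1e6, 270e-9) == pytest.approx(
            1.08, abs=1e-12
        )

    def test_zero_capacitance_gives_zero(self):
        assert nn.analytic_rise_time(1e6, 0.0) == 0.0

    def test_negative_arguments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nn.analytic_rise_time(-1.0, 1.0)


class TestTransient:
    def test_preamp_step_matches_the_first_order_formula(
        self, preamp_path_digital
    ):
        res, _ = nn.transient(preamp_path_digital, "step", amplitude=2.1e-3,
                              plateau_gain=1000.0)
        assert res.rise_time == pytest.approx(nn.analytic_rise_time(1e6, 270e-9),
                                              rel=0.05)
        assert res.settling_time == pytest.approx(
            nn.analytic_settling_time(1e6, 270e-9), rel=0.05
        )

    @pytest.mark.parametrize("channel", ["cheb_digital", "bessel_digital"])
    def test_biphasic_settles_faster_than_impulse(self, channel, request):
        dig = request.getfixturevalue(channel)
        imp, _ = nn.transient(dig, "impulse")
        bip, _ = nn.transient(dig, "biphasic")
        assert bip.settling_time < imp.settling_time

    def test_chebyshev_step_overshoots_at_least_as_much_as_bessel(
        self, cheb_digital, bessel_digital
    ):
        cheb, _ = nn.transient(cheb_digital, "step")
        bess, _ = nn.transient(bessel_digital, "step")
        assert cheb.overshoot >= bess.overshoot


class TestAmplitudeSpectrum:
    def test_on_bin_tone_calibration(self):
        fs, A, f0 = 1000.0, 0.5, 50.0
        t = np.arange(int(20 * fs)) / fs
        x = nn.SignalTrace(A * np.sin(2 * np.pi * f0 * t), fs)
        level = nn.amplitude_spectrum(x).level_at(f0)
        assert level == pytest.approx(20 * np.log10(A / np.sqrt(2)), abs=0.02)

    def test_off_bin_tone_scalloping_is_small_with_flattop(self):
        fs, A = 1000.0, 1.0
        f0 = 50.0257  # deliberately between bins
        t = np.arange(int(20 * fs)) / fs
        x = nn.SignalTrace(A * np.sin(2 * np.pi * f0 * t), fs)
        level = nn.amplitude_spectrum(x).level_at(f0)
        assert level == pytest.approx(20 * np.log10(A / np.sqrt(2)), abs=0.02)

    def test_zero_trace_sits_at_the_guarded_floor(self):
        x = nn.SignalTrace(np.zeros(4096), 1000.0)
        spec = nn.amplitude_spectrum(x)
        assert np.all(spec.amplitude_db == SPECTRUM_FLOOR_DB)

    def test_empty_nfft_rejected(self):
        x = nn.SignalTrace(np.zeros(16), 1000.0)
        with pytest.raises(InvalidArgumentError):
            nn.amplitude_spectrum(x, nfft=32)


class TestIntegratedNoise:
    def test_default_model_over_the_recording_band(self):
        rms = nn.integrated_noise_rms(nn.NoiseModel(), 0.5, 500.0)
        assert rms == pytest.approx(95.4e-9, rel=0.005)

    def test_white_only_narrow_band(self):
        model = nn.NoiseModel(corner_hz=0.0)
        rms = nn.integrated_noise_rms(model, 0.5, 40.0)
        assert rms == pytest.approx(np.sqrt(16e-18 * 39.5), rel=1e-9)
        assert rms == pytest.approx(25.1e-9, rel=0.01)

    def test_degenerate_band_is_zero(self):
        assert nn.integrated_noise_rms(nn.NoiseModel(), 10.0, 10.0) == 0.0

    def test_dc_lower_edge_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nn.integrated_noise_rms(nn.NoiseModel(), 0.0, 100.0)

    @given(
        f_hi=st.floats(10.0, 1000.0),
        s0=st.floats(1e-18, 1e-15),
        fc=st.floats(0.0, 100.0),
    )
    def test_monotone_in_bandwidth_and_parameters(self, f_hi, s0, fc):
        base = nn.NoiseModel(white_density=s0, corner_hz=fc)
        more_band = nn.integrated_noise_rms(base, 0.5, f_hi * 1.5)
        assert nn.integrated_noise_rms(base, 0.5, f_hi) <= more_band
        louder = nn.NoiseModel(white_density=s0 * 2, corner_hz=fc)
        pinker = nn.NoiseModel(white_density=s0, corner_hz=fc + 1)
        assert nn.integrated_noise_rms(base, 0.5, f_hi) <= \
            nn.integrated_noise_rms(louder, 0.5, f_hi)
        assert nn.integrated_noise_rms(base, 0.5, f_hi) <= \
            nn.integrated_noise_rms(pinker, 0.5, f_hi)


class TestTHD:
    fs = 5000.0

    def _tone(self, A, f0=15.0, duration=40.0):
        t = np.arange(int(duration * self.fs)) / self.fs
        return nn.SignalTrace(A * np.sin(2 * np.pi * f0 * t), self.fs)

    def test_linear_channel_adds_no_harmonics(self, cheb_model):
        dig = nn.discretize(cheb_model, self.fs)
        y = nn.apply(dig, self._tone(1e-3))
        assert nn.thd(y, 15.0).thd_percent < 1e-3

    def test_cubic_matches_the_small_distortion_expansion(self):
        a3, A = 0.1, 0.5
        x = self._tone(A)
        y = nn.SignalTrace(x.samples + a3 * x.samples**3, self.fs)
        res = nn.thd(y, 15.0)
        hd3 = a3 * A**2 / 4
        expected = 100 * hd3 / (1 + 3 * a3 * A**2 / 4)
        assert res.thd_percent == pytest.approx(expected, rel=0.01)

    def test_default_nonlinearity_keeps_thd_below_bound(self, cheb_digital):
        nl = nn.NonlinearitySpec()
        dig = nn.discretize(nn.build_channel("chebyshev", 60), self.fs)
        y = nn.apply(dig, self._tone(2.3e-3), nl)
        assert nn.thd(y, 15.0).thd_percent <= 0.2

    def test_thd_is_gain_invariant_for_the_same_nonlinearity_node(self):
        nl = nn.NonlinearitySpec()
        x = self._tone(1e-4)
        res = {}
        for gain in (60, 80):
            dig = nn.discretize(nn.build_channel("chebyshev", gain), self.fs)
            res[gain] = nn.thd(nn.apply(dig, x, nl), 15.0).thd_percent
        assert res[60] == pytest.approx(res[80], rel=0.02)

    def test_unresolvable_fundamental_rejected(self):
        from neuronotch.errors import ResolutionError

        with pytest.raises(ResolutionError):
            nn.thd(self._tone(1e-3, duration=0.1), 15.0)


class TestIP3:
    def test_channel_sweep_recovers_canonical_slopes(self, cheb_model):
        dig = nn.discretize(cheb_model, 5000.0)
        nl = nn.NonlinearitySpec()
        res = nn.ip3(
            lambda x: nn.apply(dig, x, nl),
            input_levels=np.geomspace(3e-5, 1e-3, 7),
            fs=5000.0,
        )
        assert res.fundamental_slope == pytest.approx(1.0, abs=0.05)
        assert res.imd3_slope == pytest.approx(3.0, abs=0.1)

    def test_pure_cubic_intercept_matches_closed_form(self):
        a3 = 0.1
        res = nn.ip3(
            lambda x: nn.SignalTrace(x.samples + a3 * x.samples**3, x.fs),
            input_levels=np.geomspace(1e-3, 3e-2, 7),
            fs=5000.0,
        )
        assert res.intercept_input_dbm == pytest.approx(
            cubic_ip3_closed_form(a3), abs=0.5
        )

    def test_slopes_do_not_depend_on_reference_impedance(self):
        a3 = 0.1
        out = {}
        for z in (50.0, 600.0):
            out[z] = nn.ip3(
                lambda x: nn.SignalTrace(x.samples + a3 * x.samples**3, x.fs),
                input_levels=np.geomspace(1e-3, 1e-2, 5),
                fs=5000.0,
                reference_impedance=z,
            )
        assert out[50.0].fundamental_slope == pytest.approx(
            out[600.0].fundamental_slope, abs=1e-6
        )
        assert out[50.0].imd3_slope == pytest.approx(
            out[600.0].imd3_slope, abs=1e-6
        )

    def test_linear_system_has_no_measurable_products(self):
        with pytest.raises(InsufficientLevelError):
            nn.ip3(
                lambda x: x,
                input_levels=np.geomspace(1e-3, 1e-2, 5),
                fs=5000.0,
            )


class TestNormalizedRMSE:
    def test_identical_traces_score_zero(self):
        x = nn.SignalTrace(np.sin(np.linspace(0, 20, 1000)), 100.0)
        assert nn.normalized_rmse(x, x).nrmse_percent == 0.0

    def test_hand_computed_offset_example(self):
        ref = nn.SignalTrace(np.tile([0.0, 1.0, 0.0, -1.0], 64), 100.0)
        test = ref + 0.1
        assert nn.normalized_rmse(test, ref).nrmse_percent == pytest.approx(5.0)

    def test_scaled_sine_closed_form(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        ref = nn.SignalTrace(np.sin(2 * np.pi * 5.0 * t), fs)
        test = 1.01 * ref
        expected = 100 * 0.01 * ref.rms() / (np.max(ref.samples)
                                             - np.min(ref.samples))
        assert nn.normalized_rmse(test, ref).nrmse_percent == pytest.approx(
            expected, rel=1e-6
        )

    def test_constant_reference_rejected(self):
        ref = nn.SignalTrace(np.ones(100), 100.0)
        with pytest.raises(UndefinedNormalizationError):
            nn.normalized_rmse(ref, ref)

    def test_mismatched_traces_rejected(self):
        a = nn.SignalTrace(np.zeros(10), 100.0)
        b = nn.SignalTrace(np.zeros(20), 100.0)
        with pytest.raises(IncompatibleTraceError):
            nn.normalized_rmse(a, b)

    @given(st.integers(0, 2**31 - 1))
    def test_triangle_bound_for_shared_reference_range(self, seed):
        rng = np.random.default_rng(seed)
        base = np.concatenate([rng.standard_normal(62), [3.0, -3.0]])
        y = np.concatenate([rng.standard_normal(62), [3.0, -3.0]])
        z = np.concatenate([rng.standard_normal(62), [3.0, -3.0]])
        fs = 100.0
        x_t, y_t, z_t = (nn.SignalTrace(v, fs) for v in (base, y, z))
        lhs = nn.normalized_rmse(x_t, z_t).nrmse_percent
        rhs = (nn.normalized_rmse(x_t, y_t).nrmse_percent
               + nn.normalized_rmse(y_t, z_t).nrmse_percent)
        assert lhs <= rhs + 1e-9


def test_slope_fit_recovers_an_exact_line():
    f = np.geomspace(1.0, 100.0, 30)
    mag = -40.0 * np.log10(f) + 7.0
    slope, resid = nn.slope_db_per_decade(f, mag)
    assert slope == pytest.approx(-40.0, abs=1e-9)
    assert resid == pytest.approx(0.0, abs=1e-9)
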