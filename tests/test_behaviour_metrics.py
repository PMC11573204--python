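"""Behavioural metrics: RMSE, SPARC (vs independent oracle), lag, EMG."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapticdyad.behaviour_metrics import (
    EmgCalibration,
    MetricConfig,
    cocontraction,
    emg_to_torque,
    fit_emg_calibration,
    normalise_cocontraction,
    rmse,
    sparc,
    xcorr_delay,
)
from hapticdyad.target_trajectory import target_position


def sparc_oracle(movement, fs=100.0, padlevel=4, fc=10.0, amp_th=0.05):
    """Independent transcription of the published spectral-arc-length
    definition, kept deliberately separate from the implementation."""
    nfft = int(pow(2, np.ceil(np.log2(len(movement))) + padlevel))
    f = np.arange(0, fs, fs / nfft)
    Mf = abs(np.fft.fft(movement, nfft))
    Mf = Mf / max(Mf)
    fc_inx = ((f <= fc) * 1).nonzero()[0]
    f_sel, Mf_sel = f[fc_inx], Mf[fc_inx]
    inx = ((Mf_sel >= amp_th) * 1).nonzero()[0]
    fc_inx = range(inx[0], inx[-1] + 1)
    f_sel, Mf_sel = f_sel[fc_inx], Mf_sel[fc_inx]
    new_sal = -sum(
        np.sqrt(pow(np.diff(f_sel) / (f_sel[-1] - f_sel[0]), 2)
                + pow(np.diff(Mf_sel), 2)))
    return new_sal


class TestRmse:
    def test_identical_series_zero(self):
        x = np.sin(np.linspace(0, 5, 100))
        assert rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros(50)
        assert rmse(x + np.deg2rad(3.0), x) == pytest.approx(3.0)

    def test_zero_response_against_full_target(self):
        # numeric oracle: RMS of the product-of-sines over 30 s; close
        # to the A/2 long-window limit of 9.25 deg
        t = np.arange(0, 30.0 + 1e-9, 0.01)
        target = target_position(t)
        oracle = np.rad2deg(np.sqrt(np.mean(target ** 2)))
        assert rmse(np.zeros_like(t), target) == pytest.approx(oracle)
        assert oracle == pytest.approx(9.25, abs=0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=50))
    def test_nonnegative(self, vals):
        x = np.asarray(vals)
        assert rmse(x, np.zeros_like(x)) >= 0.0


class TestSparc:
    @pytest.fixture()
    def smooth_speed(self, rng):
        t = np.linspace(0, 3, 300)
        return np.abs(np.sin(np.pi * t / 3.0)) + 0.1

    def test_matches_independent_oracle_on_random_signals(self, rng):
        cfg = MetricConfig()
        for _ in range(50):
            n = int(rng.integers(100, 2000))
            t = np.linspace(0, 1, n)
            freqs = rng.uniform(0.3, 4.0, 4)
            amps = rng.uniform(0.2, 1.0, 4)
            v = np.abs(sum(a * np.sin(2 * np.pi * f * t)
                           for a, f in zip(amps, freqs)))
            assert sparc(v, cfg) == pytest.approx(sparc_oracle(v), abs=1e-9)

    def test_amplitude_scale_invariance(self, smooth_speed):
        assert sparc(3.7 * smooth_speed) == pytest.approx(sparc(smooth_speed),
                                                          abs=1e-12)

    def test_time_shift_invariance(self):
        # compactly supported pulse: a pure shift multiplies the padded
        # spectrum by a phase factor, so its magnitude is untouched
        t = np.arange(1000)
        pulse = np.exp(-0.5 * ((t - 350) / 40.0) ** 2)
        shifted = np.exp(-0.5 * ((t - 450) / 40.0) ** 2)
        assert sparc(shifted) == pytest.approx(sparc(pulse), abs=1e-12)

    def test_noise_reduces_smoothness(self, rng):
        """Measurement noise on the angle, amplified by differentiation,
        makes the speed profile strictly less smooth (SNR 10:1)."""
        fs = 100.0
        t = np.arange(1500) / fs
        speed_clean = np.exp(-0.5 * ((t - 7.0) / 1.2) ** 2)
        angle = np.cumsum(speed_clean) / fs
        base = sparc(speed_clean)
        noisier = 0
        for _ in range(20):
            noisy_angle = angle + rng.normal(0, angle.std() / 10.0, t.shape)
            speed = np.abs(np.gradient(noisy_angle, 1 / fs))
            noisier += sparc(speed) < base
        assert noisier == 20

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sparc(np.zeros(100))


class TestXcorrDelay:
    def test_identical_series(self):
        t = np.linspace(0, 10, 1000)
        x = np.sin(t)
        assert xcorr_delay(x, x) == 0.0

    @pytest.mark.parametrize("shift", [1, 5, 50, 150])
    def test_recovers_integer_sample_shifts(self, shift):
        t = np.arange(0, 30, 0.01)
        target = target_position(t)
        response = np.roll(target, shift)
        # roll wraps; restrict to the causal interior by windowing
        assert xcorr_delay(target, response) == pytest.approx(shift / 100.0,
                                                              abs=0.011)

    def test_sinusoid_phase_relation(self):
        fs, f0, phase = 100.0, 1.3, 0.7
        t = np.arange(0, 20, 1 / fs)
        target = np.sin(2 * np.pi * f0 * t)
        response = np.sin(2 * np.pi * f0 * t - phase)
        lag = phase / (2 * np.pi * f0)
        assert xcorr_delay(target, response) == pytest.approx(lag, abs=0.011)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            xcorr_delay(np.ones(100), np.arange(100.0))


class TestEmgCalibration:
    def test_noiseless_recovery_is_exact(self):
        emg_f = np.concatenate([np.linspace(0, 2, 100), np.zeros(100)])
        emg_e = np.concatenate([np.zeros(100), np.linspace(0, 2, 100)])
        torque = 2.0 * emg_f - 1.5 * emg_e
        cal = fit_emg_calibration(emg_f, emg_e, torque)
        assert cal.flexor_slope == pytest.approx(2.0, abs=1e-9)
        assert cal.extensor_slope == pytest.approx(-1.5, abs=1e-9)

    def test_slope_recovery_under_noise(self, rng):
        from hapticdyad.synthetic_cohort import (
            DEFAULT_CALIBRATION,
            synth_calibration_session,
        )
        emg_f, emg_e, torque = synth_calibration_session(
            DEFAULT_CALIBRATION, seed=5, noise_frac=0.05)
        cal = fit_emg_calibration(emg_f, emg_e, torque)
        assert cal.flexor_slope == pytest.approx(
            DEFAULT_CALIBRATION.flexor_slope, rel=0.02)
        assert cal.extensor_slope == pytest.approx(
            DEFAULT_CALIBRATION.extensor_slope, rel=0.02)

    def test_rank_deficient_rejected(self):
        flat = np.ones(100)
        torque = np.concatenate([np.ones(50), -np.ones(50)])
        with pytest.raises(ValueError):
            fit_emg_calibration(flat, flat, torque)


class TestCocontraction:
    def test_min_of_magnitudes(self):
        out = cocontraction([0.5], [-0.3])
        assert out[0] == pytest.approx(0.3)

    def test_either_channel_zero(self):
        assert cocontraction([0.0], [-0.4])[0] == 0.0
        assert cocontraction([0.4], [0.0])[0] == 0.0

    def test_symmetric_activation(self):
        assert cocontraction([0.7], [-0.7])[0] == pytest.approx(0.7)

    @given(st.lists(st.floats(0, 2), min_size=1, max_size=30),
           st.lists(st.floats(0, 2), min_size=1, max_size=30))
    def test_bounded_by_channel_maxima(self, f, e):
        n = min(len(f), len(e))
        tf = np.asarray(f[:n])
        te = -np.asarray(e[:n])
        u = cocontraction(tf, te)
        assert np.all(u <= min(tf.max(), np.abs(te).max()) + 1e-12)

    def test_emg_to_torque_clips_sign_violations(self):
        cal = EmgCalibration(2.0, -0.1, -2.0, 0.1)
        tf, te = emg_to_torque([0.0], [0.0], cal)
        assert tf[0] == 0.0 and te[0] == 0.0


class TestNormaliseCocontraction:
    def test_endpoints(self):
        u = normalise_cocontraction([0.2, 0.5, 0.8])
        assert u[0] == 0.0 and u[-1] == 1.0

    def test_affine_invariance(self):
        base = np.array([0.2, 0.35, 0.5, 0.9])
        assert np.allclose(normalise_cocontraction(base),
                           normalise_cocontraction(3.0 * base + 1.7))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            normalise_cocontraction([0.4, 0.4, 0.4])
        with pytest.raises(ValueError):
            normalise_cocontraction([0.4])
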