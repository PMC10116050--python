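"""Envelope pipeline: filters, calibration, rest subtraction."""

import numpy as np
import pytest
from scipy import signal

from myoreach.processing import (
    CalibrationError,
    CalibrationProfile,
    EnvelopeSeries,
    StreamingPipeline,
    calibrate,
    envelope,
    highpass,
    highpass_sos,
    lowpass_sos,
    process,
    voluntary,
)
from myoreach.recording import EmgRecording

from conftest import sine_recording

ROLES6 = ("fcu", "ecu", "mid1", "mid2", "mid3", "mid4")


def const_recording(value, duration_s=5.0, fs=1000.0):
    n = int(duration_s * fs)
    return EmgRecording(np.full((6, n), float(value)), fs, ROLES6)


class TestHighpass:
    def test_removes_dc(self):
        out = highpass(const_recording(3.0))
        tail = out.samples[:, -1000:]
        assert np.max(np.abs(tail.mean(axis=1))) < 1e-6

    def test_zero_in_zero_out(self):
        out = highpass(const_recording(0.0))
        assert np.all(out.samples == 0.0)

    def test_passband_sinusoid_nearly_unity(self):
        # 100 Hz is deep in the passband of a 20 Hz high-pass
        rec = sine_recording(100.0, amplitude=1.0, duration_s=5.0)
        out = highpass(rec)
        steady = out.samples[0, -2000:]
        amp = (steady.max() - steady.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_rejects_non_finite(self):
        bad = np.zeros((6, 1000))
        bad[2, 500] = np.nan
        with pytest.raises(ValueError, match="finite"):
            EmgRecording(bad, 1000.0, ROLES6)


class TestEnvelope:
    def test_zero_signal_zero_envelope(self):
        env = envelope(const_recording(0.0))
        assert np.all(env.values == 0.0)

    def test_rectified_sine_steady_state(self):
        # mean of |a sin| is 2a/pi and the 2 Hz low-pass has unit DC gain;
        # 97 Hz is incommensurate with fs so the sampled mean converges to it
        a = 0.8
        rec = sine_recording(97.0, amplitude=a, duration_s=10.0)
        env = envelope(rec)
        tail = env.values[0, -2000:].mean()
        assert tail == pytest.approx(2 * a / np.pi, rel=0.03)

    def test_amplitude_step_tracks_up(self):
        a, fs = 0.5, 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 97 * t) * np.where(t < 5.0, a, 2 * a)
        rec = EmgRecording(np.tile(x, (6, 1)), fs, ROLES6)
        env = envelope(rec).values[0]
        assert env[-2000:].mean() == pytest.approx(4 * a / np.pi, rel=0.03)
        # plateau-to-plateau trend is upward through the transition
        pre = env[int(4.5 * fs) : int(5.0 * fs)].mean()
        post = env[int(6.0 * fs) : int(6.5 * fs)].mean()
        assert post > pre

    def test_non_negative_everywhere(self):
        rng = np.random.default_rng(0)
        rec = EmgRecording(rng.standard_normal((6, 4000)), 1000.0, ROLES6)
        assert np.all(process(rec).values >= 0.0)

    def test_positively_homogeneous(self):
        # rectification and linear filtering commute with positive scaling
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 4000))
        rec = EmgRecording(x, 1000.0, ROLES6)
        rec3 = EmgRecording(3.0 * x, 1000.0, ROLES6)
        e1, e3 = process(rec).values, process(rec3).values
        np.testing.assert_allclose(e3, 3.0 * e1, rtol=1e-9, atol=1e-12)


class TestStreaming:
    @pytest.mark.parametrize("chunk", [1, 7, 250, 1000])
    def test_chunked_equals_batch(self, chunk):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 3000))
        rec = EmgRecording(x, 1000.0, ROLES6)
        batch_hp = highpass(rec).samples
        batch_env = process(rec).values
        pipe = StreamingPipeline(6, 1000.0)
        hp_parts, env_parts = [], []
        for i in range(0, 3000, chunk):
            hp, env = pipe.push(x[:, i : i + chunk])
            hp_parts.append(hp)
            env_parts.append(env)
        np.testing.assert_allclose(np.hstack(hp_parts), batch_hp, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(np.hstack(env_parts), batch_env, rtol=1e-9, atol=1e-12)


class TestFilterDesign:
    @pytest.mark.parametrize(
        "sos_fn,cutoff", [(highpass_sos, 20.0), (lowpass_sos, 2.0)]
    )
    def test_minus_3db_at_cutoff(self, sos_fn, cutoff):
        _, h = signal.sosfreqz(sos_fn(1000.0), worN=[cutoff], fs=1000.0)
        assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_coefficients_follow_fs(self):
        # same analogue prototype discretised at two rates: both -3 dB at 20 Hz
        for fs in (500.0, 2000.0):
            _, h = signal.sosfreqz(highpass_sos(fs), worN=[20.0], fs=fs)
            assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=0.01)


class TestCalibrate:
    def test_snr_on_synthetic_kit(self, healthy_calib):
        assert np.all(healthy_calib.mvc_env > 10 * healthy_calib.rest_env)

    def test_identical_recordings_fail(self, healthy_kit):
        with pytest.raises(CalibrationError):
            calibrate(healthy_kit.rest, healthy_kit.rest)

    def test_mvc_mean_is_forearm_mean(self):
        calib = CalibrationProfile(
            rest_env=np.zeros(6),
            mvc_env=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            channel_roles=ROLES6,
        )
        assert calib.mvc_mean_env == pytest.approx(3.5)

    def test_trigger_excluded_from_mvc_mean(self):
        calib = CalibrationProfile(
            rest_env=np.zeros(7),
            mvc_env=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 100.0]),
            channel_roles=ROLES6 + ("trigger",),
        )
        assert calib.mvc_mean_env == pytest.approx(3.5)

    def test_too_short_recording_rejected(self, healthy_kit):
        short = healthy_kit.mvc.replace_samples(healthy_kit.mvc.samples[:, :2000])
        with pytest.raises(ValueError, match="shorter"):
            calibrate(short, healthy_kit.rest)

    def test_error_names_offending_channel(self):
        with pytest.raises(CalibrationError, match="ecu"):
            CalibrationProfile(
                rest_env=np.full(6, 0.1),
                mvc_env=np.array([1.0, 0.05, 1.0, 1.0, 1.0, 1.0]),
                channel_roles=ROLES6,
            )

    def test_json_round_trip(self, healthy_calib, tmp_path):
        path = tmp_path / "calib.json"
        healthy_calib.save(path)
        loaded = CalibrationProfile.load(path)
        np.testing.assert_allclose(loaded.mvc_env, healthy_calib.mvc_env)
        np.testing.assert_allclose(loaded.rest_env, healthy_calib.rest_env)
        assert loaded.channel_roles == healthy_calib.channel_roles


class TestVoluntary:
    def _calib(self):
        return CalibrationProfile(
            rest_env=np.full(6, 0.1),
            mvc_env=np.ones(6),
            channel_roles=ROLES6,
        )

    def test_rest_level_maps_to_zero(self):
        env = EnvelopeSeries(np.full((6, 10), 0.1), 1000.0)
        out = voluntary(env, self._calib())
        assert np.all(out.values == 0.0)

    def test_below_rest_clamped(self):
        env = EnvelopeSeries(np.full((6, 10), 0.05), 1000.0)
        out = voluntary(env, self._calib())
        assert np.all(out.values == 0.0)

    def test_subtraction_arithmetic(self):
        env = EnvelopeSeries(np.full((6, 10), 0.6), 1000.0)
        out = voluntary(env, self._calib())
        np.testing.assert_allclose(out.values, 0.5)
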