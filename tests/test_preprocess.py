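"""Preprocessing chain: re-referencing, filtering, downsampling, segmenting."""

import numpy as np
import pytest

from eegmci.errors import InsufficientDataError, InvalidConfigError, InvalidInputError
from eegmci.preprocess import (
    PreprocessConfig,
    bandpass_fir,
    downsample,
    notch,
    preprocess_epoch,
    rereference_average,
    select_segment,
)
from eegmci.spectral import welch_psd

from conftest import make_epoch, sine_epoch


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


class TestRereference:
    def test_constant_two_channels(self):
        ep = make_epoch(np.vstack([np.full(100, 3.0), np.full(100, 5.0)]))
        out = rereference_average(ep)
        assert np.allclose(out.data[0], -1.0)
        assert np.allclose(out.data[1], 1.0)

    def test_column_means_zero(self, rng):
        ep = make_epoch(rng.normal(size=(16, 500)))
        out = rereference_average(ep)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_idempotent(self, rng):
        ep = rereference_average(make_epoch(rng.normal(size=(4, 200))))
        again = rereference_average(ep)
        assert np.allclose(ep.data, again.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            rereference_average(make_epoch(np.zeros((1, 100))))


class TestBandpass:
    def test_stopband_100hz(self):
        ep = sine_epoch(100.0, fs=500.0, duration=30.0)
        out = bandpass_fir(ep, 0.1, 70.0)
        assert _rms(out.data) < 0.1 * _rms(ep.data)

    def test_passband_10hz(self):
        ep = sine_epoch(10.0, fs=250.0, duration=30.0)
        out = bandpass_fir(ep, 8.0, 13.0)
        assert abs(_rms(out.data) - _rms(ep.data)) < 0.1 * _rms(ep.data)

    def test_deep_stopband_below_half_lowcut(self):
        # 4 Hz tone vs an 8-13 Hz band: attenuation >= 20 dB at 0.5 * lo
        ep = sine_epoch(4.0, fs=250.0, duration=30.0)
        out = bandpass_fir(ep, 8.0, 13.0)
        assert _rms(out.data) < 0.1 * _rms(ep.data)

    def test_zero_in_zero_out(self):
        ep = make_epoch(np.zeros((2, 5000)))
        out = bandpass_fir(ep, 1.0, 40.0)
        assert np.allclose(out.data, 0.0)

    def test_cutoff_above_nyquist_rejected(self):
        ep = sine_epoch(10.0, fs=250.0, duration=10.0)
        with pytest.raises(InvalidConfigError):
            bandpass_fir(ep, 0.1, 130.0)


class TestNotch:
    def test_50hz_attenuated_20db(self):
        ep = sine_epoch(50.0, fs=250.0, duration=30.0)
        out = notch(ep, 50.0)
        assert _rms(out.data) < 0.1 * _rms(ep.data)

    def test_10hz_preserved(self):
        ep = sine_epoch(10.0, fs=250.0, duration=30.0)
        out = notch(ep, 50.0)
        assert abs(_rms(out.data) - _rms(ep.data)) < 0.05 * _rms(ep.data)

    def test_zero_in_zero_out(self):
        out = notch(make_epoch(np.zeros((2, 5000))), 50.0)
        assert np.allclose(out.data, 0.0)


class TestDownsample:
    def test_peak_survives_500_to_250(self):
        ep = sine_epoch(10.0, fs=500.0, duration=30.0)
        out = downsample(ep, 250.0)
        assert out.fs == 250.0
        spec = welch_psd(out)
        peak = spec.frequencies[np.argmax(spec.psd[0])]
        assert peak == pytest.approx(10.0, abs=0.5)

    def test_identity_when_rates_equal(self, rng):
        ep = make_epoch(rng.normal(size=(2, 1000)))
        out = downsample(ep, 250.0)
        assert out.fs == ep.fs
        assert np.array_equal(out.data, ep.data)

    def test_sample_count_arithmetic(self):
        ep = sine_epoch(5.0, fs=500.0, duration=60.0)
        out = downsample(ep, 250.0)
        assert out.n_samples == 15000

    def test_upsampling_rejected(self):
        with pytest.raises(InvalidConfigError):
            downsample(sine_epoch(5.0, fs=250.0, duration=10.0), 500.0)


class TestSelectSegment:
    def test_whole_recording(self, rng):
        ep = make_epoch(rng.normal(size=(2, 250 * 30)))
        out = select_segment(ep, 30.0)
        assert np.array_equal(out.data, ep.data)

    def test_lowest_amplitude_avoids_transient(self, rng):
        data = rng.normal(size=(2, 250 * 60))
        data[:, 250 * 10] += 500.0  # large spike at t = 10 s
        ep = make_epoch(data)
        out = select_segment(ep, 30.0, strategy="lowest_amplitude")
        assert out.n_samples == 250 * 30
        assert np.abs(out.data).max() < 400.0

    def test_too_short_rejected(self, rng):
        ep = make_epoch(rng.normal(size=(2, 250 * 10)))
        with pytest.raises(InsufficientDataError):
            select_segment(ep, 30.0)

    def test_first_and_offset_strategies(self, rng):
        ep = make_epoch(rng.normal(size=(1, 2500)))
        first = select_segment(ep, 4.0, strategy="first")
        assert np.array_equal(first.data, ep.data[:, :1000])
        off = select_segment(ep, 4.0, strategy="offset", offset_seconds=2.0)
        assert np.array_equal(off.data, ep.data[:, 500:1500])


class TestChain:
    def test_deterministic_and_channel_order_stable(self, rng):
        data = rng.normal(size=(16, 500 * 35))
        names = tuple(f"E{i}" for i in range(16))
        ep = make_epoch(data, fs=500.0, channels=names)
        cfg = PreprocessConfig()
        out1 = preprocess_epoch(ep, cfg)
        out2 = preprocess_epoch(ep, cfg)
        assert out1.channels == names
        assert out1.fs == 250.0
        assert out1.n_samples == 250 * 30
        assert np.array_equal(out1.data, out2.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            PreprocessConfig(bandpass_lo=10.0, bandpass_hi=5.0).validate()
        with pytest.raises(InvalidConfigError):
            PreprocessConfig(bandpass_hi=130.0, target_fs=250.0).validate()
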