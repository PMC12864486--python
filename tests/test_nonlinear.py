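"""Complexity measures: permutation entropy, sample entropy, delay estimation,
and the phase-space spread statistic (M-DCPSR)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegmci.nonlinear as nl
from eegmci.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidConfigError,
    UndefinedEntropyError,
)
from eegmci.nonlinear import (
    estimate_delay_autocorr,
    mdcpsr,
    ordinal_pattern_distribution,
    permutation_entropy,
    phase_space_model,
    sample_entropy,
    sample_entropy_counts,
)


def brute_force_sample_entropy(x: np.ndarray, m: int, r: float):
    """Independent O(N²) oracle: explicit double loop over template pairs."""
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < r:
                    a += 1
    # ordered pairs double the unordered counts; the ratio is unchanged
    return a // 2, b // 2


class TestPermutationEntropy:
    def test_monotone_series_zero(self):
        assert permutation_entropy(np.arange(50.0), m=3) == pytest.approx(0.0)
        assert permutation_entropy(np.linspace(5, -5, 30), m=2) == pytest.approx(0.0)

    def test_seven_point_worked_example(self):
        x = np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0])
        dist = ordinal_pattern_distribution(x, m=2, tau=1)
        assert sorted(dist.counts.tolist()) == [2, 4]
        assert dist.pe == pytest.approx(0.9183, abs=1e-4)

    def test_iid_noise_near_maximal(self, rng):
        x = rng.uniform(size=10_000)
        assert permutation_entropy(x, m=3) >= 0.99

    def test_bounded_zero_one(self, rng):
        for _ in range(10):
            x = rng.normal(size=200)
            assert 0.0 <= permutation_entropy(x, m=3) <= 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-10_000, 10_000), min_size=10, max_size=80,
                    unique=True))
    def test_invariant_under_monotone_transform(self, values):
        # integer grid keeps the transform injective in float64
        x = np.array(values, dtype=np.float64) / 100.0
        pe_raw = permutation_entropy(x, m=3)
        pe_tr = permutation_entropy(np.exp(x / 100.0) + 5.0, m=3)
        assert pe_raw == pytest.approx(pe_tr, abs=1e-12)

    def test_errors(self):
        with pytest.raises(InvalidConfigError):
            permutation_entropy(np.arange(10.0), m=1)
        with pytest.raises(InsufficientDataError):
            permutation_entropy(np.array([1.0, 2.0]), m=3)


class TestSampleEntropy:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(20, 200))
    def test_matches_brute_force_oracle(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        r = 0.2 * x.std()
        a, b = brute_force_sample_entropy(x, 2, r)
        if a == 0 or b == 0:
            with pytest.raises(UndefinedEntropyError):
                sample_entropy_counts(x, m=2, r=r)
        else:
            counts = sample_entropy_counts(x, m=2, r=r)
            assert (counts.a, counts.b) == (a, b)
            assert counts.se == pytest.approx(-np.log(a / b))

    def test_periodic_series_near_zero(self):
        x = np.array([1.0, 2.0, 3.0] * 20)
        assert sample_entropy(x) == pytest.approx(0.0, abs=0.05)

    def test_noise_exceeds_sinusoid(self, rng):
        t = np.arange(1000) / 250.0
        sine = np.sin(2 * np.pi * 10 * t)
        noise = rng.normal(size=1000) * sine.std()
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_windowed_average_close_to_full(self, rng):
        x = rng.normal(size=2000)
        full = sample_entropy(x)
        windowed = sample_entropy(x, window_seconds=4.0, fs=250.0)
        assert windowed == pytest.approx(full, rel=0.15)

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            sample_entropy(np.full(100, 2.0))
        with pytest.raises(InsufficientDataError):
            sample_entropy(np.array([1.0, 2.0]))
        with pytest.raises(UndefinedEntropyError):
            # strictly increasing with huge steps: no template matches at all
            sample_entropy(np.arange(0.0, 1000.0, 10.0), r=0.1)


class TestDelayEstimation:
    def test_10hz_tone_at_250hz(self):
        t = np.arange(0, 8, 1 / 250.0)
        x = np.sin(2 * np.pi * 10 * t)
        # first crossing lies between lags 6 and 7; |R(6)| < |R(7)|
        assert estimate_delay_autocorr(x, fs=250.0) == 7
        assert estimate_delay_autocorr(x, fs=250.0, delay_rule="nearest_zero") == 6

    def test_white_noise_small_delay(self, rng):
        # the sample autocorrelation of white noise usually changes sign within
        # the first couple of lags; occasional longer positive runs are noise
        taus = [estimate_delay_autocorr(rng.normal(size=2000)) for _ in range(20)]
        assert np.median(taus) <= 2
        assert max(taus) <= 20

    def test_fallback_when_no_crossing(self, monkeypatch, caplog):
        monkeypatch.setattr(nl, "autocorrelation",
                            lambda x, cap: np.linspace(1.0, 0.01, cap + 1))
        with caplog.at_level("WARNING", logger="eegmci.nonlinear"):
            tau = estimate_delay_autocorr(np.arange(500.0), fs=250.0)
        assert tau == 25
        assert any("zero crossing" in rec.message for rec in caplog.records)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_delay_autocorr(np.ones(100))


class TestMdcpsr:
    def test_constant_series_with_explicit_delay(self):
        assert mdcpsr(np.full(100, 3.0), tau=5) == pytest.approx(0.0)

    def test_unit_sinusoid_quarter_period(self):
        # f = 12.5 Hz at 250 Hz: period 20 samples, quarter period 5;
        # distances are sqrt(1 + sin^2), median -> sqrt(1.5)
        t = np.arange(0, 40, 1 / 250.0)
        val = mdcpsr(np.sin(2 * np.pi * 12.5 * t), tau=5)
        assert val == pytest.approx(np.sqrt(1.5), rel=0.01)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 100.0])
    def test_homogeneous_in_amplitude(self, rng, scale):
        x = rng.normal(size=1000)
        assert mdcpsr(scale * x, tau=3) == pytest.approx(scale * mdcpsr(x, tau=3))

    def test_embedded_point_count(self, rng):
        x = rng.normal(size=100)
        model = phase_space_model(x, tau=7)
        assert model.points.shape == (100 - 14, 3)
        assert np.all(model.distances >= 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            phase_space_model(np.arange(10.0), tau=4)
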