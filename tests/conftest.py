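"""Shared fixtures: small epochs and a miniature end-to-end cohort.

Everything is generated programmatically; the mini cohort is session-scoped
because feature extraction on even 12 subjects is the slowest shared step.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegmci.channels import CHANNELS
from eegmci.core import EegEpoch
from eegmci.features import FeatureConfig, extract_cohort_features
from eegmci.pipeline import preprocess_cohort
from eegmci.preprocess import PreprocessConfig
from eegmci.synthetic import generate_cohort


def make_epoch(data: np.ndarray, fs: float = 250.0, subject_id: str = "S01",
               timepoint: int = 1, channels=None) -> EegEpoch:
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EegEpoch(subject_id=subject_id, timepoint=timepoint,
                    channels=tuple(channels), data=data, fs=fs)


def sine_epoch(freq: float, fs: float = 250.0, duration: float = 30.0,
               n_channels: int = 1, amplitude: float = 1.0) -> EegEpoch:
    t = np.arange(int(round(duration * fs))) / fs
    row = amplitude * np.sin(2 * np.pi * freq * t)
    return make_epoch(np.tile(row, (n_channels, 1)), fs=fs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_cohort():
    """12 subjects (6 per group), 3 visits, 8 s recordings — fast but
    structurally complete."""
    return generate_cohort(n_smci=6, n_pmci=6, timepoints=(1, 2, 3),
                           duration=8.0, seed=42)


@pytest.fixture(scope="session")
def mini_preprocess_config() -> PreprocessConfig:
    return PreprocessConfig(segment_seconds=8.0)


@pytest.fixture(scope="session")
def mini_cross_features(mini_cohort, mini_preprocess_config):
    """Full 328-column cross-sectional feature table of the mini cohort."""
    clean = preprocess_cohort(mini_cohort, mini_preprocess_config)
    return extract_cohort_features(clean, timepoints=(1, 2, 3),
                                   config=FeatureConfig())
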