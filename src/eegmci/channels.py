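"""Channel montage, frequency bands and canonical feature-name registry.

Every stage of the pipeline derives its column names and orderings from this
module so that feature tables are byte-stable across runs.
"""

from __future__ import annotations

from typing import Sequence

#: 16-channel 10-20 montage, fixed order.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

#: Classical EEG sub-bands (Hz), contiguous and non-overlapping; bin
#: assignment throughout the package is half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

N_RATIOS = 5

#: Six longitudinal trend descriptors, fixed order.
DESCRIPTORS: tuple[str, ...] = ("MF", "SDF", "RF", "AF", "MVF", "SDVF")

GROUPS: tuple[str, str] = ("SMCI", "PMCI")

#: Outcome coding: PMCI (converted to AD) is the positive class.
GROUP_LABELS: dict[str, int] = {"SMCI": 0, "PMCI": 1}

#: Anterior→posterior position used for topographic amplitude gradients in the
#: synthetic generator (0 = frontal pole, 1 = occipital).
_AP_POSITION: dict[str, float] = {
    "Fp1": 0.0, "Fp2": 0.0, "F7": 0.2, "F3": 0.2, "F4": 0.2, "F8": 0.2,
    "T3": 0.5, "C3": 0.5, "C4": 0.5, "T4": 0.5,
    "T5": 0.8, "P3": 0.8, "P4": 0.8, "T6": 0.8,
    "O1": 1.0, "O2": 1.0,
}


def anterior_posterior_position(channel: str) -> float:
    return _AP_POSITION[channel]


def channel_pairs(channels: Sequence[str] = CHANNELS) -> list[tuple[str, str]]:
    """All unordered channel pairs in lexicographic (i < j) index order."""
    n = len(channels)
    return [(channels[i], channels[j]) for i in range(n) for j in range(i + 1, n)]


def ratio_feature_names(channels: Sequence[str] = CHANNELS) -> list[str]:
    return [f"Ratio{k}__{ch}" for k in range(1, N_RATIOS + 1) for ch in channels]


def psde_feature_names(channels: Sequence[str] = CHANNELS) -> list[str]:
    return [f"PSDE_{band}__{ch}" for band in BAND_NAMES for ch in channels]


def nonlinear_feature_names(channels: Sequence[str] = CHANNELS) -> list[str]:
    return [f"{feat}__{ch}" for feat in ("PE", "SE", "MDCPSR") for ch in channels]


def pli_feature_names(channels: Sequence[str] = CHANNELS) -> list[str]:
    return [f"PLI__{a}-{b}" for a, b in channel_pairs(channels)]


def cross_sectional_feature_names(
    channels: Sequence[str] = CHANNELS,
    spectral: bool = True,
    nonlinear: bool = True,
    connectivity: bool = True,
) -> list[str]:
    """Canonical order of the per-recording feature bank.

    With all three feature sets on a 16-channel montage this is the full
    328-name bank: 80 PSD ratios, 80 PSD entropies, 48 nonlinear, 120 PLI.
    """
    names: list[str] = []
    if spectral:
        names += ratio_feature_names(channels)
        names += psde_feature_names(channels)
    if nonlinear:
        names += nonlinear_feature_names(channels)
    if connectivity:
        names += pli_feature_names(channels)
    return names


def longitudinal_feature_names(cross_sectional_names: Sequence[str]) -> list[str]:
    """Six descriptors per cross-sectional feature: ``{feature}__{descriptor}``."""
    return [f"{feat}__{d}" for feat in cross_sectional_names for d in DESCRIPTORS]
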