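"""Per-recording cross-sectional feature extraction.

Assembles the full feature bank (80 PSD ratios + 80 PSD entropies + 48
nonlinear + 120 PLI = 328 features on the 16-channel montage) in the canonical
column order defined by :mod:`eegmci.channels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .channels import cross_sectional_feature_names
from .connectivity import connectivity_feature_vector
from .core import CohortDataset, EegEpoch
from .nonlinear import nonlinear_feature_vector
from .spectral import WelchParams, spectral_feature_vector


@dataclass
class FeatureConfig:
    """Which feature sets to extract, and their knobs."""

    spectral: bool = True
    nonlinear: bool = True
    connectivity: bool = True
    welch: WelchParams | None = None
    pe_m: int = 3
    pe_tau: int = 1
    se_m: int = 2
    se_window_seconds: float | None = None
    delay_rule: str = "larger_side"
    pli_band: str = "alpha"
    pli_method: str = "signed"


def extract_features(epoch: EegEpoch, config: FeatureConfig | None = None) -> pd.Series:
    """All cross-sectional features of one preprocessed recording, in the
    canonical order (328 values with everything enabled on 16 channels)."""
    cfg = config or FeatureConfig()
    values: dict[str, float] = {}
    if cfg.spectral:
        values.update(spectral_feature_vector(epoch, cfg.welch))
    if cfg.nonlinear:
        values.update(nonlinear_feature_vector(
            epoch, pe_m=cfg.pe_m, pe_tau=cfg.pe_tau, se_m=cfg.se_m,
            se_window_seconds=cfg.se_window_seconds, delay_rule=cfg.delay_rule,
        ))
    if cfg.connectivity:
        values.update(connectivity_feature_vector(
            epoch, band=cfg.pli_band, method=cfg.pli_method,
        ))
    order = cross_sectional_feature_names(
        epoch.channels, spectral=cfg.spectral,
        nonlinear=cfg.nonlinear, connectivity=cfg.connectivity,
    )
    return pd.Series([values[name] for name in order], index=order, name=epoch.subject_id)


def extract_cohort_features(
    cohort: CohortDataset,
    timepoints: tuple[int, ...] = (1, 2, 3),
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for every available (subject, timepoint) recording.

    Returns a frame indexed by (subject_id, timepoint) with one column per
    cross-sectional feature plus a ``group`` column.
    """
    rows = []
    keys = []
    groups = []
    for subject in cohort:
        for tp in timepoints:
            if tp not in subject.epochs:
                continue
            rows.append(extract_features(subject.epochs[tp], config))
            keys.append((subject.subject_id, tp))
            groups.append(subject.group)
    table = pd.DataFrame(rows)
    table.index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "timepoint"])
    table.insert(0, "group", groups)
    return table
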