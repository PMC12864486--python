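"""Longitudinal trend descriptors over repeated cross-sectional measurements.

For each cross-sectional feature trajectory X(t) observed at the first three
visits (months 0, 4, 8; δt = 4 months) six descriptors are computed:

* MF   — mean of the three values (central tendency),
* SDF  — sample standard deviation (T−1 denominator),
* RF   — range, max − min,
* AF   — area under the trajectory between the first and last visit
         (trapezoidal rule over the two intervals),
* MVF  — mean of the interval velocities (X(t+1) − X(t)) / δt,
* SDVF — sample standard deviation of those velocities.

By default the velocities are the T−1 = 2 consecutive-interval slopes;
``include_span_slope=True`` additionally includes the first-to-last slope as a
third velocity (an alternative reading of the construction, off by default).

The full bank of 328 cross-sectional features yields 6 × 328 = 1,968
longitudinal columns per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import DESCRIPTORS, GROUP_LABELS
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Measurement times of the three predictor visits, in months.
DEFAULT_TIMES_MONTHS = (0.0, 4.0, 8.0)


@dataclass
class LongitudinalConfig:
    times_months: tuple[float, ...] = DEFAULT_TIMES_MONTHS
    include_span_slope: bool = False


def longitudinal_stats(
    values,
    times=DEFAULT_TIMES_MONTHS,
    include_span_slope: bool = False,
) -> dict[str, float]:
    """The six trend descriptors of one feature trajectory.

    ``values`` are the feature measurements at ``times`` (months, strictly
    increasing, equidistant for the primary design: 0, 4, 8).
    """
    x = np.asarray(values, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    if x.shape != t.shape or x.ndim != 1:
        raise InvalidInputError("values and times must be 1-D and equally long")
    if x.size != 3:
        raise InvalidInputError(f"the primary design uses T=3 visits, got {x.size}")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("measurement times must be strictly increasing")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(t))):
        raise InvalidInputError("non-finite trajectory values")

    dt = np.diff(t)
    velocities = np.diff(x) / dt
    if include_span_slope:
        velocities = np.append(velocities, (x[-1] - x[0]) / (t[-1] - t[0]))

    # Trapezoidal area under the polygon between the first and last visit.
    af = float(np.sum((x[:-1] + x[1:]) / 2.0 * dt))

    return {
        "MF": float(x.mean()),
        "SDF": float(x.std(ddof=1)),
        "RF": float(x.max() - x.min()),
        "AF": af,
        "MVF": float(velocities.mean()),
        "SDVF": float(velocities.std(ddof=1)),
    }


def build_feature_table(
    cross_sectional: pd.DataFrame,
    timepoints: tuple[int, ...] = (1, 2, 3),
    config: LongitudinalConfig | None = None,
) -> pd.DataFrame:
    """Assemble the subjects × (6·P) longitudinal feature table.

    ``cross_sectional`` is the frame produced by
    :func:`eegmci.features.extract_cohort_features`: indexed by
    (subject_id, timepoint), one column per feature, plus a ``group`` column.
    Subjects missing any of the requested timepoints are excluded with a
    logged warning (complete-case analysis).  The result has one row per
    subject, a ``label`` column (SMCI = 0, PMCI = 1) and columns named
    ``{feature}__{descriptor}`` in canonical order.
    """
    cfg = config or LongitudinalConfig()
    if len(cfg.times_months) != len(timepoints):
        raise InvalidInputError("times_months must match the number of timepoints")
    feature_cols = [c for c in cross_sectional.columns if c != "group"]
    groups = cross_sectional["group"]

    subjects = cross_sectional.index.get_level_values("subject_id").unique()
    rows = {}
    labels = {}
    for sid in subjects:
        sub = cross_sectional.loc[sid]
        missing = [tp for tp in timepoints if tp not in sub.index]
        if missing:
            logger.warning("subject %s missing timepoint(s) %s; excluded", sid, missing)
            continue
        traj = sub.loc[list(timepoints), feature_cols].to_numpy(dtype=np.float64)
        out = np.empty(len(feature_cols) * len(DESCRIPTORS), dtype=np.float64)
        for p, feat in enumerate(feature_cols):
            stats = longitudinal_stats(
                traj[:, p], cfg.times_months,
                include_span_slope=cfg.include_span_slope,
            )
            for d, desc in enumerate(DESCRIPTORS):
                out[p * len(DESCRIPTORS) + d] = stats[desc]
        rows[sid] = out
        labels[sid] = GROUP_LABELS[groups.loc[(sid, timepoints[0])]]

    columns = [f"{feat}__{d}" for feat in feature_cols for d in DESCRIPTORS]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "subject_id"
    table.insert(0, "label", pd.Series(labels))
    return table
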