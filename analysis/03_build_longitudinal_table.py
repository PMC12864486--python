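#!/usr/bin/env python
"""Construct the subject × 1,968 longitudinal trend-feature table.

For every cross-sectional feature trajectory over visits 1-3 (months 0/4/8)
six descriptors are computed: mean (MF), SD (SDF), range (RF), area under the
trajectory (AF), and the mean/SD of the interval velocities (MVF, SDVF).

Reads results/cross_sectional_features.csv; writes results/longitudinal_table.csv.
"""

from pathlib import Path

import pandas as pd

from eegmci.longitudinal import build_feature_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cross = pd.read_csv(ROOT / "results" / "cross_sectional_features.csv",
                        index_col=["subject_id", "timepoint"])
    table = build_feature_table(cross, timepoints=(1, 2, 3))
    out = ROOT / "results" / "longitudinal_table.csv"
    table.to_csv(out)
    print(f"built {table.shape[0]} subjects x {table.shape[1] - 1} trend "
          f"features (label column included) -> {out}")
    assert table.shape[1] - 1 == 1968


if __name__ == "__main__":
    main()
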