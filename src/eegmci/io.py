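"""Cohort persistence: numeric-array archive + JSON sidecar + CSV manifest.

A cohort directory contains:

* ``cohort.npz``      — one array per recording, keyed ``{subject_id}__t{tp}``
* ``cohort.json``     — sidecar: channels, sampling rate, per-subject group
                        and metadata, and the full generation config
* ``manifest.csv``    — one row per recording: subject_id, group, timepoint,
                        array key
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CohortDataset, EegEpoch, SubjectRecord
from .errors import InvalidInputError


def _key(subject_id: str, timepoint: int) -> str:
    return f"{subject_id}__t{timepoint}"


def save_cohort(cohort: CohortDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    manifest_rows = []
    sidecar: dict = {"subjects": {}, "generation_config": dict(cohort.generation_config)}
    fs = None
    channels = None
    for subject in cohort:
        sidecar["subjects"][subject.subject_id] = {
            "group": subject.group,
            "metadata": subject.metadata,
            "timepoints": sorted(subject.epochs),
        }
        for tp, epoch in sorted(subject.epochs.items()):
            arrays[_key(subject.subject_id, tp)] = epoch.data
            manifest_rows.append({
                "subject_id": subject.subject_id,
                "group": subject.group,
                "timepoint": tp,
                "array_key": _key(subject.subject_id, tp),
            })
            fs, channels = epoch.fs, list(epoch.channels)
    sidecar["fs"] = fs
    sidecar["channels"] = channels
    np.savez_compressed(directory / "cohort.npz", **arrays)
    (directory / "cohort.json").write_text(json.dumps(sidecar, indent=2, default=str))
    pd.DataFrame(manifest_rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def load_cohort(directory: str | Path) -> CohortDataset:
    directory = Path(directory)
    sidecar = json.loads((directory / "cohort.json").read_text())
    archive = np.load(directory / "cohort.npz")
    channels = tuple(sidecar["channels"])
    fs = float(sidecar["fs"])
    subjects = []
    for sid, info in sidecar["subjects"].items():
        epochs = {}
        for tp in info["timepoints"]:
            key = _key(sid, int(tp))
            if key not in archive:
                raise InvalidInputError(f"archive missing array {key}")
            epochs[int(tp)] = EegEpoch(
                subject_id=sid, timepoint=int(tp), channels=channels,
                data=archive[key], fs=fs,
            )
        subjects.append(SubjectRecord(
            subject_id=sid, group=info["group"], epochs=epochs,
            metadata=info.get("metadata", {}),
        ))
    return CohortDataset(subjects=subjects,
                         generation_config=sidecar.get("generation_config", {}))
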