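"""Core data containers: epochs, subject records, cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping

import numpy as np

from .channels import CHANNELS, GROUP_LABELS, GROUPS
from .errors import InvalidInputError


@dataclass
class EegEpoch:
    """One subject × timepoint recording.

    Parameters
    ----------
    subject_id : str
        Subject identifier, unique within a cohort.
    timepoint : int
        Visit index, 1-based (months 0/4/8/12 → timepoints 1–4).
    channels : tuple of str
        Channel names, ordered; the row order of ``data``.
    data : ndarray, shape (n_channels, n_samples)
        Voltage samples in µV.
    fs : float
        Sampling rate in Hz.
    """

    subject_id: str
    timepoint: int
    channels: tuple[str, ...]
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise InvalidInputError("epoch data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.channels):
            raise InvalidInputError(
                f"{len(self.channels)} channel names but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EegEpoch":
        """Copy of this epoch with new samples (and optionally a new rate)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass
class SubjectRecord:
    """Per-subject bundle: outcome group, epochs by timepoint, covariates."""

    subject_id: str
    group: str
    epochs: dict[int, EegEpoch] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidInputError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def label(self) -> int:
        """Binary outcome: PMCI (progressed to AD within one year) = 1."""
        return GROUP_LABELS[self.group]

    def has_timepoints(self, timepoints: tuple[int, ...]) -> bool:
        return all(t in self.epochs for t in timepoints)


@dataclass
class CohortDataset:
    """A collection of subject records plus the configuration that made it."""

    subjects: list[SubjectRecord]
    generation_config: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("subject_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    def map_epochs(self, fn) -> "CohortDataset":
        """Apply ``fn(EegEpoch) -> EegEpoch`` to every epoch (new cohort)."""
        subjects = [
            SubjectRecord(
                subject_id=s.subject_id,
                group=s.group,
                epochs={t: fn(ep) for t, ep in s.epochs.items()},
                metadata=dict(s.metadata),
            )
            for s in self.subjects
        ]
        return CohortDataset(subjects=subjects, generation_config=dict(self.generation_config))


def standard_channels() -> tuple[str, ...]:
    """The fixed 16-channel 10–20 montage used by the study pipeline."""
    return CHANNELS
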