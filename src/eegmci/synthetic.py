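"""Synthetic multi-timepoint EEG cohort generator.

The generator emulates the statistical structure a longitudinal MCI-progression
study assumes, so the whole downstream pipeline can be exercised without any
clinical recordings:

* two outcome groups (stable vs. progressive MCI; defaults 38 and 27 subjects),
* four equidistant visits (months 0, 4, 8, 12),
* progressive spectral slowing in the PMCI group (delta/theta band amplitude
  rising, alpha/beta falling),
* falling signal complexity (a regularity weight ``rho`` mixes in a
  deterministic quasi-periodic component, which lowers permutation and sample
  entropy as an emergent consequence, never as a fitted target),
* falling alpha-band phase synchrony (a coupling weight ``kappa`` injects a
  shared alpha source into all channels with fixed nonzero phase lags),
* group differences negligible at visits 1–2 and pronounced at visits 3–4.

Each channel is a sum of band-limited stochastic components (white noise
brick-wall filtered into the five classical sub-bands, with mild
anterior/posterior topographic gradients — alpha strongest occipitally), the
``rho``-weighted deterministic component, and a pink-noise floor.  Per-subject
heterogeneity enters as log-normal amplitude random effects held constant
across visits, which is what gives longitudinal trend features their
within-subject baseline cancellation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import hilbert

from .channels import BAND_NAMES, BANDS, CHANNELS, GROUPS, anterior_posterior_position
from .core import CohortDataset, EegEpoch, SubjectRecord
from .errors import InvalidConfigError

#: Deterministic (regular) component: two incommensurate theta-range tones.
_DET_FREQS = (5.2, 7.6)
_DET_REL_AMPS = (1.0, 0.7)

#: Per-channel phase offsets (rad) of the shared alpha source.  Offsets are
#: spaced so every pair difference stays strictly inside (0, π): a constant lag
#: neither 0 nor π is what yields a nonzero phase lag index.
_ALPHA_PHASE_STEP = 0.15
_ALPHA_PHASE_BASE = 0.3

#: Channel phase step of the deterministic component.
_DET_PHASE_STEP = 0.4

#: Output scale (µV RMS of the summed stochastic components, before the
#: group×time amplitude multiplier).
_OUTPUT_RMS_UV = 20.0


def _per_group_tp(value: float, timepoints: Sequence[int]) -> dict[str, dict[int, float]]:
    return {g: {t: value for t in timepoints} for g in GROUPS}


@dataclass
class EffectSchedule:
    """Group × timepoint effect structure of the synthetic cohort.

    ``band_multipliers[group][tp][band]`` scales the base band amplitude;
    ``band_tilt[group][tp][band]`` is the within-band 1/f^χ exponent of the
    stochastic component (spectral slowing flattens the slow bands, χ ↓ →
    in-band PSD entropy ↑, and steepens the fast bands, χ ↑ → entropy ↓);
    ``kappa`` (alpha-coupling) and ``rho`` (regularity) are in [0, 1];
    ``amplitude_scale`` is an overall signal-amplitude multiplier (drives the
    phase-space spread measure, which is amplitude-proportional, without
    touching scale-invariant features).
    """

    band_amplitude: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 1.0, "theta": 0.8, "alpha": 1.3, "beta": 0.55, "gamma": 0.25,
        }
    )
    band_multipliers: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)
    band_tilt: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)
    kappa: dict[str, dict[int, float]] = field(default_factory=dict)
    rho: dict[str, dict[int, float]] = field(default_factory=dict)
    amplitude_scale: dict[str, dict[int, float]] = field(default_factory=dict)
    subject_sd: float = 0.15
    subject_tilt_sd: float = 0.2
    epoch_jitter_sd: float = 0.05
    noise_floor: float = 0.25
    det_weight: float = 1.2

    def validate(self) -> None:
        for band, amp in self.band_amplitude.items():
            if amp <= 0:
                raise InvalidConfigError(f"band amplitude {band} must be > 0")
        for g, per_tp in self.band_multipliers.items():
            for t, mults in per_tp.items():
                for band, m in mults.items():
                    if m <= 0:
                        raise InvalidConfigError(
                            f"multiplier for {g}/t{t}/{band} must be > 0, got {m}"
                        )
        for name, table in (("kappa", self.kappa), ("rho", self.rho)):
            for g, per_tp in table.items():
                for t, v in per_tp.items():
                    if not 0.0 <= v <= 1.0:
                        raise InvalidConfigError(f"{name}[{g}][{t}]={v} outside [0, 1]")
        for g, per_tp in self.amplitude_scale.items():
            for t, v in per_tp.items():
                if v <= 0:
                    raise InvalidConfigError(f"amplitude_scale[{g}][{t}] must be > 0")
        for g, per_tp in self.band_tilt.items():
            for t, tilts in per_tp.items():
                for band, v in tilts.items():
                    if abs(v) > 8:
                        raise InvalidConfigError(
                            f"band_tilt[{g}][{t}][{band}]={v} is implausibly steep"
                        )
        if self.subject_sd < 0 or self.epoch_jitter_sd < 0 or self.subject_tilt_sd < 0:
            raise InvalidConfigError("random-effect SDs must be >= 0")
        if self.noise_floor < 0:
            raise InvalidConfigError("noise floor must be >= 0")

    @classmethod
    def default(cls, timepoints: Sequence[int] = (1, 2, 3, 4)) -> "EffectSchedule":
        """Study-condition schedule: groups identical at visits 1–2, PMCI
        diverging at 3–4 (spectral slowing, rising regularity, falling alpha
        coupling, falling overall amplitude); SMCI drifts mildly in the same
        directions, so both groups trend while only 3–4 separate."""
        smci_mult = {
            1: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
            2: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
            3: {"delta": 1.08, "theta": 1.1, "alpha": 0.96, "beta": 0.98, "gamma": 1.0},
            4: {"delta": 1.15, "theta": 1.2, "alpha": 0.92, "beta": 0.96, "gamma": 1.0},
        }
        pmci_mult = {
            1: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
            2: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
            3: {"delta": 1.35, "theta": 1.5, "alpha": 0.75, "beta": 0.85, "gamma": 0.95},
            4: {"delta": 1.7, "theta": 2.0, "alpha": 0.55, "beta": 0.7, "gamma": 0.9},
        }
        # Within-band spectral exponents: slowing flattens delta/theta
        # (entropy up) and steepens alpha/beta/gamma (entropy down) in the
        # progressive group, mildly in the stable group.
        base_tilt = {"delta": 1.0, "theta": 0.8, "alpha": 0.3, "beta": 0.5, "gamma": 0.5}
        smci_tilt = {
            1: dict(base_tilt),
            2: dict(base_tilt),
            3: {"delta": 0.9, "theta": 0.72, "alpha": 0.4, "beta": 0.6, "gamma": 0.55},
            4: {"delta": 0.82, "theta": 0.66, "alpha": 0.5, "beta": 0.7, "gamma": 0.6},
        }
        pmci_tilt = {
            1: dict(base_tilt),
            2: dict(base_tilt),
            3: {"delta": 0.3, "theta": 0.2, "alpha": 1.1, "beta": 2.4, "gamma": 1.1},
            4: {"delta": 0.0, "theta": 0.0, "alpha": 1.6, "beta": 3.0, "gamma": 1.5},
        }
        kappa = {
            "SMCI": {1: 0.6, 2: 0.6, 3: 0.55, 4: 0.5},
            "PMCI": {1: 0.6, 2: 0.6, 3: 0.35, 4: 0.2},
        }
        rho = {
            "SMCI": {1: 0.2, 2: 0.2, 3: 0.25, 4: 0.3},
            "PMCI": {1: 0.2, 2: 0.2, 3: 0.6, 4: 0.75},
        }
        amplitude_scale = {
            "SMCI": {1: 1.0, 2: 1.0, 3: 0.95, 4: 0.9},
            "PMCI": {1: 1.0, 2: 1.0, 3: 0.6, 4: 0.45},
        }
        tps = tuple(timepoints)
        sched = cls(
            band_multipliers={
                "SMCI": {t: dict(smci_mult[t]) for t in tps},
                "PMCI": {t: dict(pmci_mult[t]) for t in tps},
            },
            band_tilt={
                "SMCI": {t: dict(smci_tilt[t]) for t in tps},
                "PMCI": {t: dict(pmci_tilt[t]) for t in tps},
            },
            kappa={g: {t: kappa[g][t] for t in tps} for g in GROUPS},
            rho={g: {t: rho[g][t] for t in tps} for g in GROUPS},
            amplitude_scale={g: {t: amplitude_scale[g][t] for t in tps} for g in GROUPS},
        )
        sched.validate()
        return sched

    @classmethod
    def null(cls, timepoints: Sequence[int] = (1, 2, 3, 4)) -> "EffectSchedule":
        """No group or time effects at all: both groups are draws from the
        same process at every visit (type-I / leakage calibration)."""
        tps = tuple(timepoints)
        ones = {band: 1.0 for band in BAND_NAMES}
        base_tilt = {"delta": 1.0, "theta": 0.8, "alpha": 0.3, "beta": 0.5, "gamma": 0.5}
        sched = cls(
            band_multipliers={g: {t: dict(ones) for t in tps} for g in GROUPS},
            band_tilt={g: {t: dict(base_tilt) for t in tps} for g in GROUPS},
            kappa=_per_group_tp(0.6, tps),
            rho=_per_group_tp(0.2, tps),
            amplitude_scale=_per_group_tp(1.0, tps),
        )
        sched.validate()
        return sched

    def with_multiplier(self, group: str, timepoint: int, band: str, value: float) -> "EffectSchedule":
        """Copy of the schedule with one band multiplier replaced."""
        new = copy.deepcopy(self)
        new.band_multipliers[group][timepoint][band] = value
        new.validate()
        return new

    def to_dict(self) -> dict:
        return {
            "band_amplitude": dict(self.band_amplitude),
            "band_multipliers": copy.deepcopy(self.band_multipliers),
            "band_tilt": copy.deepcopy(self.band_tilt),
            "kappa": copy.deepcopy(self.kappa),
            "rho": copy.deepcopy(self.rho),
            "amplitude_scale": copy.deepcopy(self.amplitude_scale),
            "subject_sd": self.subject_sd,
            "subject_tilt_sd": self.subject_tilt_sd,
            "epoch_jitter_sd": self.epoch_jitter_sd,
            "noise_floor": self.noise_floor,
            "det_weight": self.det_weight,
        }


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        lo: float, hi: float, tilt: float = 0.0) -> np.ndarray:
    """Unit-variance noise confined to [lo, hi) Hz (brick-wall FFT mask),
    optionally shaped as 1/f^tilt within the band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    shape = np.zeros_like(freqs)
    shape[mask] = 1.0
    if tilt != 0.0:
        shape[mask] = (freqs[mask] / lo) ** (-tilt / 2.0)  # amplitude ∝ f^(−χ/2)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f noise (0.5–100 Hz shaped band)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    valid = freqs >= 0.5
    scale[valid] = 1.0 / np.sqrt(freqs[valid])
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _band_gradient(band: str, channel: str) -> float:
    """Mild resting-state topography: alpha posterior-dominant, slow bands
    slightly anterior-dominant."""
    ap = anterior_posterior_position(channel)
    if band == "alpha":
        return 0.7 + 0.6 * ap
    if band in ("delta", "theta"):
        return 1.15 - 0.3 * ap
    return 1.0


def draw_subject_effects(rng: np.random.Generator, schedule: EffectSchedule) -> dict:
    """Per-subject random effects: log-normal band and overall amplitude
    multipliers (constant across visits) plus a phase offset for the
    deterministic component."""
    sd = schedule.subject_sd
    return {
        "band": {band: float(np.exp(rng.normal(0.0, sd))) for band in BAND_NAMES},
        "tilt": {band: float(rng.normal(0.0, schedule.subject_tilt_sd))
                 for band in BAND_NAMES},
        "amp": float(np.exp(rng.normal(0.0, sd))),
        "det_phase": float(rng.uniform(0.0, 2.0 * np.pi)),
    }


def generate_epoch(
    group: str,
    timepoint: int,
    schedule: EffectSchedule,
    subject_effects: Mapping | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    subject_id: str = "synthetic",
    channels: Sequence[str] = CHANNELS,
    fs: float = 250.0,
    duration: float = 30.0,
) -> EegEpoch:
    """Generate one multi-channel epoch under the given effect schedule.

    Deterministic for a fixed seed; the random draw order does not depend on
    schedule values, so two schedules differing only in a multiplier reuse the
    same noise realizations (scaled), which makes programmed effects strictly
    monotone per recording.
    """
    schedule.validate()
    if group not in GROUPS:
        raise InvalidConfigError(f"unknown group {group!r}")
    if fs < 100:
        raise InvalidConfigError("fs must be >= 100 Hz")
    if duration < 4:
        raise InvalidConfigError("duration must be >= 4 s")
    rng = np.random.default_rng(seed)
    if subject_effects is None:
        subject_effects = draw_subject_effects(rng, schedule)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    mults = schedule.band_multipliers[group][timepoint]
    tilts = schedule.band_tilt.get(group, {}).get(timepoint, {})
    subj_tilt = subject_effects.get("tilt", {b: 0.0 for b in BAND_NAMES})
    kappa = schedule.kappa[group][timepoint]
    rho = schedule.rho[group][timepoint]
    amp_scale = schedule.amplitude_scale[group][timepoint]

    # Shared alpha source, phase-rotated per channel via its analytic signal.
    alpha_lo, alpha_hi = BANDS["alpha"]
    common = _band_limited_noise(rng, n, fs, alpha_lo, alpha_hi)
    common_analytic = hilbert(common)

    jitter = {
        band: float(np.exp(rng.normal(0.0, schedule.epoch_jitter_sd)))
        for band in BAND_NAMES
    }

    data = np.empty((len(channels), n), dtype=np.float64)
    for c, ch in enumerate(channels):
        sig = np.zeros(n)
        for band in BAND_NAMES:
            lo, hi = BANDS[band]
            tilt = tilts.get(band, 0.0) + subj_tilt.get(band, 0.0)
            indep = _band_limited_noise(rng, n, fs, lo, hi, tilt=tilt)
            if band == "alpha":
                phi = _ALPHA_PHASE_BASE + _ALPHA_PHASE_STEP * c
                lagged = np.real(common_analytic * np.exp(-1j * phi))
                lagged_sd = lagged.std()
                if lagged_sd > 0:
                    lagged = lagged / lagged_sd
                comp = np.sqrt(max(0.0, 1.0 - kappa**2)) * indep + kappa * lagged
            else:
                comp = indep
            amp = (
                schedule.band_amplitude[band]
                * mults[band]
                * subject_effects["band"][band]
                * jitter[band]
                * _band_gradient(band, ch)
            )
            sig += amp * comp
        stoch_rms = sig.std()

        theta_c = subject_effects["det_phase"] + _DET_PHASE_STEP * c
        det = np.zeros(n)
        for f, a in zip(_DET_FREQS, _DET_REL_AMPS):
            det += a * np.sin(2.0 * np.pi * f * t + theta_c * (1.0 + 0.3 * f / _DET_FREQS[0]))
        det /= det.std()
        sig = sig + rho * schedule.det_weight * stoch_rms * det

        pink = _pink_noise(rng, n, fs)
        sig = sig + schedule.noise_floor * stoch_rms * pink

        data[c] = sig * (_OUTPUT_RMS_UV / stoch_rms) * amp_scale * subject_effects["amp"]

    return EegEpoch(
        subject_id=subject_id,
        timepoint=timepoint,
        channels=tuple(channels),
        data=data,
        fs=float(fs),
    )


def generate_cohort(
    schedule: EffectSchedule | None = None,
    *,
    n_smci: int = 38,
    n_pmci: int = 27,
    timepoints: Sequence[int] = (1, 2, 3, 4),
    fs: float = 250.0,
    duration: float = 30.0,
    seed: int = 0,
    channels: Sequence[str] = CHANNELS,
) -> CohortDataset:
    """Generate a full synthetic cohort (default 38 SMCI + 27 PMCI, 4 visits).

    Deterministic for a fixed seed: per-subject and per-epoch streams are
    spawned from one :class:`numpy.random.SeedSequence`.
    """
    if n_smci < 1 or n_pmci < 1:
        raise InvalidConfigError("need at least one subject per group")
    if duration <= 0:
        raise InvalidConfigError("duration must be positive")
    timepoints = tuple(timepoints)
    if schedule is None:
        schedule = EffectSchedule.default(timepoints=tuple(sorted(set(timepoints) | {1, 2, 3, 4}))
                                          if max(timepoints) <= 4 else timepoints)
    schedule.validate()
    for g in GROUPS:
        for tp in timepoints:
            if tp not in schedule.band_multipliers[g]:
                raise InvalidConfigError(f"schedule lacks timepoint {tp} for group {g}")

    root = np.random.SeedSequence(seed)
    groups = ["SMCI"] * n_smci + ["PMCI"] * n_pmci
    subject_seeds = root.spawn(len(groups))

    subjects: list[SubjectRecord] = []
    counters = {"SMCI": 0, "PMCI": 0}
    for group, subj_ss in zip(groups, subject_seeds):
        counters[group] += 1
        sid = f"{group}{counters[group]:02d}"
        subj_rng = np.random.default_rng(subj_ss)
        effects = draw_subject_effects(subj_rng, schedule)
        metadata = {
            "age": float(np.round(subj_rng.normal(69.0, 7.7), 1)),
            "sex": "M" if subj_rng.random() < 0.4 else "F",
            "mmse_baseline": float(np.clip(np.round(subj_rng.normal(23.5, 1.8)), 18, 28)),
        }
        epoch_seeds = subj_ss.spawn(len(timepoints))
        epochs = {
            tp: generate_epoch(
                group, tp, schedule, effects, ep_ss,
                subject_id=sid, channels=channels, fs=fs, duration=duration,
            )
            for tp, ep_ss in zip(timepoints, epoch_seeds)
        }
        subjects.append(SubjectRecord(subject_id=sid, group=group, epochs=epochs,
                                      metadata=metadata))

    config = {
        "schedule": schedule.to_dict(),
        "n_smci": n_smci,
        "n_pmci": n_pmci,
        "timepoints": list(timepoints),
        "fs": fs,
        "duration": duration,
        "seed": seed,
        "channels": list(channels),
    }
    return CohortDataset(subjects=subjects, generation_config=config)
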