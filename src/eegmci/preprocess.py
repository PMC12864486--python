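"""Automated resting-state EEG preprocessing.

Stage order (fixed): common-average re-reference → zero-phase FIR band-pass →
FIR notch → anti-aliased downsampling → fixed-length segment selection.
Human-in-the-loop steps of clinical practice (examiner epoch screening, bad
channel interpolation, ICA artifact removal) are deliberately not implemented;
the amplitude-based segment selector is the automated stand-in.

All filters are windowed-sinc (Hamming) designs applied forward–backward with
:func:`scipy.signal.filtfilt`, so they are zero-phase.  The number of taps is
derived from the transition bandwidth (edge/5) and capped so the filter fits
the recording.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np
from scipy.signal import filtfilt, firwin, resample_poly

from .core import EegEpoch
from .errors import InsufficientDataError, InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

#: Hamming-window FIR: ~3.3 normalized-frequency units per transition band.
_HAMMING_TBW = 3.3


@dataclass
class PreprocessConfig:
    """Parameters of the automated preprocessing chain."""

    bandpass_lo: float = 0.1
    bandpass_hi: float = 70.0
    notch_freq: float = 50.0
    notch_halfwidth: float = 2.0
    target_fs: float = 250.0
    segment_seconds: float = 30.0
    segment_strategy: Literal["lowest_amplitude", "first", "offset"] = "lowest_amplitude"
    segment_offset_seconds: float = 0.0

    def validate(self) -> None:
        if not 0 < self.bandpass_lo < self.bandpass_hi:
            raise InvalidConfigError("need 0 < bandpass_lo < bandpass_hi")
        if self.bandpass_hi >= self.target_fs / 2:
            raise InvalidConfigError(
                "bandpass_hi must stay below the post-downsampling Nyquist rate"
            )
        if self.segment_seconds <= 0:
            raise InvalidConfigError("segment_seconds must be positive")
        if self.notch_halfwidth <= 0:
            raise InvalidConfigError("notch_halfwidth must be positive")


def _num_taps(transition_hz: float, fs: float, n_samples: int) -> int:
    """Odd tap count for a Hamming FIR with the given transition band, capped
    so forward-backward filtering is feasible on ``n_samples``."""
    taps = int(np.ceil(_HAMMING_TBW * fs / transition_hz))
    if taps % 2 == 0:
        taps += 1
    cap = max(3, (n_samples - 2) // 3)  # filtfilt needs n > 3 * taps
    if cap % 2 == 0:
        cap -= 1
    if taps > cap:
        logger.debug("FIR taps capped %d -> %d (short recording)", taps, cap)
        taps = cap
    return taps


def _apply_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # even-extension padding: the default odd extension injects a DC step at
    # the edges that long high-pass filters turn into large transients
    return filtfilt(taps, [1.0], data, axis=-1, padtype="even")


def rereference_average(epoch: EegEpoch) -> EegEpoch:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    if epoch.n_channels < 2:
        raise InvalidInputError("average reference needs at least 2 channels")
    return epoch.with_data(epoch.data - epoch.data.mean(axis=0, keepdims=True))


def bandpass_fir(epoch: EegEpoch, lo: float, hi: float) -> EegEpoch:
    """Zero-phase FIR band-pass, realized as a high-pass/low-pass cascade so
    each edge gets its own transition bandwidth (edge/5)."""
    nyq = epoch.fs / 2
    if not 0 < lo < hi:
        raise InvalidConfigError("need 0 < lo < hi")
    if hi >= nyq:
        raise InvalidConfigError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    n = epoch.n_samples
    hp = firwin(_num_taps(lo / 5.0, epoch.fs, n), lo, pass_zero=False, fs=epoch.fs)
    lp = firwin(_num_taps(hi / 5.0, epoch.fs, n), hi, pass_zero=True, fs=epoch.fs)
    return epoch.with_data(_apply_fir(_apply_fir(epoch.data, hp), lp))


def notch(epoch: EegEpoch, freq: float, halfwidth: float = 2.0) -> EegEpoch:
    """Zero-phase FIR band-stop around ``freq`` (default 48–52 Hz)."""
    nyq = epoch.fs / 2
    if not 0 < freq < nyq:
        raise InvalidConfigError(f"notch frequency {freq} Hz outside (0, Nyquist)")
    lo, hi = freq - halfwidth, freq + halfwidth
    if lo <= 0 or hi >= nyq:
        raise InvalidConfigError("notch band must lie strictly inside (0, Nyquist)")
    taps = firwin(_num_taps(halfwidth / 2.0, epoch.fs, epoch.n_samples),
                  [lo, hi], fs=epoch.fs)  # pass_zero default -> band-stop
    return epoch.with_data(_apply_fir(epoch.data, taps))


def downsample(epoch: EegEpoch, target_fs: float) -> EegEpoch:
    """Anti-aliased rate reduction (polyphase resampling)."""
    if target_fs > epoch.fs:
        raise InvalidConfigError("target_fs must not exceed the current rate")
    if target_fs == epoch.fs:
        return epoch.with_data(epoch.data.copy())
    frac = Fraction(target_fs / epoch.fs).limit_denominator(1000)
    data = resample_poly(epoch.data, frac.numerator, frac.denominator, axis=-1)
    return epoch.with_data(data, fs=target_fs)


def select_segment(
    epoch: EegEpoch,
    segment_seconds: float,
    strategy: Literal["lowest_amplitude", "first", "offset"] = "lowest_amplitude",
    offset_seconds: float = 0.0,
) -> EegEpoch:
    """Pick one contiguous segment of exact length.

    ``lowest_amplitude`` (default) scans candidate windows on a 1 s grid and
    returns the one whose peak absolute amplitude across channels is smallest —
    an automated proxy for the manual selection of clean background rhythm.
    """
    n_seg = int(round(segment_seconds * epoch.fs))
    n = epoch.n_samples
    if n_seg > n:
        raise InsufficientDataError(
            f"recording is {epoch.duration:.1f} s, need {segment_seconds} s"
        )
    if n_seg == n:
        return epoch.with_data(epoch.data.copy())
    if strategy == "first":
        start = 0
    elif strategy == "offset":
        start = int(round(offset_seconds * epoch.fs))
        if start + n_seg > n:
            raise InsufficientDataError("offset segment extends past the recording")
    elif strategy == "lowest_amplitude":
        step = max(1, int(round(epoch.fs)))  # 1 s grid
        starts = list(range(0, n - n_seg + 1, step))
        if starts[-1] != n - n_seg:
            starts.append(n - n_seg)
        peak = np.abs(epoch.data)
        best, best_val = 0, np.inf
        for s in starts:
            v = peak[:, s:s + n_seg].max()
            if v < best_val:
                best, best_val = s, v
        start = best
    else:
        raise InvalidConfigError(f"unknown segment strategy {strategy!r}")
    return epoch.with_data(epoch.data[:, start:start + n_seg].copy())


def preprocess_epoch(epoch: EegEpoch, config: PreprocessConfig | None = None) -> EegEpoch:
    """Full automated chain in the documented order."""
    cfg = config or PreprocessConfig()
    cfg.validate()
    out = rereference_average(epoch)
    out = bandpass_fir(out, cfg.bandpass_lo, cfg.bandpass_hi)
    if cfg.notch_freq < out.fs / 2 - cfg.notch_halfwidth:
        out = notch(out, cfg.notch_freq, cfg.notch_halfwidth)
    else:
        warnings.warn("notch frequency at/above Nyquist; notch skipped")
    out = downsample(out, cfg.target_fs)
    out = select_segment(out, cfg.segment_seconds, cfg.segment_strategy,
                         cfg.segment_offset_seconds)
    return out
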