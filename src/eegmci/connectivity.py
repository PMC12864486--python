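"""Alpha-band phase lag index (PLI) between all channel pairs.

The PLI of two signals is |⟨sign(sin(φx(t) − φy(t)))⟩|: it is 0 when the
instantaneous phase difference is centered on 0 or π (no consistent lag, or a
lag indistinguishable from volume conduction) and 1 for perfect phase locking
at any other value.  Phases come from the analytic signal (Hilbert transform)
of the band-filtered data; one second is trimmed from each end to suppress
filter and Hilbert edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

from .channels import BANDS, channel_pairs
from .core import EegEpoch
from .errors import DegenerateInputError, InsufficientDataError, InvalidInputError

_EDGE_TRIM_SECONDS = 1.0
_MIN_DURATION_SECONDS = 4.0


def _band_filter(data: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    n = data.shape[-1]
    taps = int(np.ceil(3.3 * fs / (lo / 2.0)))  # 4 Hz transition at the 8 Hz edge
    if taps % 2 == 0:
        taps += 1
    cap = max(3, (n - 2) // 3)  # filtfilt needs n > 3 * taps
    if cap % 2 == 0:
        cap -= 1
    taps = min(taps, cap)
    h = firwin(taps, [lo, hi], pass_zero=False, fs=fs)
    return filtfilt(h, [1.0], data, axis=-1, padtype="even")


def analytic_phase(series: np.ndarray, fs: float,
                   band: tuple[float, float] | str | None = "alpha",
                   trim_seconds: float = _EDGE_TRIM_SECONDS) -> np.ndarray:
    """Instantaneous phase of the (optionally band-filtered) analytic signal,
    with ``trim_seconds`` discarded at each end.  Phases lie in (−π, π]."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < _MIN_DURATION_SECONDS * fs:
        raise InsufficientDataError(
            f"need at least {_MIN_DURATION_SECONDS:.0f} s of signal for phase estimation"
        )
    if np.allclose(x, 0.0):
        raise DegenerateInputError("zero signal has no defined phase")
    if band is not None:
        band_hz = BANDS[band] if isinstance(band, str) else band
        x = _band_filter(x, fs, band_hz)
    an = hilbert(x)
    trim = int(round(trim_seconds * fs))
    if trim > 0:
        an = an[trim:-trim]
    return np.angle(an)


def analytic_amplitude(series: np.ndarray, fs: float,
                       band: tuple[float, float] | str | None = None,
                       trim_seconds: float = _EDGE_TRIM_SECONDS) -> np.ndarray:
    """Instantaneous amplitude (analytic-signal envelope), edge-trimmed."""
    x = np.asarray(series, dtype=np.float64)
    if band is not None:
        band_hz = BANDS[band] if isinstance(band, str) else band
        x = _band_filter(x, fs, band_hz)
    an = hilbert(x)
    trim = int(round(trim_seconds * fs))
    if trim > 0:
        an = an[trim:-trim]
    return np.abs(an)


def _pli_from_phases(phi_x: np.ndarray, phi_y: np.ndarray,
                     method: Literal["signed", "folded_abs"]) -> float:
    if method == "signed":
        s = np.sign(np.sin(phi_x - phi_y))
    elif method == "folded_abs":
        # As-printed audit variant: fold |Δφ| into [0, 2π) before the sign,
        # which can never be negative and therefore saturates near 1.
        s = np.sign(np.mod(np.abs(phi_x - phi_y), 2.0 * np.pi))
    else:
        raise InvalidInputError(f"unknown PLI method {method!r}")
    return float(abs(s.mean()))


def pli_pair(x: np.ndarray, y: np.ndarray, fs: float,
             band: tuple[float, float] | str | None = "alpha",
             method: Literal["signed", "folded_abs"] = "signed") -> float:
    """Phase lag index of two equally sampled signals, in [0, 1].

    Symmetric in its arguments and invariant to amplitude scaling of either
    signal; sign(0) contributes 0 to the mean.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InvalidInputError("signals must have equal length")
    phi_x = analytic_phase(x, fs, band=band)
    phi_y = analytic_phase(y, fs, band=band)
    return _pli_from_phases(phi_x, phi_y, method)


@dataclass
class PliMatrix:
    """Symmetric PLI matrix with a canonical flattened pair vector."""

    channels: tuple[str, ...]
    matrix: np.ndarray  # (n, n), zero diagonal

    @property
    def pair_names(self) -> list[str]:
        return [f"PLI__{a}-{b}" for a, b in channel_pairs(self.channels)]

    @property
    def pair_values(self) -> np.ndarray:
        """Upper triangle in lexicographic (i < j) order — 120 values for the
        16-channel montage."""
        iu = np.triu_indices(len(self.channels), k=1)
        return self.matrix[iu]


def pli_matrix(epoch: EegEpoch,
               band: tuple[float, float] | str | None = "alpha",
               method: Literal["signed", "folded_abs"] = "signed") -> PliMatrix:
    """PLI between all channel pairs of an epoch (band-filter + Hilbert once
    per channel, then pairwise sign statistics)."""
    n_ch = epoch.n_channels
    if n_ch < 2:
        raise InvalidInputError("PLI needs at least two channels")
    phases = np.vstack(
        [analytic_phase(epoch.data[c], epoch.fs, band=band) for c in range(n_ch)]
    )
    mat = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            v = _pli_from_phases(phases[i], phases[j], method)
            mat[i, j] = mat[j, i] = v
    return PliMatrix(channels=epoch.channels, matrix=mat)


def connectivity_feature_vector(epoch: EegEpoch,
                                band: tuple[float, float] | str | None = "alpha",
                                method: Literal["signed", "folded_abs"] = "signed"
                                ) -> dict[str, float]:
    """All pairwise PLI features of one recording, keyed ``PLI__{chA}-{chB}``."""
    pm = pli_matrix(epoch, band=band, method=method)
    return dict(zip(pm.pair_names, (float(v) for v in pm.pair_values)))
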