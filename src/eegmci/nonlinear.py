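"""Nonlinear complexity features: permutation entropy, sample entropy, and the
median distance from the centroid of a 3-D phase-space reconstruction (M-DCPSR).

Permutation entropy is the Shannon entropy of the ordinal-pattern distribution
of delay-embedded windows, normalized by ln(m!) so it lies in [0, 1]; rank ties
are broken by temporal order (stable sort).  Sample entropy follows Richman &
Moorman: −ln(A/B), where B counts template pairs (i ≠ j) of length m whose
Chebyshev distance is < r and A counts the same at length m+1, with m = 2 and
r = 0.2 × SD by default.  M-DCPSR embeds the series at m = 3 with a delay taken
from the first zero crossing of the autocorrelation function and returns the
median Euclidean distance of the embedded points from their centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numba
import numpy as np

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidConfigError,
    UndefinedEntropyError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Permutation entropy
# ---------------------------------------------------------------------------

@dataclass
class OrdinalPatternDistribution:
    m: int
    tau: int
    counts: np.ndarray          # length m!, canonical permutation order
    probabilities: np.ndarray
    raw_entropy: float          # H(m), nats
    pe: float                   # H(m) / ln(m!)


def _permutation_index(perms: np.ndarray, m: int) -> np.ndarray:
    """Map each row (a permutation of 0..m-1) to its Lehmer rank."""
    n = perms.shape[0]
    idx = np.zeros(n, dtype=np.int64)
    remaining = perms.copy()
    for pos in range(m):
        smaller = (remaining[:, pos + 1:] < remaining[:, [pos]]).sum(axis=1)
        idx = idx * (m - pos) + smaller
    return idx


def ordinal_pattern_distribution(series: np.ndarray, m: int = 3, tau: int = 1
                                 ) -> OrdinalPatternDistribution:
    """Tally the ordinal patterns of all delay windows of a scalar series."""
    x = np.asarray(series, dtype=np.float64)
    if m < 2:
        raise InvalidConfigError("embedding dimension m must be >= 2")
    if tau < 1:
        raise InvalidConfigError("delay tau must be >= 1")
    if not np.all(np.isfinite(x)):
        raise InvalidConfigError("series contains non-finite values")
    n = x.size
    n_windows = n - (m - 1) * tau
    if n_windows < 2:
        raise InsufficientDataError(
            f"series of length {n} too short for m={m}, tau={tau}"
        )
    # windows[i] = (x[i], x[i+tau], ..., x[i+(m-1)tau])
    windows = np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]
    perms = np.argsort(windows, axis=1, kind="stable")  # ties keep temporal order
    pattern_ids = _permutation_index(perms.astype(np.int64), m)
    counts = np.bincount(pattern_ids, minlength=math.factorial(m)).astype(np.int64)
    probs = counts / counts.sum()
    nz = probs[probs > 0]
    h = float(-(nz * np.log(nz)).sum())
    return OrdinalPatternDistribution(
        m=m, tau=tau, counts=counts, probabilities=probs,
        raw_entropy=h, pe=h / math.log(math.factorial(m)),
    )


def permutation_entropy(series: np.ndarray, m: int = 3, tau: int = 1) -> float:
    """Normalized permutation entropy in [0, 1]; 0 for a monotone series,
    → 1 for long i.i.d. noise."""
    return ordinal_pattern_distribution(series, m=m, tau=tau).pe


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

@dataclass
class TemplateMatchCounts:
    m: int
    r: float
    a: int  # (m+1)-length matches
    b: int  # m-length matches
    se: float


@numba.njit(cache=True)
def _se_pair_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    n = x.shape[0]
    nt = n - m  # both template lengths use the first n-m start indices
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) >= r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return a, b


def sample_entropy_counts(series: np.ndarray, m: int = 2, r: float | None = None
                          ) -> TemplateMatchCounts:
    """Template-match counts A, B and SE = −ln(A/B).

    Both template lengths are evaluated over the same N − m start indices
    (Richman & Moorman convention); matches use strict Chebyshev distance < r
    over unordered pairs i ≠ j.
    """
    x = np.ascontiguousarray(series, dtype=np.float64)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"need at least m+2={m + 2} samples, got {n}")
    if r is None:
        sd = x.std(ddof=0)
        if sd == 0:
            raise DegenerateInputError("constant series: tolerance r = 0.2 SD is zero")
        r = 0.2 * sd
    if r <= 0:
        raise InvalidConfigError("tolerance r must be positive")
    a, b = _se_pair_counts(x, m, float(r))
    if b == 0:
        raise UndefinedEntropyError("no length-m template matches (B = 0)")
    if a == 0:
        raise UndefinedEntropyError("no length-(m+1) template matches (A = 0)")
    return TemplateMatchCounts(m=m, r=float(r), a=int(a), b=int(b),
                               se=float(-np.log(a / b)))


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None,
                   window_seconds: float | None = None, fs: float | None = None
                   ) -> float:
    """Sample entropy of a scalar series.

    ``window_seconds`` (with ``fs``) optionally averages SE over non-overlapping
    windows instead of the full series — a documented runtime knob, off by
    default.  The tolerance r defaults to 0.2 × SD of each analyzed stretch.
    """
    x = np.asarray(series, dtype=np.float64)
    if window_seconds is None:
        return sample_entropy_counts(x, m=m, r=r).se
    if fs is None:
        raise InvalidConfigError("window_seconds requires fs")
    w = int(round(window_seconds * fs))
    if w < m + 2:
        raise InvalidConfigError("window too short for sample entropy")
    n_win = x.size // w
    if n_win == 0:
        return sample_entropy_counts(x, m=m, r=r).se
    vals = [sample_entropy_counts(x[i * w:(i + 1) * w], m=m, r=r).se
            for i in range(n_win)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Delay estimation and M-DCPSR
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased normalized autocorrelation R(0..max_lag) of the centered series."""
    x = np.asarray(series, dtype=np.float64)
    xc = x - x.mean()
    ssd = float(xc @ xc)
    if ssd == 0:
        raise DegenerateInputError("constant series has no autocorrelation structure")
    n = x.size
    # full autocorrelation by FFT, keep non-negative lags
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    return acov / ssd


def estimate_delay_autocorr(
    series: np.ndarray,
    fs: float = 250.0,
    delay_rule: Literal["larger_side", "nearest_zero"] = "larger_side",
) -> int:
    """Embedding delay from the first zero crossing of the autocorrelation.

    At the first lag j with R(j−1)·R(j) ≤ 0 the delay is picked by comparing
    |R| on the two sides of the crossing.  The default rule takes τ = j when
    |R(j−1)| ≤ |R(j)| and τ = j−1 otherwise (the side with the *larger*
    magnitude); ``nearest_zero`` takes the side whose |R| is smaller.  If no
    crossing occurs within lag ⌊N/2⌋ the fallback is fs/10 rounded, with a
    warning.
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    if n < 4:
        raise InsufficientDataError("need at least 4 samples to estimate a delay")
    cap = n // 2
    r = autocorrelation(x, cap)
    for j in range(1, cap + 1):
        if r[j - 1] * r[j] <= 0:
            if delay_rule == "larger_side":
                tau = j if abs(r[j - 1]) <= abs(r[j]) else j - 1
            elif delay_rule == "nearest_zero":
                tau = j if abs(r[j]) <= abs(r[j - 1]) else j - 1
            else:
                raise InvalidConfigError(f"unknown delay_rule {delay_rule!r}")
            return max(tau, 1)
    tau = max(1, int(round(fs / 10.0)))
    logger.warning(
        "autocorrelation has no zero crossing within lag %d; falling back to tau=%d",
        cap, tau,
    )
    return tau


@dataclass
class PhaseSpaceModel:
    tau: int
    points: np.ndarray    # (n_points, 3)
    centroid: np.ndarray  # (3,)
    distances: np.ndarray
    mdcpsr: float


def phase_space_model(series: np.ndarray, tau: int) -> PhaseSpaceModel:
    """3-D delay embedding, centroid, and distances from the centroid."""
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    n_pts = n - 2 * tau
    if n_pts < 3:
        raise InsufficientDataError(
            f"only {n_pts} embedded points at tau={tau}; need at least 3"
        )
    pts = np.column_stack([x[:n_pts], x[tau:tau + n_pts], x[2 * tau:2 * tau + n_pts]])
    centroid = pts.mean(axis=0)
    dists = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
    return PhaseSpaceModel(tau=tau, points=pts, centroid=centroid,
                           distances=dists, mdcpsr=float(np.median(dists)))


def mdcpsr(
    series: np.ndarray,
    tau: int | None = None,
    fs: float = 250.0,
    delay_rule: Literal["larger_side", "nearest_zero"] = "larger_side",
) -> float:
    """Median distance from the centroid of the 3-D phase-space reconstruction.

    The delay is estimated from the autocorrelation unless given explicitly.
    Homogeneous of degree 1 in the signal amplitude.
    """
    if tau is None:
        tau = estimate_delay_autocorr(series, fs=fs, delay_rule=delay_rule)
    if tau < 1:
        raise InvalidConfigError("tau must be >= 1")
    return phase_space_model(series, tau).mdcpsr


def nonlinear_feature_vector(
    epoch,
    pe_m: int = 3,
    pe_tau: int = 1,
    se_m: int = 2,
    se_window_seconds: float | None = None,
    delay_rule: Literal["larger_side", "nearest_zero"] = "larger_side",
) -> dict[str, float]:
    """PE, SE and M-DCPSR for every channel of a preprocessed epoch, keyed
    ``PE__{ch}``, ``SE__{ch}``, ``MDCPSR__{ch}``."""
    out: dict[str, float] = {}
    for c, ch in enumerate(epoch.channels):
        x = epoch.data[c]
        out[f"PE__{ch}"] = permutation_entropy(x, m=pe_m, tau=pe_tau)
    for c, ch in enumerate(epoch.channels):
        out[f"SE__{ch}"] = sample_entropy(
            epoch.data[c], m=se_m,
            window_seconds=se_window_seconds, fs=epoch.fs,
        )
    for c, ch in enumerate(epoch.channels):
        out[f"MDCPSR__{ch}"] = mdcpsr(epoch.data[c], fs=epoch.fs, delay_rule=delay_rule)
    return out
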