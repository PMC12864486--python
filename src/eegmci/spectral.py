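"""Spectral features: Welch PSD, sub-band powers, PSD ratios, PSD entropy.

Band powers are Riemann sums of the Welch PSD over half-open bins
``lo <= f < hi`` (half-open so the shared edges at 4, 8, 13 and 30 Hz are
counted exactly once).  The five slowing ratios are

    Ratio1 = δ/α            Ratio2 = θ/α
    Ratio3 = δ/(α+β)        Ratio4 = θ/(α+β)
    Ratio5 = (δ+θ)/(α+β+γ)

and the per-band PSD entropy is the Shannon entropy of the normalized in-band
PSD bin sequence, natural log, so 0 ≤ E ≤ ln(N_bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .channels import BAND_NAMES, BANDS
from .core import EegEpoch
from .errors import DegenerateInputError, InsufficientDataError, InvalidInputError


@dataclass
class WelchParams:
    """Welch estimator settings: 2 s Hann segments at 50% overlap give a
    0.5 Hz grid at 250 Hz, resolving the 0.5 Hz delta edge."""

    segment_seconds: float = 2.0
    overlap_fraction: float = 0.5
    window: str = "hann"


@dataclass
class SpectralDecomposition:
    """Per-channel Welch PSD on a uniform frequency grid (µV²/Hz)."""

    frequencies: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    channels: tuple[str, ...]
    params: WelchParams = field(default_factory=WelchParams)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def welch_psd(epoch: EegEpoch, params: WelchParams | None = None) -> SpectralDecomposition:
    """Welch PSD estimate of every channel."""
    params = params or WelchParams()
    nperseg = int(round(params.segment_seconds * epoch.fs))
    if epoch.n_samples < nperseg:
        raise InsufficientDataError(
            f"epoch ({epoch.n_samples} samples) shorter than one Welch segment ({nperseg})"
        )
    noverlap = int(round(params.overlap_fraction * nperseg))
    freqs, psd = welch(
        epoch.data, fs=epoch.fs, window=params.window,
        nperseg=nperseg, noverlap=noverlap, axis=-1,
    )
    return SpectralDecomposition(frequencies=freqs, psd=psd,
                                 channels=epoch.channels, params=params)


def band_powers(spec: SpectralDecomposition,
                bands: dict[str, tuple[float, float]] = BANDS) -> dict[str, np.ndarray]:
    """Per-channel band power: df × Σ PSD bins with lo <= f < hi."""
    fmax_needed = max(hi for _, hi in bands.values())
    fmin_needed = min(lo for lo, _ in bands.values())
    f = spec.frequencies
    if f[0] > fmin_needed or f[-1] < fmax_needed - spec.df:
        raise InvalidInputError(
            f"frequency grid [{f[0]}, {f[-1]}] Hz does not cover the bands"
        )
    powers = {}
    for name, (lo, hi) in bands.items():
        mask = (f >= lo) & (f < hi)
        powers[name] = spec.psd[:, mask].sum(axis=1) * spec.df
    return powers


def psd_ratios(powers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """The five spectral-slowing ratios per channel."""
    d, t = np.asarray(powers["delta"], float), np.asarray(powers["theta"], float)
    a, b, g = (np.asarray(powers[k], float) for k in ("alpha", "beta", "gamma"))
    denoms = {"Ratio1": a, "Ratio2": a, "Ratio3": a + b, "Ratio4": a + b,
              "Ratio5": a + b + g}
    for name, den in denoms.items():
        if np.any(den <= 0):
            raise DegenerateInputError(f"zero denominator band power for {name}")
    return {
        "Ratio1": d / a,
        "Ratio2": t / a,
        "Ratio3": d / (a + b),
        "Ratio4": t / (a + b),
        "Ratio5": (d + t) / (a + b + g),
    }


def psd_entropy(spec: SpectralDecomposition, band: str | tuple[float, float],
                base: float | None = None) -> np.ndarray:
    """Shannon entropy of the normalized PSD bins within one band, per channel.

    ``base=None`` means natural log.  0·log 0 is treated as 0.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    mask = (spec.frequencies >= lo) & (spec.frequencies < hi)
    if not mask.any():
        raise InvalidInputError(f"no frequency bins inside [{lo}, {hi}) Hz")
    p = spec.psd[:, mask]
    totals = p.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise DegenerateInputError("all-zero PSD within the band")
    probs = p / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(probs), 0.0)
    ent = -terms.sum(axis=1)
    if base is not None:
        ent = ent / np.log(base)
    return ent


def spectral_feature_vector(epoch: EegEpoch,
                            params: WelchParams | None = None) -> dict[str, float]:
    """All spectral features of one recording, keyed by canonical name
    (``Ratio{k}__{channel}``, ``PSDE_{band}__{channel}``)."""
    spec = welch_psd(epoch, params)
    powers = band_powers(spec)
    ratios = psd_ratios(powers)
    out: dict[str, float] = {}
    for k in range(1, 6):
        vals = ratios[f"Ratio{k}"]
        for c, ch in enumerate(epoch.channels):
            out[f"Ratio{k}__{ch}"] = float(vals[c])
    for band in BAND_NAMES:
        ent = psd_entropy(spec, band)
        for c, ch in enumerate(epoch.channels):
            out[f"PSDE_{band}__{ch}"] = float(ent[c])
    return out
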