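"""Welch spectral analysis and HRV band powers.

Computed on the ectopic-corrected, 4 Hz-resampled, detrended tachogram.
The periodogram uses Blackman windows of 256 samples with 50% overlap
(8 averaged windows for a 1200-sample 5-min segment; a final partial
window is discarded, not zero-padded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import signal as sps

from .signals import UniformSeries

__all__ = ["PowerSpectrum", "BandPowers", "welch_psd", "band_powers", "BAND_EDGES"]

#: standard HRV band edges in Hz, half-open [lo, hi)
BAND_EDGES = {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}
#: the literal band table with LF starting at 0 (VLF ⊂ LF); selectable by config
BAND_EDGES_LF_INCLUDES_VLF = {"vlf": (0.0, 0.04), "lf": (0.0, 0.15), "hf": (0.15, 0.40)}


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    density: np.ndarray  # ms²/Hz, one-sided
    resolution: float
    window: str = "blackman-256"
    overlap: float = 0.5

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < -1e-12):
            raise ValueError("spectral density must be non-negative")


@dataclass
class BandPowers:
    vlf: float
    lf: float
    hf: float
    tp: float
    lf_hf: float
    lfn: float
    hfn: float


def welch_psd(
    series: UniformSeries, window_len: int = 256, overlap: float = 0.5
) -> PowerSpectrum:
    """One-sided Welch periodogram with a Blackman window.

    Window-power normalised so the integral over [0, fs/2] matches the series
    variance for stationary inputs (Parseval).
    """
    n = len(series)
    if n < window_len:
        raise ValueError(
            f"Welch PSD needs at least {window_len} samples, got {n}"
        )
    noverlap = int(round(window_len * overlap))
    freqs, density = sps.welch(
        series.values,
        fs=series.fs,
        window=sps.get_window("blackman", window_len),
        nperseg=window_len,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )
    return PowerSpectrum(
        freqs=freqs,
        density=density,
        resolution=series.fs / window_len,
        window=f"blackman-{window_len}",
        overlap=overlap,
    )


def _band_integral(psd: PowerSpectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over the half-open band [lo, hi)."""
    f, d = psd.freqs, psd.density
    mask = (f >= lo) & (f < hi)
    if mask.sum() < 2:
        return 0.0
    return float(integrate.trapezoid(d[mask], f[mask]))


def band_powers(
    psd: PowerSpectrum, edges: dict[str, tuple[float, float]] | None = None
) -> BandPowers:
    """Integrate the PSD into VLF/LF/HF absolute and normalised powers.

    ``LF/HF`` and the normalised powers are NaN sentinels when their
    denominators vanish; denominators below 1e-12 ms² (numerical residue of
    an essentially zero spectrum) count as vanished.
    """
    edges = edges or BAND_EDGES
    if psd.freqs[-1] < 0.4:
        raise ValueError("PSD must cover 0-0.4 Hz for HRV band powers")
    eps = 1e-12
    vlf = _band_integral(psd, *edges["vlf"])
    lf = _band_integral(psd, *edges["lf"])
    hf = _band_integral(psd, *edges["hf"])
    tp = float(integrate.trapezoid(psd.density, psd.freqs))
    lf_hf = lf / hf if hf > eps else float("nan")
    lfn = lf / tp if tp > eps else float("nan")
    hfn = hf / tp if tp > eps else float("nan")
    return BandPowers(vlf=vlf, lf=lf, hf=hf, tp=tp, lf_hf=lf_hf, lfn=lfn, hfn=hfn)
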