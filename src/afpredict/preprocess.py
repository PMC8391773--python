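"""ECG/RR preprocessing: R-peak detection, impulse rejection, resampling, detrending.

Three preprocessed views of a 5-minute segment feed the feature families:

* the raw RR series (time-domain and nonlinear features);
* the ectopic-corrected, 4 Hz cubic-spline-resampled, detrended tachogram
  (frequency-domain features);
* the *uncorrected*, 4 Hz-resampled, detrended tachogram (time-frequency
  features) — ectopy is deliberately left in because its variability carries
  the predictive signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signals import FLAG_ECTOPIC, FLAG_NORMAL, EcgRecord, RRSeries, UniformSeries

__all__ = [
    "detect_r_peaks",
    "rr_from_peaks",
    "impulse_rejection",
    "resample_uniform",
    "detrend",
    "extract_segment",
    "PreprocessedSegment",
    "preprocess_rr",
]


def detect_r_peaks(ecg: EcgRecord, channel: int = 0) -> np.ndarray:
    """Detect QRS complexes with a derivative/energy detector.

    Band-pass 5–25 Hz, squared derivative, 150 ms moving-window integration,
    adaptive threshold with a 200 ms refractory period; each detection is
    refined to the local absolute maximum of the band-passed signal within
    ±50 ms.  Returns strictly increasing sample indices.
    """
    x = ecg.channel(channel)
    fs = ecg.fs
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of signal for QRS detection")
    if fs < 100:
        raise ValueError("QRS detection requires fs >= 100 Hz")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no QRS detected", stacklevel=2)
        return np.array([], dtype=int)

    sos = sps.butter(3, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    thr = 0.2 * np.percentile(integ, 99)
    cand, _ = sps.find_peaks(integ, height=thr, distance=refractory)
    if len(cand) == 0:
        warnings.warn("no QRS candidates above threshold", stacklevel=2)
        return np.array([], dtype=int)

    # refine each candidate to the local |bp| maximum within ±50 ms
    half = int(round(0.050 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.asarray(sorted(set(peaks)), dtype=int)
    # enforce the refractory after refinement
    keep = [0]
    for i in range(1, len(peaks)):
        if peaks[i] - peaks[keep[-1]] >= refractory:
            keep.append(i)
        elif np.abs(bp[peaks[i]]) > np.abs(bp[peaks[keep[-1]]]):
            keep[-1] = i
    return peaks[keep]


def rr_from_peaks(peaks: np.ndarray, fs: float) -> RRSeries:
    """Convert R-peak sample indices to an RR series (ms)."""
    peaks = np.asarray(peaks)
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to form RR intervals")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak indices must be strictly increasing")
    times = peaks / fs
    intervals = np.diff(times) * 1000.0
    return RRSeries(times, intervals)


def impulse_rejection(
    rr: RRSeries, tau: float = 4.0, mode: str = "interpolate"
) -> RRSeries:
    """Flag and correct ectopic intervals with a median/MAD impulse filter.

    Interval ``i`` is flagged when

        D(i) = |RR_i − median(RR)| / (1.483 · max(MAD(RR), 1 ms)) > tau,

    the 1.483 factor making the MAD a consistent estimator of the standard
    deviation under normality and the 1 ms floor keeping quasi-constant
    segments well defined.  Flagged intervals are replaced by cubic-spline
    interpolation over the unflagged neighbours (``mode="interpolate"``) or
    dropped (``mode="delete"``).  Idempotent: the statistic is computed from
    the original series only.
    """
    if rr.n_intervals < 20:
        raise ValueError("impulse rejection needs at least 20 intervals")
    if mode not in ("interpolate", "delete"):
        raise ValueError(f"unknown ectopic mode {mode!r}")
    x = rr.intervals
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    d = np.abs(x - med) / (1.483 * max(mad, 1.0))
    flagged = d > tau
    if np.all(flagged):
        raise ValueError("segment unusable: every interval flagged as ectopic")
    if not np.any(flagged):
        out = rr.copy()
        out.flags[:] = FLAG_NORMAL
        return out

    t = rr.interval_times
    good = ~flagged
    if mode == "delete":
        keep_beats = np.concatenate([[True], good])
        times = rr.beat_times[keep_beats]
        return RRSeries(times, np.diff(times) * 1000.0)

    if good.sum() < 4:
        raise ValueError("segment unusable: too few normal intervals to interpolate")
    spline = CubicSpline(t[good], x[good])
    corrected = x.copy()
    # clip spline overshoot (clustered flags) into the range of normal beats
    corrected[flagged] = np.clip(
        spline(t[flagged]), x[good].min(), x[good].max()
    )
    flags = np.where(flagged, FLAG_ECTOPIC, FLAG_NORMAL).astype(np.int8)
    # beat times are re-accumulated so the corrected tachogram is self-consistent
    beat_times = rr.beat_times[0] + np.concatenate(
        [[0.0], np.cumsum(corrected) / 1000.0]
    )
    return RRSeries(beat_times, corrected, flags)


def resample_uniform(rr: RRSeries, fs: float = 4.0) -> UniformSeries:
    """Cubic-spline resample the tachogram onto a uniform 1/fs grid.

    The interval value is anchored at the closing beat of its pair; the
    spline is evaluated on the grid spanning first to last beat time (the
    sub-second stretch before the first anchor is spline-extrapolated).  A
    300 s segment yields 1200 ± 2 samples at 4 Hz.
    """
    if rr.n_intervals < 3 or rr.duration_s < 2.0:
        raise ValueError("resampling needs >= 4 beats spanning >= 2 s")
    t = rr.interval_times
    spline = CubicSpline(t, rr.intervals)
    grid = np.arange(rr.beat_times[0], rr.beat_times[-1] + 1e-12, 1.0 / fs)
    return UniformSeries(spline(grid), fs=fs, start_time=float(grid[0]))


def detrend(series: UniformSeries, cutoff: float = 0.01) -> UniformSeries:
    """Zero-phase high-pass detrending (2nd-order Butterworth, forward-backward).

    Removes slow trends below ``cutoff`` Hz while leaving the LF/HF
    oscillations essentially untouched; any residual DC offset left by the
    finite-length filtering is subtracted so the output mean is ~0.
    """
    n = len(series)
    sos = sps.butter(2, cutoff, btype="highpass", fs=series.fs, output="sos")
    min_len = 3 * max(int(series.fs / cutoff / 10), 25)
    if n <= min_len:
        raise ValueError(f"detrending needs more than {min_len} samples, got {n}")
    padlen = min(n - 1, int(series.fs / cutoff))
    out = sps.sosfiltfilt(sos, series.values, padlen=padlen)
    out = out - out.mean()
    return series.replace(out)


def extract_segment(
    record: EcgRecord | RRSeries,
    onset_s: float,
    offset_s: float = 0.0,
    len_s: float = 300.0,
):
    """Extract the window of length ``len_s`` ending ``offset_s`` before ``onset_s``.

    With offset 0 this is the window immediately before the (AF) onset; with
    offset 600 it covers the data from 15 to 10 minutes before onset.  For
    control records ``onset_s`` is an arbitrary stated reference point.
    """
    stop = onset_s - offset_s
    start = stop - len_s
    t0 = record.beat_times[0] if isinstance(record, RRSeries) else 0.0
    if start < t0 - 1e-9:
        raise ValueError(
            f"record too short: window [{start:.1f}, {stop:.1f}] s needs "
            f"{onset_s - offset_s - t0:.1f} s of history, window is {len_s:.0f} s"
        )
    return record.slice_time(start, stop)


@dataclass
class PreprocessedSegment:
    """The three preprocessed views of one 5-min segment."""

    rr_raw: RRSeries
    freq_series: UniformSeries  # ectopic-corrected, resampled, detrended
    tf_series: UniformSeries    # uncorrected, resampled, detrended


def preprocess_rr(
    rr: RRSeries,
    tau: float = 4.0,
    fs_resample: float = 4.0,
    detrend_cutoff: float = 0.01,
    ectopic_mode: str = "interpolate",
) -> PreprocessedSegment:
    """Produce all three preprocessing paths from a raw RR series."""
    corrected = impulse_rejection(rr, tau=tau, mode=ectopic_mode)
    freq_series = detrend(resample_uniform(corrected, fs_resample), detrend_cutoff)
    tf_series = detrend(resample_uniform(rr, fs_resample), detrend_cutoff)
    return PreprocessedSegment(rr_raw=rr, freq_series=freq_series, tf_series=tf_series)
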