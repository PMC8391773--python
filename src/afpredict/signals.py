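"""Core signal containers shared across the pipeline.

Conventions used throughout the package:

* all RR intervals are in **milliseconds**;
* all times (beat times, window boundaries) are in **seconds**;
* undefined feature values (a ratio with a zero denominator, entropy with no
  template matches) are reported as ``math.nan`` sentinels rather than raised,
  so that callers can decide whether a degenerate segment is an error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EcgRecord",
    "RRSeries",
    "UniformSeries",
    "SubbandDecomposition",
    "Envelope",
]

#: per-interval quality flags
FLAG_NORMAL = 0
FLAG_ECTOPIC = 1


@dataclass
class EcgRecord:
    """A multi-channel ECG waveform in millivolts.

    Attributes
    ----------
    samples : (n_channels, n_samples) float array, mV
    fs : sampling rate in Hz
    channel_names : one name per channel
    record_id : free-text identifier
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[1] == 0:
            raise ValueError("ECG record has no samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, index: int = 0) -> np.ndarray:
        return self.samples[index]

    def slice_time(self, start_s: float, stop_s: float) -> "EcgRecord":
        """Extract the sub-record covering [start_s, stop_s)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"window [{start_s}, {stop_s}) s outside record of "
                f"{self.duration_s:.1f} s"
            )
        return EcgRecord(
            self.samples[:, i0:i1], self.fs, list(self.channel_names), self.record_id
        )


@dataclass
class RRSeries:
    """A beat-indexed tachogram.

    ``beat_times`` holds the times of the R peaks in seconds (length n+1 for n
    intervals); ``intervals`` the RR intervals in milliseconds; ``flags`` one
    quality flag per interval (``FLAG_NORMAL`` / ``FLAG_ECTOPIC``).
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.intervals), dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
        if len(self.intervals) != len(self.beat_times) - 1:
            raise ValueError(
                "need exactly one interval per consecutive beat pair: "
                f"{len(self.beat_times)} beats vs {len(self.intervals)} intervals"
            )
        if len(self.flags) != len(self.intervals):
            raise ValueError("one flag per interval required")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def interval_times(self) -> np.ndarray:
        """Time anchor of each interval: the closing beat of its pair (s)."""
        return self.beat_times[1:]

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.beat_times.copy(), self.intervals.copy(), self.flags.copy()
        )

    def slice_time(self, start_s: float, stop_s: float) -> "RRSeries":
        """Beats (and the intervals they close) falling inside [start_s, stop_s]."""
        keep = (self.beat_times >= start_s) & (self.beat_times <= stop_s)
        idx = np.flatnonzero(keep)
        if len(idx) < 2:
            raise ValueError("fewer than two beats in requested window")
        i0, i1 = idx[0], idx[-1]
        return RRSeries(
            self.beat_times[i0 : i1 + 1],
            self.intervals[i0:i1],
            self.flags[i0:i1],
        )


@dataclass
class UniformSeries:
    """An evenly sampled tachogram (ms) at ``fs`` Hz starting at ``start_time`` s."""

    values: np.ndarray
    fs: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("uniform series must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.fs

    def replace(self, values: np.ndarray) -> "UniformSeries":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SubbandDecomposition:
    """An ordered set of component signals with nominal center frequencies.

    ``components`` is a (K, n) matrix (ms); the shape is shared between the
    complex-demodulation components and time-domain wavelet band
    reconstructions so downstream envelope/feature code is agnostic to the
    method that produced them.
    """

    components: np.ndarray
    center_freqs: np.ndarray
    bandwidth: float
    fs: float
    method: str = "vfcdm"

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)
        if self.components.shape[0] != len(self.center_freqs):
            raise ValueError("one center frequency per component required")

    @property
    def K(self) -> int:
        return self.components.shape[0]

    def component(self, i: int) -> np.ndarray:
        """1-based component accessor (band 1 = first row)."""
        if not 1 <= i <= self.K:
            raise IndexError(f"component index {i} outside 1..{self.K}")
        return self.components[i - 1]


@dataclass
class Envelope:
    """Instantaneous amplitude/phase of an analytic signal.

    ``valid_mask`` marks interior samples unaffected by the edge transients of
    the discrete Hilbert transform.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    valid_mask: np.ndarray
    fs: float = 4.0

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if np.any(self.amplitude < 0):
            raise ValueError("instantaneous amplitude must be non-negative")

    @property
    def valid_amplitude(self) -> np.ndarray:
        return self.amplitude[self.valid_mask]
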