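"""Synthetic RR tachograms and ECG with controllable premature atrial beats.

The generator emulates the structure the prediction method exploits: a normal
sinus rhythm tachogram with low-frequency (Mayer-wave) and high-frequency
(respiratory) oscillations plus white beat-to-beat noise, into which premature
atrial contractions (PACs) are injected at a configurable rate.  A PAC
shortens one interval to a fraction ``c`` of its sinus value and is followed
by a compensatory pause so that the couplet sum — and hence the mean heart
rate — is preserved.  Every generator is a pure function of its configuration
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signals import EcgRecord, RRSeries

__all__ = [
    "SynthConfig",
    "SynthRecord",
    "generate_nsr_rr",
    "inject_pacs",
    "generate_cohort",
    "synth_ecg",
]

LABEL_PREAF = "pre-AF"
LABEL_CONTROL = "control"


@dataclass
class SynthConfig:
    """Parameters of the synthetic tachogram.

    Defaults describe a 5-minute normal-sinus-rhythm segment at 75 bpm with
    LF and HF oscillations inside the standard HRV bands (LF at 0.095 Hz to
    sit away from the 0.04/0.15 Hz band edges) and mild beat-to-beat noise.
    """

    duration_s: float = 300.0
    mean_rr_ms: float = 800.0
    lf_amp_ms: float = 20.0
    lf_freq_hz: float = 0.095
    hf_amp_ms: float = 10.0
    hf_freq_hz: float = 0.25
    noise_sd_ms: float = 5.0
    pac_rate_per_min: float = 0.0
    pac_prematurity: tuple[float, float] = (0.55, 0.80)
    pac_ramp: float = 0.0  # linear multiplier of PAC density toward segment end
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValueError("mean RR must be positive")
        if self.pac_rate_per_min < 0:
            raise ValueError("PAC rate must be non-negative")
        lo, hi = self.pac_prematurity
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("prematurity fraction must lie in (0, 1)")


@dataclass
class SynthRecord:
    """A generated tachogram with its ground truth."""

    rr: RRSeries
    pac_truth: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ecg: EcgRecord | None = None
    label: str = LABEL_CONTROL
    config: SynthConfig | None = None


def generate_nsr_rr(cfg: SynthConfig) -> SynthRecord:
    """Generate a PAC-free normal-sinus-rhythm tachogram.

    Interval k is ``mean + lf_amp*sin(2π f_LF t_k) + hf_amp*sin(2π f_HF t_k)
    + N(0, noise_sd²)`` with ``t_k`` the cumulative beat time, so the
    spectral content of the tachogram is known by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    intervals: list[float] = []
    times = [0.0]
    t = 0.0
    while t < cfg.duration_s:
        rr = (
            cfg.mean_rr_ms
            + cfg.lf_amp_ms * np.sin(2 * np.pi * cfg.lf_freq_hz * t)
            + cfg.hf_amp_ms * np.sin(2 * np.pi * cfg.hf_freq_hz * t)
            + rng.normal(0.0, cfg.noise_sd_ms)
        )
        if rr <= 200.0:
            raise ValueError(
                "configuration produces RR intervals <= 200 ms; "
                "reduce amplitudes/noise or raise mean RR"
            )
        intervals.append(rr)
        t += rr / 1000.0
        times.append(t)
    rr_series = RRSeries(np.asarray(times), np.asarray(intervals))
    rec = SynthRecord(rr=rr_series, label=LABEL_CONTROL, config=cfg)
    if cfg.pac_rate_per_min > 0:
        rec = inject_pacs(
            rec, cfg.pac_rate_per_min, cfg.pac_prematurity,
            seed=rng.integers(2**31), ramp=cfg.pac_ramp,
        )
    return rec


def inject_pacs(
    rec: SynthRecord,
    rate_per_min: float,
    prematurity: tuple[float, float] = (0.55, 0.80),
    seed: int = 0,
    ramp: float = 0.0,
) -> SynthRecord:
    """Inject premature beats with compensatory pauses.

    At each chosen site k the interval ``RR_k`` becomes ``c·RR_k`` (the
    premature beat, ``c`` drawn uniformly from ``prematurity``) and
    ``RR_{k+1}`` becomes ``(2−c)·RR_k + (RR_{k+1} − RR_k)``, preserving the
    couplet sum exactly.  Sites are sampled without adjacency so pauses never
    overlap.  ``ramp > 0`` biases site density linearly toward the segment
    end (density ∝ 1 + ramp·(t/T)), emulating ectopy accelerating toward an
    AF onset, while keeping the expected total count at ``rate_per_min``.
    """
    if rate_per_min < 0:
        raise ValueError("PAC rate must be non-negative")
    if rate_per_min == 0:
        return rec
    rr = rec.rr
    n = rr.n_intervals
    n_pacs = int(round(rate_per_min * rr.duration_s / 60.0))
    if n_pacs == 0:
        return rec
    # candidate sites leave room for the compensatory pause
    candidates = np.arange(0, n - 1)
    if n_pacs > (len(candidates) + 1) // 2:
        raise ValueError(
            f"PAC rate {rate_per_min}/min needs {n_pacs} non-adjacent sites; "
            f"only {(len(candidates) + 1) // 2} available"
        )
    rng = np.random.default_rng(seed)
    frac = rr.interval_times[candidates] / rr.beat_times[-1]
    weights = 1.0 + ramp * frac
    sites: list[int] = []
    avail = candidates.copy()
    w = weights.copy()
    for _ in range(n_pacs):
        if len(avail) == 0:
            raise ValueError("cannot place PACs without adjacency")
        pick = rng.choice(avail, p=w / w.sum())
        sites.append(int(pick))
        keep = np.abs(avail - pick) > 1
        avail, w = avail[keep], w[keep]
    sites_arr = np.sort(np.asarray(sites, dtype=int))

    intervals = rr.intervals.copy()
    lo, hi = prematurity
    for k in sites_arr:
        c = rng.uniform(lo, hi)
        base = intervals[k]
        intervals[k] = c * base
        intervals[k + 1] = (2.0 - c) * base + (intervals[k + 1] - base)
    beat_times = rr.beat_times[0] + np.concatenate(
        [[0.0], np.cumsum(intervals) / 1000.0]
    )
    new_rr = RRSeries(beat_times, intervals)
    return SynthRecord(
        rr=new_rr,
        pac_truth=sites_arr,
        ecg=rec.ecg,
        label=LABEL_PREAF,
        config=rec.config,
    )


def generate_cohort(
    n_per_class: int,
    control_cfg: SynthConfig | None = None,
    preaf_cfg: SynthConfig | None = None,
    seed: int = 0,
) -> list[SynthRecord]:
    """Generate a labeled cohort of controls and pre-AF records.

    Mirrors the 25-control / 25-pre-AF study design: controls use a low (or
    zero) PAC rate, pre-AF records a high one, optionally with the PAC ramp.
    Per-record seeds are spawned from the master seed so records are
    reproducible and pairwise distinct.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 records per class")
    control_cfg = control_cfg or SynthConfig(pac_rate_per_min=0.5)
    preaf_cfg = preaf_cfg or SynthConfig(pac_rate_per_min=10.0)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * n_per_class)]
    records = []
    for i in range(n_per_class):
        rec = generate_nsr_rr(replace(control_cfg, seed=seeds[i]))
        rec.label = LABEL_CONTROL
        records.append(rec)
    for i in range(n_per_class):
        rec = generate_nsr_rr(replace(preaf_cfg, seed=seeds[n_per_class + i]))
        rec.label = LABEL_PREAF
        records.append(rec)
    return records


def _gaussian_bump(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def synth_ecg(
    rr: RRSeries,
    fs: float = 125.0,
    wander_amp_mv: float = 0.05,
    wander_freq_hz: float = 0.2,
    noise_sd_mv: float = 0.02,
    seed: int = 0,
) -> EcgRecord:
    """Render an ECG waveform from beat times with a P-QRS-T bump template.

    Each beat places a 1 mV R wave (80 ms QRS footprint), small Q/S troughs,
    a P wave 180 ms before and a T wave 280 ms after the R peak.  Baseline
    wander (0.2 Hz sinusoid) and white measurement noise are added on top.
    The R-peak ground truth is exactly ``rr.beat_times``.
    """
    t_end = rr.beat_times[-1] + 0.5
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) / fs
    sig = np.zeros(n)
    # QRS width 80 ms: R sigma 13 ms keeps ~99% of the bump inside the window
    for bt in rr.beat_times:
        sig += _gaussian_bump(t, bt, 0.013, 1.0)          # R
        sig += _gaussian_bump(t, bt - 0.028, 0.009, -0.12)  # Q
        sig += _gaussian_bump(t, bt + 0.028, 0.009, -0.15)  # S
        sig += _gaussian_bump(t, bt - 0.18, 0.025, 0.10)    # P
        sig += _gaussian_bump(t, bt + 0.28, 0.045, 0.30)    # T
    rng = np.random.default_rng(seed)
    sig += wander_amp_mv * np.sin(2 * np.pi * wander_freq_hz * t)
    sig += rng.normal(0.0, noise_sd_mv, size=n)
    return EcgRecord(sig[np.newaxis, :], fs, ["synthetic"], "synthetic-ecg")
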