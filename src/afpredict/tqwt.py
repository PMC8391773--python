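"""Tunable Q-factor wavelet transform (TQWT) with perfect reconstruction.

The transform iterates a two-channel frequency-domain filter bank on its
low-pass channel.  With Q-factor ``Q``, redundancy ``r`` and ``J`` levels the
channel scalings are β = 2/(Q+1) (high-pass) and α = 1 − β/r (low-pass); each
stage shrinks the low-pass channel length by the factor α.  The transition
between channels uses the Daubechies-type function

    θ(ω) = ½ (1 + cos ω) √(2 − cos ω),   ω ∈ [0, π],

which is power-complementary (θ(ω)² + θ(π−ω)² = 1), so the analysis/synthesis
pair reconstructs perfectly and the sub-band energies sum exactly to the input
energy (a tight frame).  Channel lengths are rounded to even sizes per stage.

Wavelet band j = 1 is the highest-frequency band; the nominal center
frequency of band j is f_c(j) = α^j · (2−β)/(4α) · fs, which at Q=3, r=4,
J=17, fs=4 Hz reproduces the descending table 1.31, 1.15, 1.00, … 0.18 Hz
for j = 2..17.

Features: per-band energy, and a spectral-entropy feature ENT — the L2 norm
over time of the per-frame Shannon entropy (base 2) of the normalised
short-time spectrum of a band's time-domain reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import UniformSeries

__all__ = [
    "TqwtParams",
    "TqwtCoefficients",
    "tqwt_analyze",
    "tqwt_synthesize",
    "tqwt_center_frequencies",
    "subband_signal",
    "subband_energy",
    "spectral_entropy_feature",
]


@dataclass(frozen=True)
class TqwtParams:
    Q: float = 3.0
    r: float = 4.0
    J: int = 17
    fs: float = 4.0

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q-factor must be >= 1")
        if self.r < 3:
            raise ValueError("redundancy must be >= 3 to avoid excessive ringing")
        if self.J < 1:
            raise ValueError("need at least one decomposition level")
        if not 0 < self.alpha < 1:
            raise ValueError("low-pass scaling alpha must lie in (0, 1)")

    @property
    def beta(self) -> float:
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.r


@dataclass
class TqwtCoefficients:
    """J wavelet sub-band sequences (j=1 highest frequency) + final low-pass."""

    subbands: list[np.ndarray]
    lowpass: np.ndarray
    params: TqwtParams
    n_samples: int
    _stage_lengths: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def J(self) -> int:
        return len(self.subbands)

    def band(self, j: int) -> np.ndarray:
        """1-based accessor, j=1 the highest-frequency wavelet band."""
        if not 1 <= j <= self.J:
            raise IndexError(f"band index {j} outside 1..{self.J}")
        return self.subbands[j - 1]


def _theta(omega: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.cos(omega)) * np.sqrt(2.0 - np.cos(omega))


def _channel_lengths(n: int, alpha: float, beta: float) -> tuple[int, int]:
    n0 = 2 * int(round(alpha * n / 2.0))
    n1 = 2 * int(round(beta * n / 2.0))
    return n0, n1


def _afb(X: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Analysis filter bank on a unitary DFT spectrum of even length."""
    n = len(X)
    P = (n - n1) // 2                # pure pass-band bins (low-pass side)
    T = (n0 + n1 - n) // 2 - 1       # transition bins
    S = (n - n0) // 2                # pure high-pass bins before Nyquist
    t = np.arange(1, T + 1)
    trans = _theta(t / (T + 1) * np.pi)
    transrev = trans[::-1]

    V0 = np.zeros(n0, dtype=complex)
    V0[0] = X[0]
    V0[1 : P + 1] = X[1 : P + 1]
    V0[P + 1 : P + T + 1] = X[P + 1 : P + T + 1] * trans
    # V0[n0 // 2] stays 0 (new Nyquist)
    V0[n0 // 2 + 1 : n0 // 2 + 1 + T] = (
        X[n - P - T : n - P] * transrev
    )
    V0[n0 - P :] = X[n - P :]

    V1 = np.zeros(n1, dtype=complex)
    V1[1 : T + 1] = X[P + 1 : P + T + 1] * transrev
    V1[T + 1 : T + S + 2] = X[P + T + 1 : n // 2 + 1]   # includes input Nyquist
    V1[n1 // 2 + 1 : n1 // 2 + 1 + S] = X[n // 2 + 1 : n // 2 + 1 + S]
    V1[n1 - T :] = X[n - P - T : n - P] * transrev[::-1]
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, n: int) -> np.ndarray:
    """Synthesis filter bank: exact inverse of :func:`_afb`."""
    n0, n1 = len(V0), len(V1)
    P = (n - n1) // 2
    T = (n0 + n1 - n) // 2 - 1
    S = (n - n0) // 2
    t = np.arange(1, T + 1)
    trans = _theta(t / (T + 1) * np.pi)
    transrev = trans[::-1]

    Y = np.zeros(n, dtype=complex)
    Y[0] = V0[0]
    Y[1 : P + 1] = V0[1 : P + 1]
    Y[P + 1 : P + T + 1] = (
        V0[P + 1 : P + T + 1] * trans + V1[1 : T + 1] * transrev
    )
    Y[P + T + 1 : n // 2 + 1] = V1[T + 1 : T + S + 2]
    Y[n // 2 + 1 : n // 2 + 1 + S] = V1[n1 // 2 + 1 : n1 // 2 + 1 + S]
    Y[n - P - T : n - P] = (
        V0[n0 // 2 + 1 : n0 // 2 + 1 + T] * transrev + V1[n1 - T :] * transrev[::-1]
    )
    Y[n - P :] = V0[n0 - P :]
    return Y


def _stage_plan(n: int, params: TqwtParams) -> list[tuple[int, int, int]]:
    """(N, N0, N1) per stage; raises naming the max feasible J if too short."""
    plan = []
    cur = n
    for j in range(1, params.J + 1):
        n0, n1 = _channel_lengths(cur, params.alpha, params.beta)
        T = (n0 + n1 - cur) // 2 - 1
        if T < 0 or n0 >= cur or n1 < 8:
            raise ValueError(
                f"series of {n} samples supports at most J={j - 1} levels "
                f"at Q={params.Q}, r={params.r}"
            )
        plan.append((cur, n0, n1))
        cur = n0
    return plan


def tqwt_analyze(series: UniformSeries, params: TqwtParams | None = None) -> TqwtCoefficients:
    """Decompose into J wavelet sub-bands plus a final low-pass sequence."""
    params = params or TqwtParams()
    x = series.values
    n = len(x)
    if n % 2:
        raise ValueError("TQWT requires an even-length series")
    plan = _stage_plan(n, params)
    X = np.fft.fft(x, norm="ortho")
    subbands: list[np.ndarray] = []
    for cur, n0, n1 in plan:
        V0, V1 = _afb(X, n0, n1)
        # unitary DFTs at every channel length make the frame tight (Parseval)
        subbands.append(np.fft.ifft(V1, norm="ortho").real)
        X = V0
    lowpass = np.fft.ifft(X, norm="ortho").real
    return TqwtCoefficients(
        subbands=subbands,
        lowpass=lowpass,
        params=params,
        n_samples=n,
        _stage_lengths=plan,
    )


def tqwt_synthesize(coeffs: TqwtCoefficients) -> UniformSeries:
    """Perfect-reconstruction inverse of :func:`tqwt_analyze`."""
    plan = coeffs._stage_lengths
    if len(plan) != coeffs.J:
        raise ValueError("coefficient stage plan inconsistent with band count")
    for (cur, n0, n1), band in zip(plan, coeffs.subbands):
        if len(band) != n1:
            raise ValueError(
                f"sub-band length {len(band)} does not match expected {n1}"
            )
    if len(coeffs.lowpass) != plan[-1][1]:
        raise ValueError("low-pass channel length mismatch")
    X = np.fft.fft(coeffs.lowpass, norm="ortho")
    for (cur, n0, n1), band in zip(reversed(plan), reversed(coeffs.subbands)):
        V1 = np.fft.fft(band, norm="ortho")
        X = _sfb(X, V1, cur)
    x = np.fft.ifft(X, norm="ortho").real
    return UniformSeries(x, fs=coeffs.params.fs)


def tqwt_center_frequencies(
    params: TqwtParams | None = None, empirical_n: int | None = None
) -> np.ndarray:
    """Nominal center frequency of each wavelet band, descending (Hz).

    f_c(j) = α^j · (2−β)/(4α) · fs.  With ``empirical_n`` set, instead
    measures each band's spectral peak by synthesizing a unit impulse placed
    in that band alone and locating the FFT argmax (an independent
    cross-check of the closed form).
    """
    params = params or TqwtParams()
    j = np.arange(1, params.J + 1)
    if empirical_n is None:
        a, b = params.alpha, params.beta
        return a**j * (2.0 - b) / (4.0 * a) * params.fs
    probe = UniformSeries(np.zeros(empirical_n), fs=params.fs)
    out = np.empty(params.J)
    for jj in j:
        c = tqwt_analyze(probe, params)
        band = c.subbands[jj - 1]
        band[len(band) // 2] = 1.0  # impulse in the middle of the band
        rec = tqwt_synthesize(c).values
        spec = np.abs(np.fft.rfft(rec))
        out[jj - 1] = np.argmax(spec) * params.fs / empirical_n
    return out


def subband_signal(coeffs: TqwtCoefficients, j: int) -> UniformSeries:
    """Full-length time-domain reconstruction of wavelet band j alone.

    All other bands and the low-pass channel are zeroed before synthesis, so
    every band shares the input's time base (needed for the spectrogram-based
    entropy feature).
    """
    if not 1 <= j <= coeffs.J:
        raise IndexError(f"band index {j} outside 1..{coeffs.J}")
    iso = TqwtCoefficients(
        subbands=[
            b.copy() if k == j - 1 else np.zeros_like(b)
            for k, b in enumerate(coeffs.subbands)
        ],
        lowpass=np.zeros_like(coeffs.lowpass),
        params=coeffs.params,
        n_samples=coeffs.n_samples,
        _stage_lengths=coeffs._stage_lengths,
    )
    return tqwt_synthesize(iso)


def subband_energy(
    coeffs: TqwtCoefficients, j: int, coeff_domain: bool = False
) -> float:
    """Energy of band j: sum of squares of its full-length reconstruction.

    ``coeff_domain=True`` sums the raw decimated coefficients instead.
    """
    if coeff_domain:
        return float(np.sum(coeffs.band(j) ** 2))
    return float(np.sum(subband_signal(coeffs, j).values ** 2))


def spectral_entropy_feature(
    coeffs: TqwtCoefficients,
    j: int,
    frame_len: int = 128,
    overlap: float = 0.5,
    coeff_domain: bool = False,
) -> float:
    """ENT: L2 norm over frames of the per-frame spectral Shannon entropy.

    A Hann-windowed one-sided spectrogram S(t,f) of the band-j signal is
    normalised per frame into a probability distribution
    P(t,m) = S(t,m)/Σ_f S(t,f); the frame entropy is
    H(t) = −Σ P log2 P (bits); the feature is sqrt(Σ_t H(t)²).  An all-zero
    band yields 0 by convention.
    """
    x = coeffs.band(j) if coeff_domain else subband_signal(coeffs, j).values
    if len(x) < 2 * frame_len:
        raise ValueError(
            f"band signal of {len(x)} samples too short for "
            f"{frame_len}-sample spectrogram frames"
        )
    if not np.any(x):
        return 0.0
    noverlap = int(round(frame_len * overlap))
    _, _, S = sps.stft(
        x,
        fs=coeffs.params.fs,
        window="hann",
        nperseg=frame_len,
        noverlap=noverlap,
        boundary=None,
        padded=False,
    )
    power = np.abs(S) ** 2
    col_sums = power.sum(axis=0)
    h = np.zeros(power.shape[1])
    nz = col_sums > 0
    P = power[:, nz] / col_sums[nz]
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    h[nz] = -(P * logP).sum(axis=0)
    return float(np.sqrt(np.sum(h**2)))
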