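"""Time-domain and nonlinear HRV features computed from the raw RR series.

Conventions fixed here and relied on by the tests:

* sample (n−1) variance everywhere a standard deviation is taken, so the
  Poincaré identity SD1² + SD2² = 2·Var(RR) holds exactly;
* skewness/kurtosis are of the RR intervals (not instantaneous rate) and
  kurtosis is the raw (non-excess) moment ratio;
* entropy parameters default to m = 2, r = 0.2·SDNN of the segment with a
  1 ms floor so constant series stay well defined;
* undefined values (no template matches, zero denominators) are returned as
  NaN sentinels, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signals import RRSeries

__all__ = [
    "TimeDomainFeatures",
    "time_domain",
    "poincare",
    "sample_entropy",
    "approximate_entropy",
    "multiscale_entropy",
    "ar_residual_power",
]

#: modal-bin width of the triangular index, in ms (classic 1/128 s convention)
TRI_BIN_MS = 1000.0 / 128.0


@dataclass
class TimeDomainFeatures:
    sdnn: float
    nn50: int
    pnn50: float
    skewness: float
    kurtosis: float
    rmssd: float
    rmssd_norm: float
    tri_index: float


def _intervals(rr: RRSeries | np.ndarray) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.intervals
    return np.asarray(rr, dtype=float)


def time_domain(rr: RRSeries, nn_threshold_ms: float = 50.0) -> TimeDomainFeatures:
    """Standard time-domain statistics of a 5-min tachogram.

    ``nn_threshold_ms`` generalises the NN50/pNN50 pair (20 ms gives the
    NN20/pNN20 variants used by the comparison feature sets).
    """
    x = _intervals(rr)
    n = len(x)
    if n < 10:
        raise ValueError("time-domain features need at least 10 intervals")
    diffs = np.diff(x)
    sdnn = float(np.std(x, ddof=1))
    nn = int(np.sum(np.abs(diffs) > nn_threshold_ms))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    if sdnn == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    # triangular index: N over the tallest histogram bin (1/128 s bins)
    edges = np.arange(x.min(), x.max() + 2 * TRI_BIN_MS, TRI_BIN_MS)
    counts, _ = np.histogram(x, bins=edges)
    tri = n / counts.max()
    return TimeDomainFeatures(
        sdnn=sdnn,
        nn50=nn,
        pnn50=nn / n,
        skewness=skew,
        kurtosis=kurt,
        rmssd=rmssd,
        rmssd_norm=rmssd / float(np.mean(x)),
        tri_index=float(tri),
    )


def poincare(rr: RRSeries) -> tuple[float, float, float]:
    """Poincaré-plot dispersions SD1 (short-term) and SD2 (long-term).

    SD1 = sqrt(½·Var(ΔRR)); SD2 = sqrt(2·Var(RR) − ½·Var(ΔRR)), both with
    sample variance.  Returns ``(SD1, SD2, SD1/SD2)``; the ratio is 0 (with
    SD2 = 0 marking the degenerate case) for a constant series and NaN when
    only SD2 vanishes.
    """
    x = _intervals(rr)
    if len(x) < 3:
        raise ValueError("Poincaré features need at least 3 intervals")
    var_rr = np.var(x, ddof=1)
    var_d = np.var(np.diff(x), ddof=1)
    sd1 = float(np.sqrt(0.5 * var_d))
    sd2 = float(np.sqrt(max(0.0, 2.0 * var_rr - 0.5 * var_d)))
    if sd2 == 0.0:
        ratio = 0.0 if sd1 == 0.0 else float("nan")
    else:
        ratio = sd1 / sd2
    return sd1, sd2, ratio


def _default_tolerance(x: np.ndarray, r_tol: float | None) -> float:
    if r_tol is None:
        r_tol = 0.2 * np.std(x, ddof=1)
    if r_tol < 0 or (r_tol == 0 and np.std(x) > 0):
        raise ValueError("tolerance must be positive")
    return max(float(r_tol), 1.0)  # 1 ms floor


def _template_counts(x: np.ndarray, m: int, r: float, exclude_self: bool) -> tuple[int, int]:
    """Chebyshev template-match counts at lengths m and m+1 (vectorized)."""
    n = len(x)
    nm = n - m  # number of (m+1)-length templates; m-templates restricted to same count
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:nm]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    dm = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=2) <= r
    dm1 = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=2) <= r
    if exclude_self:
        np.fill_diagonal(dm, False)
        np.fill_diagonal(dm1, False)
    return int(dm.sum()), int(dm1.sum())


def sample_entropy(
    rr: RRSeries | np.ndarray, m: int = 2, r_tol: float | None = None
) -> float:
    """Sample entropy: −ln(A/B) with self-matches excluded (Chebyshev metric).

    B counts template pairs matching at length m (templates restricted to the
    n−m windows that extend to length m+1), A those still matching at m+1.
    Returns NaN when either count is zero.
    """
    x = _intervals(rr)
    if len(x) < 50:
        raise ValueError("sample entropy needs at least 50 points")
    r = _default_tolerance(x, r_tol)
    b, a = _template_counts(x, m, r, exclude_self=True)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def approximate_entropy(
    rr: RRSeries | np.ndarray, m: int = 2, r_tol: float | None = None
) -> float:
    """Approximate entropy Φ_m − Φ_{m+1} with self-matches included (Pincus)."""
    x = _intervals(rr)
    if len(x) < 50:
        raise ValueError("approximate entropy needs at least 50 points")
    r = _default_tolerance(x, r_tol)

    def phi(mm: int) -> float:
        nm = len(x) - mm + 1
        tm = np.lib.stride_tricks.sliding_window_view(x, mm)
        match = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=2) <= r
        c = match.sum(axis=1) / nm
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def multiscale_entropy(
    rr: RRSeries | np.ndarray,
    m: int = 2,
    r_tol: float | None = None,
    scales: int = 5,
) -> np.ndarray:
    """Sample entropy of non-overlapping s-point means for s = 1..scales.

    The tolerance is fixed from the scale-1 series (the usual MSE
    convention) so values are comparable across scales; scales with fewer
    than 50 coarse-grained points are reported NaN.
    """
    x = _intervals(rr)
    if len(x) < 50:
        raise ValueError("multiscale entropy needs at least 50 points")
    r = _default_tolerance(x, r_tol)
    out = np.full(scales, np.nan)
    for s in range(1, scales + 1):
        n_coarse = len(x) // s
        if n_coarse < 50:
            continue
        coarse = x[: n_coarse * s].reshape(n_coarse, s).mean(axis=1)
        b, a = _template_counts(coarse, m, r, exclude_self=True)
        out[s - 1] = float("nan") if (a == 0 or b == 0) else -np.log(a / b)
    return out


def ar_residual_power(
    rr: RRSeries | np.ndarray, p: int = 12, method: str = "lstsq"
) -> float:
    """Residual noise power σ²_AR of an order-p autoregressive fit.

    The tachogram is modelled as RR(t) = Σ_k A(k)·RR(t−k) + n(t) on the
    mean-removed intervals; the variance of the residual n(t) estimates the
    unpredictable (ectopy-driven) power.  ``method`` selects conditional
    least squares (default) or Yule-Walker.
    """
    x = _intervals(rr)
    if len(x) < 5 * p:
        raise ValueError(f"AR({p}) fit needs at least {5 * p} intervals")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return 0.0
    if method == "lstsq":
        # design matrix of lagged values
        cols = [x[p - k - 1 : len(x) - k - 1] for k in range(p)]
        X = np.column_stack(cols)
        y = x[p:]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(np.var(resid, ddof=0))
    if method == "yule-walker":
        acov = np.correlate(x, x, mode="full")[len(x) - 1 :] / len(x)
        R = np.array([[acov[abs(i - j)] for j in range(p)] for i in range(p)])
        r_vec = acov[1 : p + 1]
        coef = np.linalg.solve(R, r_vec)
        return float(acov[0] - coef @ r_vec)
    raise ValueError(f"unknown AR fit method {method!r}")
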