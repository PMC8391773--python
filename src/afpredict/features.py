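"""End-to-end feature extraction for one 5-minute RR segment.

Ties the preprocessing paths to the five feature families and assembles the
named vectors the classifiers consume.  The selected 14-feature subset is
normalised RMSSD, SD1, the AR residual noise power, the VFCDM envelope
variance, LF/HF, LFn, TQWT spectral entropy of bands 8/11/12/13 and TQWT
energy of bands 9/10/11/12 — the combination in which premature-atrial-beat
variability is most visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import frequency, time_nonlinear, tqwt, vfcdm
from .preprocess import PreprocessedSegment, preprocess_rr
from .signals import RRSeries, UniformSeries

__all__ = [
    "FeatureVector",
    "SELECTED14",
    "NARIN1",
    "NARIN2",
    "FEATURE_SUBSETS",
    "extract_features",
    "assemble_features",
]

SELECTED14 = (
    "rmssd_norm",
    "sd1",
    "ar_resid",
    "vfcdm_var",
    "lf_hf",
    "lfn",
    "tqwt_ent_08",
    "tqwt_ent_11",
    "tqwt_ent_12",
    "tqwt_ent_13",
    "tqwt_energy_09",
    "tqwt_energy_10",
    "tqwt_energy_11",
    "tqwt_energy_12",
)

#: comparison baselines: NN50/pNN50 analogues at a 20 ms threshold
NARIN1 = ("rmssd", "nn20", "pnn20", "vlf", "hf")
NARIN2 = ("rmssd", "vlf", "lf", "tp")

FEATURE_SUBSETS: dict[str, tuple[str, ...] | None] = {
    "selected14": SELECTED14,
    "narin1": NARIN1,
    "narin2": NARIN2,
    "extended": None,  # every extracted feature, in extraction order
}

#: TQWT bands whose energy / spectral entropy enter the extended set
_TQWT_BANDS = range(1, 18)


@dataclass
class FeatureVector:
    """Named features for one segment, with an optional class label."""

    segment_id: str
    values: dict[str, float]
    label: str | None = None

    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.names = tuple(self.values)

    def as_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = names or self.names
        return np.array([self.values[n] for n in names], dtype=float)


def extract_features(
    rr: RRSeries,
    tau: float = 4.0,
    detrend_cutoff: float = 0.01,
    ectopic_mode: str = "interpolate",
    lf_includes_vlf: bool = False,
    tqwt_params: tqwt.TqwtParams | None = None,
    vfcdm_single_stage: bool = False,
) -> dict[str, float]:
    """Compute every feature of the extended set from a raw RR series.

    Undefined values propagate as NaN; callers selecting a subset through
    :func:`assemble_features` get an explicit error for NaNs instead.
    """
    pre = preprocess_rr(
        rr, tau=tau, detrend_cutoff=detrend_cutoff, ectopic_mode=ectopic_mode
    )
    return extract_features_from_preprocessed(
        pre,
        lf_includes_vlf=lf_includes_vlf,
        tqwt_params=tqwt_params,
        vfcdm_single_stage=vfcdm_single_stage,
    )


def extract_features_from_preprocessed(
    pre: PreprocessedSegment,
    lf_includes_vlf: bool = False,
    tqwt_params: tqwt.TqwtParams | None = None,
    vfcdm_single_stage: bool = False,
) -> dict[str, float]:
    rr = pre.rr_raw
    out: dict[str, float] = {}

    # --- time domain (raw RR) ---
    td = time_nonlinear.time_domain(rr)
    out.update(
        sdnn=td.sdnn,
        nn50=float(td.nn50),
        pnn50=td.pnn50,
        skewness=td.skewness,
        kurtosis=td.kurtosis,
        rmssd=td.rmssd,
        rmssd_norm=td.rmssd_norm,
        tri_index=td.tri_index,
    )
    td20 = time_nonlinear.time_domain(rr, nn_threshold_ms=20.0)
    out.update(nn20=float(td20.nn50), pnn20=td20.pnn50)

    # --- nonlinear (raw RR) ---
    sd1, sd2, ratio = time_nonlinear.poincare(rr)
    out.update(sd1=sd1, sd2=sd2, sd_ratio=ratio)
    out["sampen"] = time_nonlinear.sample_entropy(rr)
    out["apen"] = time_nonlinear.approximate_entropy(rr)
    mse = time_nonlinear.multiscale_entropy(rr)
    out.update({f"mse_s{s}": float(v) for s, v in enumerate(mse, start=1)})
    out["ar_resid"] = time_nonlinear.ar_residual_power(rr)

    # --- frequency domain (corrected, resampled, detrended) ---
    psd = frequency.welch_psd(pre.freq_series)
    edges = frequency.BAND_EDGES_LF_INCLUDES_VLF if lf_includes_vlf else None
    bp = frequency.band_powers(psd, edges)
    out.update(
        vlf=bp.vlf, lf=bp.lf, hf=bp.hf, tp=bp.tp,
        lf_hf=bp.lf_hf, lfn=bp.lfn, hfn=bp.hfn,
    )

    # --- VFCDM (uncorrected, resampled, detrended) ---
    decomp = vfcdm.vfcdm_decompose(pre.tf_series, single_stage=vfcdm_single_stage)
    env = vfcdm.hilbert_envelope(vfcdm.reconstruct_hf(decomp))
    v_mean, v_var, v_energy = vfcdm.vfcdm_features(env)
    out.update(vfcdm_mean=v_mean, vfcdm_var=v_var, vfcdm_energy=v_energy)

    # --- TQWT (uncorrected, resampled, detrended; even length required) ---
    tf = pre.tf_series
    if len(tf) % 2:
        tf = UniformSeries(tf.values[:-1], fs=tf.fs, start_time=tf.start_time)
    coeffs = tqwt.tqwt_analyze(tf, tqwt_params)
    for j in _TQWT_BANDS:
        out[f"tqwt_energy_{j:02d}"] = tqwt.subband_energy(coeffs, j)
        out[f"tqwt_ent_{j:02d}"] = tqwt.spectral_entropy_feature(coeffs, j)

    return out


def assemble_features(
    features: dict[str, float] | RRSeries,
    subset: str = "selected14",
    segment_id: str = "",
    label: str | None = None,
    **extract_kwargs,
) -> FeatureVector:
    """Select a named subset, rejecting undefined (NaN) values.

    ``features`` may be a raw :class:`RRSeries` (extracted here) or an
    already-extracted feature dict.
    """
    if isinstance(features, RRSeries):
        features = extract_features(features, **extract_kwargs)
    if subset not in FEATURE_SUBSETS:
        raise ValueError(
            f"unknown subset {subset!r}; choose from {sorted(FEATURE_SUBSETS)}"
        )
    names = FEATURE_SUBSETS[subset] or tuple(features)
    missing = [n for n in names if n not in features]
    if missing:
        raise ValueError(f"features not extracted: {missing}")
    bad = [n for n in names if not np.isfinite(features[n])]
    if bad:
        raise ValueError(
            f"undefined feature values for segment {segment_id!r}: {bad}"
        )
    return FeatureVector(
        segment_id=segment_id,
        values={n: float(features[n]) for n in names},
        label=label,
    )
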