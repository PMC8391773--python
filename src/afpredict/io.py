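"""File formats: PhysioNet WFDB waveforms, RR CSVs, feature tables, model bundles.

The WFDB support is a deliberately small reader/writer covering the two
dialects the pipeline meets in practice — single-segment records in signal
formats 212 (12-bit packed pairs) and 16 (little-endian 16-bit) with a plain
``.hea`` header — returning samples converted to millivolts via the header's
gain/baseline.  Multi-segment layouts are out of scope; callers concatenate.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .classify import TrainedModel
from .features import FeatureVector
from .signals import EcgRecord, RRSeries

__all__ = [
    "read_wfdb",
    "write_wfdb",
    "read_rr_csv",
    "write_rr_csv",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

_BUNDLE_VERSION = 1


# --------------------------------------------------------------------------
# WFDB
# --------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    record_name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else None
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname = parts[0]
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if g else 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        name = parts[8] if len(parts) > 8 else f"sig{len(signals)}"
        signals.append(
            dict(fname=fname, fmt=fmt, gain=gain, baseline=baseline,
                 units=units, name=name)
        )
    return record_name, n_sig, fs, n_samples, signals


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack 12-bit two's-complement sample pairs from 3-byte groups."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_groups = len(b) // 3
    b = b[: n_groups * 3].reshape(n_groups, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_groups, dtype=np.int32)
    out[0::2], out[1::2] = first, second
    out[out > 2047] -= 4096
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if np.any((v < -2048) | (v > 2047)):
        raise ValueError("format 212 requires samples in [-2048, 2047]")
    if len(v) % 2:
        v = np.append(v, 0)
    v = np.where(v < 0, v + 4096, v).reshape(-1, 2)
    out = np.empty((len(v), 3), dtype=np.uint8)
    out[:, 0] = v[:, 0] & 0xFF
    out[:, 1] = ((v[:, 0] >> 8) & 0x0F) | (((v[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = v[:, 1] & 0xFF
    return out.tobytes()


def read_wfdb(path: str | Path, channel: int | None = None) -> EcgRecord:
    """Read a single-segment WFDB record (.hea + signal file), formats 212/16.

    ``path`` is the record path with or without the ``.hea`` extension;
    ``channel`` selects one channel (default: all channels kept).
    """
    hea_path = Path(path).with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    record_name, n_sig, fs, n_samples, signals = _parse_header(hea_path)
    fmts = {s["fmt"] for s in signals}
    if not fmts <= {212, 16}:
        raise ValueError(
            f"unsupported WFDB format {sorted(fmts - {212, 16})}; "
            "only formats 212 and 16 are supported"
        )
    if len({s["fname"] for s in signals}) != 1:
        raise ValueError("multi-file signal groups are not supported")
    dat_path = hea_path.parent / signals[0]["fname"]
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = dat_path.read_bytes()
    fmt = signals[0]["fmt"]
    if n_samples is None:
        n_values = (len(raw) // 2 if fmt == 16 else (len(raw) * 2) // 3)
        n_samples = n_values // n_sig
    n_values = n_samples * n_sig
    if fmt == 16:
        need = 2 * n_values
        if len(raw) < need:
            raise IOError(
                f"truncated WFDB signal file: {len(raw)} bytes, need {need}"
            )
        digital = np.frombuffer(raw[:need], dtype="<i2").astype(np.int32)
    else:
        need = (n_values * 3 + 1) // 2
        if len(raw) < need:
            raise IOError(
                f"truncated WFDB signal file: {len(raw)} bytes, need {need}"
            )
        digital = _decode_212(raw, n_values)
    frames = digital.reshape(n_samples, n_sig)
    phys = np.empty((n_sig, n_samples))
    for i, s in enumerate(signals):
        phys[i] = (frames[:, i] - s["baseline"]) / s["gain"]
    names = [s["name"] for s in signals]
    if channel is not None:
        if not 0 <= channel < n_sig:
            raise IndexError(f"channel {channel} outside 0..{n_sig - 1}")
        phys, names = phys[channel : channel + 1], [names[channel]]
    return EcgRecord(phys, fs, names, record_name)


def write_wfdb(
    record: EcgRecord,
    path: str | Path,
    fmt: int = 16,
    gain: float = 200.0,
    baseline: int = 0,
) -> None:
    """Write a single-segment WFDB record (fixture/export helper)."""
    if fmt not in (212, 16):
        raise ValueError("only formats 212 and 16 are supported")
    path = Path(path)
    name = path.stem
    digital = np.rint(record.samples * gain + baseline).astype(np.int32)
    if fmt == 16 and np.any((digital < -32768) | (digital > 32767)):
        raise ValueError("samples overflow 16-bit range at this gain")
    frames = digital.T.reshape(-1)  # sample-major interleaving
    dat_name = f"{name}.dat"
    lines = [f"{name} {record.n_channels} {record.fs:g} {record.n_samples}"]
    for i, ch in enumerate(record.channel_names):
        lines.append(
            f"{dat_name} {fmt} {gain:g}({baseline})/mV 12 {baseline} 0 0 0 {ch}"
        )
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    if fmt == 16:
        payload = frames.astype("<i2").tobytes()
    else:
        payload = _encode_212(frames)
    (path.parent / dat_name).write_bytes(payload)


# --------------------------------------------------------------------------
# RR CSV
# --------------------------------------------------------------------------

def read_rr_csv(path: str | Path) -> RRSeries:
    """Read a beat-per-row CSV with columns ``beat_time_s, rr_ms``.

    The first row anchors the series; its ``rr_ms`` value (the interval
    before the first recorded beat) is ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty input: {path}") from None
    if df.empty:
        raise ValueError(f"empty input: {path}")
    for col in ("beat_time_s", "rr_ms"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    times = df["beat_time_s"].to_numpy(dtype=float)
    bad = np.where(np.diff(times) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"beat times not strictly increasing at row {bad[0] + 2} "
            f"(time {times[bad[0] + 1]:g} s follows {times[bad[0]]:g} s)"
        )
    if len(times) < 2:
        raise ValueError("need at least two beats")
    return RRSeries(times, df["rr_ms"].to_numpy(dtype=float)[1:])


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    """Inverse of :func:`read_rr_csv`; the first row repeats the first interval."""
    rr_col = np.concatenate([[rr.intervals[0]], rr.intervals])
    pd.DataFrame({"beat_time_s": rr.beat_times, "rr_ms": rr_col}).to_csv(
        path, index=False, float_format="%.12g"
    )


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------

def write_feature_table(vectors: list[FeatureVector], path: str | Path) -> None:
    """One CSV row per segment: segment_id, features (extraction order), label.

    All vectors must share an identical feature-name tuple; values survive a
    round trip to 12 significant digits.
    """
    if vectors:
        names = vectors[0].names
        for v in vectors[1:]:
            if v.names != names:
                raise ValueError(
                    f"heterogeneous feature names: segment {v.segment_id!r} "
                    f"differs from {vectors[0].segment_id!r}"
                )
        rows = [
            {"segment_id": v.segment_id, **v.values, "label": v.label or ""}
            for v in vectors
        ]
        df = pd.DataFrame(rows, columns=["segment_id", *names, "label"])
    else:
        df = pd.DataFrame(columns=["segment_id", "label"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(Path(path), keep_default_na=False)
    names = [c for c in df.columns if c not in ("segment_id", "label")]
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                segment_id=str(row["segment_id"]),
                values={n: float(row[n]) for n in names},
                label=str(row["label"]) or None,
            )
        )
    return out


# --------------------------------------------------------------------------
# Model bundles
# --------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model with its scaler and feature schema."""
    joblib.dump(
        {
            "bundle_version": _BUNDLE_VERSION,
            "kind": model.kind,
            "hyperparams": model.hyperparams,
            "feature_names": tuple(model.feature_names),
            "scaler_mean": model.scaler_mean,
            "scaler_sd": model.scaler_sd,
            "estimator": model.estimator,
            "seed": model.seed,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model bundle not found: {path}")
    bundle = joblib.load(path)
    if bundle.get("bundle_version") != _BUNDLE_VERSION:
        raise ValueError(
            f"model bundle version mismatch: {bundle.get('bundle_version')} "
            f"!= {_BUNDLE_VERSION}"
        )
    names = tuple(bundle["feature_names"])
    if len(names) != len(bundle["scaler_mean"]) or len(names) != len(
        bundle["scaler_sd"]
    ):
        raise ValueError("feature schema mismatch in model bundle")
    est = bundle["estimator"]
    n_in = getattr(est, "n_features_in_", len(names))
    if n_in != len(names):
        raise ValueError("feature schema mismatch in model bundle")
    return TrainedModel(
        kind=bundle["kind"],
        hyperparams=bundle["hyperparams"],
        feature_names=names,
        scaler_mean=np.asarray(bundle["scaler_mean"]),
        scaler_sd=np.asarray(bundle["scaler_sd"]),
        estimator=est,
        seed=bundle["seed"],
    )
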