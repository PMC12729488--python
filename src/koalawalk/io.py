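"""Reading, writing, resampling and time-synchronising collar streams.

Streams travel as delimited text (timestamp + three or six numeric channels
+ optional label column) with a JSON metadata sidecar. Units may be m/s^2 or
g; g is converted on read when declared. Timestamp gaps are recorded as
metadata, never silently interpolated — daily budgets are rescaled for
coverage downstream instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .stream import GRAVITY, LabelledStream

ACC_COLUMNS = ["ax", "ay", "az"]
GYRO_COLUMNS = ["gx", "gy", "gz"]
VALID_RATES = (25.0, 50.0, 100.0)


@dataclass
class StreamMeta:
    """Sidecar metadata for one stream file."""

    sample_rate: float
    units: str = "ms2"  # "ms2" | "g"
    axes: tuple[str, ...] = tuple(ACC_COLUMNS)
    start_time: str = "2023-05-15T00:00:00"
    individual_id: str = "unknown"
    sex: str = "U"
    habitat: str = "patch"
    mass_kg: float = float("nan")

    def __post_init__(self) -> None:
        if float(self.sample_rate) not in VALID_RATES:
            raise ValueError(f"sample_rate must be one of {VALID_RATES}")
        if self.units not in ("ms2", "g"):
            raise ValueError("units must be 'ms2' or 'g'")
        if len(self.axes) not in (3, 6):
            raise ValueError("axis count must be 3 or 6")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stream(stream: LabelledStream, path, units: str = "ms2") -> Path:
    """Write a stream as CSV (epoch-second timestamps, fixed 6-dp precision)
    with a JSON metadata sidecar. Returns the CSV path."""
    path = Path(path)
    scale = 1.0 if units == "ms2" else 1.0 / GRAVITY
    cols = {"t": np.round(stream.t, 6)}
    for i, name in enumerate(ACC_COLUMNS):
        cols[name] = stream.acc[:, i] * scale
    if stream.gyro is not None:
        for i, name in enumerate(GYRO_COLUMNS):
            cols[name] = stream.gyro[:, i]
    frame = pd.DataFrame(cols)
    frame["label"] = stream.labels
    frame.to_csv(path, index=False, float_format="%.6f")
    axes = tuple(ACC_COLUMNS + (GYRO_COLUMNS if stream.gyro is not None else []))
    meta = StreamMeta(
        sample_rate=stream.sample_rate, units=units, axes=axes,
        start_time=str(stream.start_time), individual_id=stream.individual_id,
        sex=stream.sex, habitat=stream.habitat, mass_kg=stream.mass_kg,
    )
    _sidecar_path(path).write_text(json.dumps(asdict(meta), indent=1))
    return path


def read_stream(path, meta_overrides: dict | None = None,
                max_missing_fraction: float = 0.05) -> LabelledStream:
    """Read a delimited-text stream and its sidecar into a LabelledStream.

    Enforces monotone timestamps, converts g to m/s^2 when declared, and
    flags any timestamp gap larger than 1.5 sample intervals in
    ``stream.gaps`` without altering the sample count. Rejects files whose
    implied missing-sample fraction exceeds ``max_missing_fraction``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_kwargs: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta_kwargs.update(json.loads(sidecar.read_text()))
    if meta_overrides:
        meta_kwargs.update(meta_overrides)
    if "axes" in meta_kwargs:
        meta_kwargs["axes"] = tuple(meta_kwargs["axes"])
    meta = StreamMeta(**meta_kwargs)

    frame = pd.read_csv(path)
    missing_cols = [c for c in ("t", *ACC_COLUMNS) if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"stream file lacks required columns: {missing_cols}")

    t = frame["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-monotone timestamps")
    step = 1.0 / meta.sample_rate
    gap_idx = np.flatnonzero(dt > 1.5 * step)
    gaps = [(float(t[i]), float(t[i + 1])) for i in gap_idx]
    missing = sum((b - a) / step - 1.0 for a, b in gaps)
    if missing > max_missing_fraction * (len(t) + missing):
        raise ValueError(
            f"{missing:.0f} missing samples (> {max_missing_fraction:.0%} "
            f"of the record); {len(gaps)} gaps at {gaps[:5]}"
        )

    scale = GRAVITY if meta.units == "g" else 1.0
    acc = frame[ACC_COLUMNS].to_numpy(dtype=float) * scale
    gyro = None
    if all(c in frame.columns for c in GYRO_COLUMNS):
        gyro = frame[GYRO_COLUMNS].to_numpy(dtype=float)

    labels = (
        frame["label"].fillna("").astype(str).to_numpy()
        if "label" in frame.columns
        else np.full(len(frame), "", dtype=object)
    )
    return LabelledStream.from_labels(
        sample_rate=meta.sample_rate, acc=acc, labels=labels, gyro=gyro,
        start_time=np.datetime64(meta.start_time),
        individual_id=meta.individual_id, sex=meta.sex,
        habitat=meta.habitat, mass_kg=meta.mass_kg, gaps=gaps,
    )


def downsample(stream: LabelledStream, target_rate: float) -> LabelledStream:
    """Decimate to ``target_rate`` with a boxcar (within-group mean)
    anti-alias filter; group labels are taken from the group's first sample.
    """
    if target_rate > stream.sample_rate:
        raise ValueError("target rate exceeds source rate")
    factor = stream.sample_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target rate must divide the source rate")
    factor = int(round(factor))
    if factor == 1:
        return stream.copy()
    n = (len(stream) // factor) * factor

    def _decimate(x: np.ndarray) -> np.ndarray:
        return x[:n].reshape(-1, factor, x.shape[1]).mean(axis=1)

    out = stream.copy()
    out.sample_rate = target_rate
    out.acc = _decimate(stream.acc)
    out.gyro = None if stream.gyro is None else _decimate(stream.gyro)
    out.label_codes = stream.label_codes[:n:factor].copy()
    return out


def detect_taps(stream: LabelledStream, min_spikes: int = 5,
                max_span_s: float = 3.0,
                amp_threshold_g: float = 3.0) -> list[float]:
    """Detect collar-tap calibration events for video/collar clock alignment.

    Finds groups of at least ``min_spikes`` super-threshold acceleration
    peaks (vector magnitude above ``amp_threshold_g``) spanning at most
    ``max_span_s`` and returns each group's centre time in stream seconds.
    """
    if stream.duration_s < max_span_s:
        raise ValueError("stream shorter than max_span_s")
    mag = np.linalg.norm(stream.acc, axis=1)
    thr = amp_threshold_g * GRAVITY
    peaks, _ = find_peaks(mag, height=thr * 0.999,
                          distance=max(1, int(0.05 * stream.sample_rate)))
    if len(peaks) == 0:
        return []
    times = peaks / stream.sample_rate
    events: list[float] = []
    group = [times[0]]
    for tm in times[1:]:
        if tm - group[0] <= max_span_s and tm - group[-1] <= 1.0:
            group.append(tm)
        else:
            if len(group) >= min_spikes:
                events.append(float(np.mean(group)))
            group = [tm]
    if len(group) >= min_spikes:
        events.append(float(np.mean(group)))
    return events


def write_config_json(config, path) -> Path:
    """Serialise a SimConfig (or any dataclass) to JSON next to its streams."""
    path = Path(path)

    def _default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, np.generic):
            return o.item()
        raise TypeError(type(o))

    path.write_text(json.dumps(asdict(config), default=_default, indent=1))
    return path


def warn_on_gaps(stream: LabelledStream) -> None:
    if stream.gaps:
        warnings.warn(f"stream has {len(stream.gaps)} recording gaps")
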