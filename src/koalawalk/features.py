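"""Windowed feature extraction and dynamic-body-acceleration summaries.

Streams are segmented into 1 s windows with 50% overlap. Each window yields
a fixed, named feature vector (per-axis statistics, spectral descriptors,
cross-axis correlations and dynamic-body-acceleration summaries). The
static/dynamic decomposition uses a centred 2 s rolling mean per axis —
VeDBA is the Euclidean norm of the dynamic residual across the three
accelerometer axes, ODBA its 1-norm counterpart.

All window-level computations are batched with numpy stride tricks, so
multi-day 50 Hz deployments extract in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .stream import LabelledStream

#: windows whose majority label covers less than this fraction are dropped
#: from training (mixed-behaviour transitions)
PURITY_THRESHOLD = 0.7

PER_AXIS_STATS = (
    "mean", "sd", "min", "max", "range", "skew", "kurtosis", "rms",
    "zero_cross", "dom_freq", "spec_entropy", "lag1_acf",
)
WINDOW_STATS = ("odba_mean", "vedba_mean", "vedba_max", "trend_slope")


@dataclass
class FeatureWindow:
    """One 1 s segment: timing, label context and (optionally) features."""

    start_s: float
    label: str
    purity: float
    individual_id: str
    features: pd.Series | None = None


# ---------------------------------------------------------------------------
# static/dynamic decomposition and VeDBA

def rolling_mean_shrunk(x: np.ndarray, width: int) -> np.ndarray:
    """Centred rolling mean along axis 0 with shrunken edge windows."""
    n = len(x)
    half = width // 2
    csum = np.cumsum(np.vstack([np.zeros((1,) + x.shape[1:]), x]), axis=0)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half, 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo).reshape(-1, *([1] * (x.ndim - 1)))
    return out


def static_dynamic_split(
    stream: LabelledStream, smooth_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split acceleration into static (gravity/posture) and dynamic parts.

    static = centred rolling mean of ``smooth_s`` per axis; dynamic = raw -
    static, so the decomposition identity holds at every sample.
    """
    if stream.duration_s <= smooth_s:
        raise ValueError("stream must be longer than the smoothing window")
    width = max(1, int(round(smooth_s * stream.sample_rate)))
    static = rolling_mean_shrunk(stream.acc, width)
    return static, stream.acc - static


def vedba(dynamic: np.ndarray) -> np.ndarray | float:
    """Vectorial Dynamic Body Acceleration: Euclidean norm of the dynamic
    3-axis residual. Accepts one sample (3,) or many (n, 3)."""
    dynamic = np.asarray(dynamic, dtype=float)
    if not np.all(np.isfinite(dynamic)):
        raise ValueError("non-finite dynamic acceleration")
    out = np.linalg.norm(dynamic, axis=-1)
    return float(out) if out.ndim == 0 else out


def odba(dynamic: np.ndarray) -> np.ndarray | float:
    """Overall Dynamic Body Acceleration: 1-norm across the three axes."""
    dynamic = np.asarray(dynamic, dtype=float)
    out = np.abs(dynamic).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def vedba_seconds(stream: LabelledStream, smooth_s: float = 2.0) -> pd.DataFrame:
    """Per-second VeDBA summaries: max and min of the per-sample norm over
    the samples of each whole clock second."""
    _, dyn = static_dynamic_split(stream, smooth_s)
    v = vedba(dyn)
    per = int(round(stream.sample_rate))
    n_sec = len(v) // per
    vv = v[: n_sec * per].reshape(n_sec, per)
    return pd.DataFrame(
        {
            "second": np.arange(n_sec),
            "vedba_max": vv.max(axis=1),
            "vedba_min": vv.min(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# segmentation

def _window_starts(n_samples: int, rate: float, window_s: float,
                   overlap: float) -> np.ndarray:
    step = int(round(window_s * (1.0 - overlap) * rate))
    width = int(round(window_s * rate))
    if step <= 0:
        raise ValueError("overlap too large: zero step")
    if n_samples < width:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - width + 1, step)


def segment(stream: LabelledStream, window_s: float = 1.0,
            overlap: float = 0.5) -> list[FeatureWindow]:
    """Cut a stream into overlapping window shells.

    Each shell carries the majority per-sample label of its span and the
    purity (majority fraction); downstream training drops shells below the
    70% purity threshold. Streams shorter than one window yield an empty
    list with a warning.
    """
    width = int(round(window_s * stream.sample_rate))
    starts = _window_starts(len(stream), stream.sample_rate, window_s, overlap)
    if len(starts) == 0:
        warnings.warn("stream shorter than one window; no segments")
        return []
    codes = sliding_window_view(stream.label_codes, width)[starts]
    maj, purity = _majority_codes(codes, len(stream.classes))
    lut = np.array(("",) + stream.classes, dtype=object)
    return [
        FeatureWindow(
            start_s=float(s / stream.sample_rate),
            label=str(lut[m + 1]),
            purity=float(p),
            individual_id=stream.individual_id,
        )
        for s, m, p in zip(starts, maj, purity)
    ]


def _majority_codes(codes: np.ndarray, n_classes: int):
    """Majority code and purity per row; missing (-1) never wins unless the
    row is entirely missing."""
    counts = np.stack(
        [(codes == c).sum(axis=1) for c in range(n_classes)], axis=1
    )
    maj = counts.argmax(axis=1).astype(np.int16)
    top = counts.max(axis=1)
    purity = top / codes.shape[1]
    maj[top == 0] = -1
    return maj, purity


# ---------------------------------------------------------------------------
# feature computation (batched)

def _axis_features(w: np.ndarray, rate: float) -> dict[str, np.ndarray]:
    """Features for one axis over all windows; w has shape (n, L)."""
    n, L = w.shape
    mean = w.mean(axis=1)
    centred = w - mean[:, None]
    var = (centred**2).mean(axis=1)
    sd = np.sqrt(var)
    ok = sd > 1e-12
    safe_sd = np.where(ok, sd, 1.0)

    m3 = (centred**3).mean(axis=1)
    m4 = (centred**4).mean(axis=1)
    skew = np.where(ok, m3 / safe_sd**3, 0.0)
    kurt = np.where(ok, m4 / safe_sd**4 - 3.0, 0.0)

    mn, mx = w.min(axis=1), w.max(axis=1)
    rms = np.sqrt((w**2).mean(axis=1))

    sgn = centred >= 0
    zc = (sgn[:, 1:] != sgn[:, :-1]).sum(axis=1).astype(float)

    spec = np.abs(np.fft.rfft(centred, axis=1)) ** 2
    spec = spec[:, 1:]  # drop DC
    freqs = np.fft.rfftfreq(L, d=1.0 / rate)[1:]
    power = spec.sum(axis=1)
    dom = np.where(power > 1e-20, freqs[spec.argmax(axis=1)], 0.0)
    p = spec / np.where(power > 1e-20, power, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    ent = np.where(power > 1e-20, ent / np.log(spec.shape[1]), 0.0)

    acf_num = (centred[:, :-1] * centred[:, 1:]).sum(axis=1)
    acf_den = (centred**2).sum(axis=1)
    lag1 = np.where(acf_den > 1e-20, acf_num / np.where(acf_den > 0, acf_den, 1.0), 0.0)

    return {
        "mean": mean, "sd": sd, "min": mn, "max": mx, "range": mx - mn,
        "skew": skew, "kurtosis": kurt, "rms": rms, "zero_cross": zc,
        "dom_freq": dom, "spec_entropy": ent, "lag1_acf": lag1,
    }


def _batch_features(raw: np.ndarray, dyn: np.ndarray, rate: float,
                    axis_names: tuple[str, ...]) -> pd.DataFrame:
    """raw: (n, L, A) windowed channels; dyn: (n, L, 3) windowed dynamic
    acceleration. Returns one row of named features per window."""
    n, L, A = raw.shape
    cols: dict[str, np.ndarray] = {}
    per_axis = []
    for a in range(A):
        feats = _axis_features(raw[:, :, a], rate)
        per_axis.append(feats)
        for stat in PER_AXIS_STATS:
            cols[f"{axis_names[a]}_{stat}"] = feats[stat]

    # pairwise correlations (0 by convention when either axis is constant)
    for a in range(A):
        for b in range(a + 1, A):
            ca = raw[:, :, a] - per_axis[a]["mean"][:, None]
            cb = raw[:, :, b] - per_axis[b]["mean"][:, None]
            denom = per_axis[a]["sd"] * per_axis[b]["sd"] * L
            ok = denom > 1e-20
            corr = np.where(ok, (ca * cb).sum(axis=1) / np.where(ok, denom, 1.0), 0.0)
            cols[f"corr_{axis_names[a]}_{axis_names[b]}"] = corr

    v = np.linalg.norm(dyn, axis=2)  # (n, L)
    cols["odba_mean"] = np.abs(dyn).sum(axis=2).mean(axis=1)
    cols["vedba_mean"] = v.mean(axis=1)
    cols["vedba_max"] = v.max(axis=1)
    tt = np.arange(L) / rate
    tc = tt - tt.mean()
    cols["trend_slope"] = (v * tc).sum(axis=1) / (tc**2).sum()

    frame = pd.DataFrame(cols)
    if not np.isfinite(frame.to_numpy()).all():
        raise FloatingPointError("non-finite feature values after extraction")
    return frame


def extract_features(samples: np.ndarray, rate: float = 50.0,
                     dynamic: np.ndarray | None = None,
                     axis_names: tuple[str, ...] | None = None,
                     window_s: float = 1.0) -> pd.Series:
    """Feature vector for a single window of shape (L, A).

    ``dynamic`` (L, 3) defaults to the window-local mean-removed
    accelerometer channels. Windows that are not exactly ``window_s`` of
    samples at ``rate``, or have an unexpected axis count, are rejected.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] not in (3, 6):
        raise ValueError("samples must be (L, 3) or (L, 6)")
    if samples.shape[0] != int(round(rate * window_s)):
        raise ValueError(
            f"expected {int(round(rate * window_s))} samples, "
            f"got {samples.shape[0]}")
    if axis_names is None:
        axis_names = ("ax", "ay", "az", "gx", "gy", "gz")[: samples.shape[1]]
    if dynamic is None:
        acc = samples[:, :3]
        dynamic = acc - acc.mean(axis=0)
    table = _batch_features(samples[None], np.asarray(dynamic, float)[None],
                            rate, tuple(axis_names))
    return table.iloc[0]


def extract_feature_table(
    stream: LabelledStream, window_s: float = 1.0, overlap: float = 0.5,
    smooth_s: float = 2.0,
) -> pd.DataFrame:
    """Segment a stream and extract features for every window.

    Returns a DataFrame with ``start_s``, ``label``, ``purity`` and
    ``individual_id`` columns followed by the feature columns, in a stable
    order identical across runs.
    """
    width = int(round(window_s * stream.sample_rate))
    starts = _window_starts(len(stream), stream.sample_rate, window_s, overlap)
    if len(starts) == 0:
        warnings.warn("stream shorter than one window; no segments")
        return pd.DataFrame()
    _, dyn = static_dynamic_split(stream, smooth_s)
    mat = stream.axes_matrix()
    axis_names = ("ax", "ay", "az", "gx", "gy", "gz")[: mat.shape[1]]
    raw_w = sliding_window_view(mat, width, axis=0)[starts]  # (n, A, L)
    dyn_w = sliding_window_view(dyn, width, axis=0)[starts]
    feats = _batch_features(
        np.swapaxes(raw_w, 1, 2), np.swapaxes(dyn_w, 1, 2), stream.sample_rate,
        tuple(axis_names),
    )
    codes = sliding_window_view(stream.label_codes, width)[starts]
    maj, purity = _majority_codes(codes, len(stream.classes))
    lut = np.array(("",) + stream.classes, dtype=object)
    head = pd.DataFrame(
        {
            "start_s": starts / stream.sample_rate,
            "label": lut[maj + 1],
            "purity": purity,
            "individual_id": stream.individual_id,
        }
    )
    return pd.concat([head, feats], axis=1)
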