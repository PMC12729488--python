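"""Rule-based post-processing of per-second behaviour labels.

The chain converts raw per-second predictions into analysis-ready 20 s bins:

1. centred 5 s modal filter (ties keep the original centre label),
2. collapse of 'blips' — runs shorter than 3 s — into the surrounding
   state, with missing seconds filled by last/next observation carried
   forward/backward,
3. regrouping of the seven model classes into the four final categories
   (plus ``Other``),
4. non-overlapping 20 s majority bins with per-bin VeDBA summaries,
5. exclusion of the residual ``Other`` bins from modelling inputs.

All steps are deterministic and operate on plain per-second label arrays.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .labels import OTHER, REGROUP_MAP

BIN_S = 20


def _encode(labels) -> tuple[np.ndarray, np.ndarray]:
    """Factorise labels to int codes; '' / NaN become missing (-1)."""
    arr = pd.Series(np.asarray(labels, dtype=object))
    arr = arr.where(~arr.isna(), "")
    codes, uniques = pd.factorize(arr.to_numpy())
    uniques = np.asarray(uniques, dtype=object)
    missing = np.flatnonzero(uniques == "")
    if len(missing):
        m = missing[0]
        codes = codes.copy()
        codes[codes == m] = -1
        codes[codes > m] -= 1
        uniques = np.delete(uniques, m)
    return codes.astype(np.int64), uniques


def _decode(codes: np.ndarray, uniques: np.ndarray) -> np.ndarray:
    lut = np.concatenate([[""], uniques])
    return lut[codes + 1].astype(object)


def modal_filter(labels, half_width: int = 2) -> np.ndarray:
    """Centred sliding modal filter over per-second labels.

    Each second is reassigned to the most frequent label of its
    ``+/- half_width`` window (shrunken at the edges). Ties for the mode
    retain the original centre label; missing centre seconds stay missing.
    """
    codes, uniques = _encode(labels)
    n, k = len(codes), len(uniques)
    if n == 0 or k == 0:
        return np.asarray(labels, dtype=object).copy()
    counts = np.zeros((k, n), dtype=np.int16)
    for off in range(-half_width, half_width + 1):
        if off < 0:
            src = codes[:off]
            sl = slice(-off, n)
        elif off > 0:
            src = codes[off:]
            sl = slice(0, n - off)
        else:
            src = codes
            sl = slice(0, n)
        for c in range(k):
            counts[c, sl] += src == c
    top = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    n_top = (counts == top).sum(axis=0)
    out = codes.copy()
    unique_win = (n_top == 1) & (top > 0) & (codes >= 0)
    out[unique_win] = winner[unique_win]
    return _decode(out, uniques)


def fill_missing(labels) -> np.ndarray:
    """Fill missing seconds: last observation carried forward, leading
    missing values carried backward from the next observation."""
    codes, uniques = _encode(labels)
    if (codes < 0).all():
        raise ValueError("label series is entirely missing")
    s = pd.Series(np.where(codes < 0, np.nan, codes)).ffill().bfill()
    return _decode(s.to_numpy().astype(np.int64), uniques)


def _rle(codes: np.ndarray):
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(codes)]]))
    return codes[starts], lengths


def collapse_blips(labels, min_run: int = 3) -> np.ndarray:
    """Absorb interior label runs shorter than ``min_run`` seconds.

    Missing labels are filled first (LOCF, then NOCB for a leading gap).
    Scanning left to right, each interior run shorter than ``min_run`` is
    absorbed into the surrounding state: agreeing flanks take that state;
    disagreeing flanks take the longer one (ties -> the preceding state).
    Repeats until no interior run is short; edge runs may stay short.
    """
    filled = fill_missing(labels)
    codes, uniques = _encode(filled)
    values, lengths = _rle(codes)
    vals = list(values)
    lens = list(lengths)
    i = 1
    while i < len(vals) - 1:
        if lens[i] >= min_run:
            i += 1
            continue
        left_v, right_v = vals[i - 1], vals[i + 1]
        if left_v == right_v:
            lens[i - 1] += lens[i] + lens[i + 1]
            del vals[i:i + 2], lens[i:i + 2]
        elif lens[i - 1] >= lens[i + 1]:  # tie -> preceding flank
            lens[i - 1] += lens[i]
            del vals[i], lens[i]
        else:
            lens[i + 1] += lens[i]
            del vals[i], lens[i]
        i = max(1, i - 1)
    return _decode(np.repeat(np.array(vals), np.array(lens)), uniques)


def smooth_labels(labels, half_width: int = 2, min_run: int = 3) -> np.ndarray:
    """Full smoothing chain: modal filter then blip collapse."""
    return collapse_blips(modal_filter(labels, half_width), min_run)


def regroup(labels, scheme: dict[str, str] | None = None) -> np.ndarray:
    """Map seven-class labels onto the final behaviour categories.

    Unknown labels are rejected; missing ('') passes through unchanged.
    """
    scheme = REGROUP_MAP if scheme is None else scheme
    codes, uniques = _encode(labels)
    unknown = [u for u in uniques if u not in scheme]
    if unknown:
        raise ValueError(f"unknown labels: {unknown}")
    mapped = np.array([scheme[u] for u in uniques], dtype=object)
    return _decode(codes, mapped)


def bin_20s(
    labels,
    vedba_seconds: pd.DataFrame | None = None,
    bin_s: int = BIN_S,
    start_time: np.datetime64 | None = None,
    meta: dict | None = None,
    gap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Aggregate per-second labels (and VeDBA) into non-overlapping bins.

    Each bin takes the majority label over its seconds (ties -> the label of
    the bin's central second); per-bin VeDBA summaries are the means of the
    within-second maxima and minima. Bins with more than ``gap_fraction``
    missing seconds are flagged as gaps. A trailing partial bin is dropped.
    """
    codes, uniques = _encode(labels)
    n_bins = len(codes) // bin_s
    if len(codes) % bin_s:
        warnings.warn("trailing partial bin dropped")
    codes = codes[: n_bins * bin_s].reshape(n_bins, bin_s)
    k = len(uniques)
    counts = np.stack([(codes == c).sum(axis=1) for c in range(k)], axis=0) \
        if k else np.zeros((0, n_bins), dtype=int)
    if k:
        top = counts.max(axis=0)
        winner = counts.argmax(axis=0)
        n_top = (counts == top).sum(axis=0)
        central = codes[:, bin_s // 2]
        out = np.where((n_top > 1), central, winner)
        out = np.where(top == 0, -1, out)
    else:
        out = np.full(n_bins, -1)
    n_missing = (codes < 0).sum(axis=1)

    bins = pd.DataFrame(
        {
            "start_s": np.arange(n_bins) * bin_s,
            "label": _decode(out.astype(np.int64), uniques),
            "is_gap": n_missing > gap_fraction * bin_s,
        }
    )
    if vedba_seconds is not None:
        vmax = vedba_seconds["vedba_max"].to_numpy()[: n_bins * bin_s]
        vmin = vedba_seconds["vedba_min"].to_numpy()[: n_bins * bin_s]
        bins["vedba_max_mean"] = vmax.reshape(n_bins, bin_s).mean(axis=1)
        bins["vedba_min_mean"] = vmin.reshape(n_bins, bin_s).mean(axis=1)
    else:
        bins["vedba_max_mean"] = np.nan
        bins["vedba_min_mean"] = np.nan

    if start_time is not None:
        ts = np.datetime64(start_time) + bins["start_s"].to_numpy().astype(
            "timedelta64[s]")
        bins["timestamp"] = ts
        bins["date"] = ts.astype("datetime64[D]")
        bins["hour"] = ((bins["start_s"] % 86400) // 3600).astype(int)
    if meta:
        for key in ("individual_id", "sex", "habitat", "mass_kg"):
            if key in meta:
                bins[key] = meta[key]
    return bins


def exclude_other(bins: pd.DataFrame, warn_fraction: float = 0.05) -> pd.DataFrame:
    """Drop residual ``Other`` bins before modelling and budgets.

    The removed fraction is reported in ``result.attrs['other_fraction']``;
    a fraction above ``warn_fraction`` triggers a model-drift warning.
    """
    n = len(bins)
    mask = bins["label"] == OTHER
    frac = float(mask.sum() / n) if n else 0.0
    if frac > warn_fraction:
        warnings.warn(
            f"'Other' represents {frac:.1%} of bins — possible model drift")
    out = bins.loc[~mask].reset_index(drop=True)
    out.attrs["other_fraction"] = frac
    return out
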