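"""Intensity-direct (ID) and intensity-histogram (GOH) feature families.

ID operates on raw HU values: 21 global statistics plus 35 local ones (a
local statistic computed on the in-mask 3x3x3 window around every voxel,
then aggregated over voxels). GOH is histogram-oriented: 19 fixed quantiles
plus 21 distributional summaries.

Conventions fixed for exact testability: quantiles use linear interpolation
of the empirical CDF (numpy's default, R type-7); SD/variance use ddof=1;
entropy/uniformity use a 64-bin (global) or 32-level (local) min-max
histogram with base-2 logs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

__all__ = [
    "discretize",
    "ID_GLOBAL_STATS",
    "ID_LOCAL_STATS",
    "ID_LOCAL_AGGS",
    "GOH_QUANTILES",
    "GOH_STATS",
    "intensity_direct_features",
    "intensity_histogram_features",
]

GOH_QUANTILES = (0.025, 0.05, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7,
                 0.75, 0.8, 0.9, 0.95, 0.975, 0.15, 0.35, 0.65, 0.85)

GOH_STATS = (
    "Mean", "Median", "Mode", "SD", "Variance", "MAD", "RobustMAD",
    "Skewness", "Kurtosis", "Energy", "Entropy", "Uniformity", "Range",
    "IQR", "CV", "QuartileCoefficient", "P90MinusP10", "Min", "Max",
    "Sum", "Count",
)

ID_GLOBAL_STATS = (
    "Mean", "Median", "Min", "Max", "Range", "SD", "Variance", "Skewness",
    "Kurtosis", "Energy", "Entropy", "MAD", "RMS", "Uniformity",
    "P10", "P25", "P75", "P90", "IQR", "0.025Quantile", "0.975Quantile",
)

ID_LOCAL_STATS = ("Mean", "Std", "Range", "Entropy", "Median", "Min", "Max")
ID_LOCAL_AGGS = ("Max", "Min", "Mean", "Median", "Std")

_N_HIST_BINS = 64
_N_LOCAL_LEVELS = 32


def discretize(image: np.ndarray, mask: np.ndarray, n_gray_levels: int) -> np.ndarray:
    """Min-max binning of in-mask intensities into levels 1..G (0 outside).

    A constant region maps to level 1 everywhere.
    """
    if n_gray_levels < 2:
        raise ValueError("n_gray_levels must be >= 2")
    m = np.asarray(mask, bool)
    out = np.zeros(np.shape(image), dtype=np.int64)
    if not m.any():
        return out
    vals = np.asarray(image, float)[m]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out[m] = 1
        return out
    lv = np.floor((vals - lo) / (hi - lo) * n_gray_levels).astype(np.int64) + 1
    out[m] = np.clip(lv, 1, n_gray_levels)
    return out


def _hist_probs(vals: np.ndarray, n_bins: int = _N_HIST_BINS) -> np.ndarray:
    counts, _ = np.histogram(vals, bins=n_bins)
    return counts / counts.sum()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _nan_dict(names) -> dict:
    return {n: float("nan") for n in names}


def intensity_direct_features(
    image: np.ndarray, mask: np.ndarray, local_window: int = 1
) -> dict:
    """The 56 ID features (21 global + 7 local statistics x 5 aggregates)."""
    m = np.asarray(mask, bool)
    names = list(ID_GLOBAL_STATS) + [
        f"Local{s}{a}" for s in ID_LOCAL_STATS for a in ID_LOCAL_AGGS
    ]
    if not m.any():
        return _nan_dict(names)
    v = np.asarray(image, float)[m]
    p = _hist_probs(v)
    constant = v.max() == v.min()
    out = {
        "Mean": float(v.mean()),
        "Median": float(np.median(v)),
        "Min": float(v.min()),
        "Max": float(v.max()),
        "Range": float(v.max() - v.min()),
        "SD": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "Variance": float(v.var(ddof=1)) if v.size > 1 else 0.0,
        "Skewness": float(stats.skew(v)) if v.size > 2 and not constant else 0.0,
        "Kurtosis": float(stats.kurtosis(v)) if v.size > 3 and not constant else 0.0,
        "Energy": float((v**2).sum()),
        "Entropy": _entropy(p),
        "MAD": float(np.abs(v - v.mean()).mean()),
        "RMS": float(np.sqrt((v**2).mean())),
        "Uniformity": float((p**2).sum()),
        "P10": float(np.quantile(v, 0.10)),
        "P25": float(np.quantile(v, 0.25)),
        "P75": float(np.quantile(v, 0.75)),
        "P90": float(np.quantile(v, 0.90)),
        "IQR": float(np.quantile(v, 0.75) - np.quantile(v, 0.25)),
        "0.025Quantile": float(np.quantile(v, 0.025)),
        "0.975Quantile": float(np.quantile(v, 0.975)),
    }
    out.update(_local_features(image, m, local_window))
    return out


def _windows(arr: np.ndarray, m: np.ndarray, radius: int):
    """Per-in-mask-voxel flattened window values (NaN outside the mask)."""
    idx = np.argwhere(m)
    lo = np.maximum(idx.min(axis=0) - radius, 0)
    hi = np.minimum(idx.max(axis=0) + radius + 1, np.asarray(arr.shape))
    sub = np.full(hi - lo + 2 * radius, np.nan)
    crop = tuple(slice(l, h) for l, h in zip(lo, hi))
    inner = tuple(slice(radius, radius + h - l) for l, h in zip(lo, hi))
    msub = np.zeros(sub.shape, bool)
    sub[inner] = np.where(m[crop], np.asarray(arr, float)[crop], np.nan)
    msub[inner] = m[crop]
    w = 2 * radius + 1
    win = sliding_window_view(sub, (w, w, w))
    centres = msub[tuple(slice(radius, radius + s) for s in win.shape[:3])]
    return win[centres].reshape(-1, w**3)


def _local_features(image: np.ndarray, m: np.ndarray, radius: int) -> dict:
    W = _windows(image, m, radius)
    per_voxel = {
        "Mean": np.nanmean(W, axis=1),
        "Std": np.sqrt(np.nanmean((W - np.nanmean(W, axis=1, keepdims=True)) ** 2, axis=1)),
        "Range": np.nanmax(W, axis=1) - np.nanmin(W, axis=1),
        "Entropy": _local_entropy(image, m, radius),
        "Median": np.nanmedian(W, axis=1),
        "Min": np.nanmin(W, axis=1),
        "Max": np.nanmax(W, axis=1),
    }
    out = {}
    for stat, vals in per_voxel.items():
        out[f"Local{stat}Max"] = float(np.max(vals))
        out[f"Local{stat}Min"] = float(np.min(vals))
        out[f"Local{stat}Mean"] = float(np.mean(vals))
        out[f"Local{stat}Median"] = float(np.median(vals))
        out[f"Local{stat}Std"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return out


def _local_entropy(image: np.ndarray, m: np.ndarray, radius: int) -> np.ndarray:
    """Window entropy of ROI-discretized intensities (32 levels, base 2)."""
    levels = discretize(image, m, _N_LOCAL_LEVELS).astype(float)
    levels[~m] = np.nan
    W = _windows(levels, m, radius)
    n = W.shape[0]
    counts = np.zeros((n, _N_LOCAL_LEVELS + 1))
    rows = np.repeat(np.arange(n), W.shape[1])
    flat = W.ravel()
    ok = ~np.isnan(flat)
    np.add.at(counts, (rows[ok], flat[ok].astype(int)), 1.0)
    counts = counts[:, 1:]
    totals = counts.sum(axis=1, keepdims=True)
    p = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    logp = np.zeros_like(p)
    np.log2(p, where=p > 0, out=logp)
    return -(p * logp).sum(axis=1)


def intensity_histogram_features(image: np.ndarray, mask: np.ndarray) -> dict:
    """The 40 GOH features: 19 quantiles + 21 distributional summaries."""
    m = np.asarray(mask, bool)
    qnames = [f"{q:g}Quantile" for q in sorted(GOH_QUANTILES)]
    if not m.any():
        return _nan_dict(qnames + list(GOH_STATS))
    v = np.asarray(image, float)[m]
    out = {f"{q:g}Quantile": float(np.quantile(v, q)) for q in sorted(GOH_QUANTILES)}

    counts, edges = np.histogram(v, bins=_N_HIST_BINS)
    p = counts / counts.sum()
    mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0)
    if v.max() == v.min():
        mode = float(v[0])
    q1, q3 = np.quantile(v, 0.25), np.quantile(v, 0.75)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    constant = v.max() == v.min()
    out.update(
        {
            "Mean": mean,
            "Median": float(np.median(v)),
            "Mode": mode,
            "SD": sd,
            "Variance": sd**2,
            "MAD": float(np.abs(v - mean).mean()),
            "RobustMAD": float(np.median(np.abs(v - np.median(v)))),
            "Skewness": float(stats.skew(v)) if v.size > 2 and not constant else 0.0,
            "Kurtosis": float(stats.kurtosis(v)) if v.size > 3 and not constant else 0.0,
            "Energy": float((v**2).sum()),
            "Entropy": _entropy(p),
            "Uniformity": float((p**2).sum()),
            "Range": float(v.max() - v.min()),
            "IQR": float(q3 - q1),
            "CV": float(sd / mean) if mean != 0 else 0.0,
            "QuartileCoefficient": float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0,
            "P90MinusP10": float(np.quantile(v, 0.9) - np.quantile(v, 0.1)),
            "Min": float(v.min()),
            "Max": float(v.max()),
            "Sum": float(v.sum()),
            "Count": float(v.size),
        }
    )
    return out
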