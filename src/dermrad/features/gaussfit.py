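"""Intensity-histogram Gaussian-fit family (IHGaussFit, 18 features).

1-, 2- and 3-component Gaussian mixtures are least-squares fitted to the
binned in-mask intensity histogram (density scale); each component reports
mean, std and amplitude, components sorted by mean. Fits that fail to
converge yield NaN for that component count only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["gaussfit_features", "gaussfit_feature_names", "MIN_FIT_VOXELS"]

MIN_FIT_VOXELS = 50
_N_BINS = 64


def _model(x, *params):
    y = np.zeros_like(x)
    for k in range(0, len(params), 3):
        a, m, s = params[k], params[k + 1], params[k + 2]
        y = y + a * np.exp(-((x - m) ** 2) / (2.0 * s**2))
    return y


def gaussfit_feature_names(components=(1, 2, 3)) -> list[str]:
    names = []
    for k in components:
        for j in range(1, k + 1):
            tag = f"{k}Gauss" if k == 1 else f"{k}Gauss{j}"
            for stat in ("Mean", "Std", "Amplitude"):
                names.append(f"IHGaussFit{tag}{stat}")
    return names


def gaussfit_features(
    image: np.ndarray, mask: np.ndarray, components=(1, 2, 3)
) -> dict:
    m = np.asarray(mask, bool)
    names = gaussfit_feature_names(components)
    out = {n: float("nan") for n in names}
    if not m.any():
        return out
    v = np.asarray(image, float)[m]

    if v.max() == v.min():
        # Degenerate: a point mass; first component carries the full bin mass.
        for k in components:
            for j in range(1, k + 1):
                tag = f"{k}Gauss" if k == 1 else f"{k}Gauss{j}"
                out[f"IHGaussFit{tag}Mean"] = float(v[0])
                out[f"IHGaussFit{tag}Std"] = 0.0
                out[f"IHGaussFit{tag}Amplitude"] = 1.0 if j == 1 else 0.0
        return out
    if v.size < MIN_FIT_VOXELS:
        return out

    counts, edges = np.histogram(v, bins=_N_BINS, density=True)
    x = (edges[:-1] + edges[1:]) / 2.0
    sd = v.std(ddof=1)
    for k in components:
        qs = np.quantile(v, (np.arange(k) + 0.5) / k)
        p0 = []
        for mu in qs:
            p0 += [counts.max() / k, float(mu), float(sd / k) or 1.0]
        lb = [0.0, v.min() - sd, 1e-9] * k
        ub = [np.inf, v.max() + sd, np.inf] * k
        try:
            popt, _ = curve_fit(
                _model, x, counts, p0=p0, bounds=(lb, ub), maxfev=5000
            )
        except (RuntimeError, ValueError):
            continue
        comps = sorted(
            [(popt[3 * j + 1], popt[3 * j + 2], popt[3 * j]) for j in range(k)]
        )
        for j, (mu, s, a) in enumerate(comps, start=1):
            tag = f"{k}Gauss" if k == 1 else f"{k}Gauss{j}"
            out[f"IHGaussFit{tag}Mean"] = float(mu)
            out[f"IHGaussFit{tag}Std"] = float(abs(s))
            out[f"IHGaussFit{tag}Amplitude"] = float(a)
    return out
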