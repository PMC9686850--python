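"""Assembly of the full 884-feature bank per ROI.

Family allocation (defaults):

====================  =====  ==========================================
family (name code)    count  parameters
====================  =====  ==========================================
GLCM 2.5D   (F2)       704   22 stats x 8 directions x 4 offsets
GLRLM 2.5D  (F3)        44   11 stats x 4 directions
NGTDM 2.5D  (F5)         5
IntensityDirect (F4)    56   21 global + 7 local stats x 5 aggregates
IntensityHist (F1)      40   19 quantiles + 21 summaries
GaussFit    (F6)        18   (mean, std, amplitude) x (1+2+3) components
Shape       (F8)        17
====================  =====  ==========================================

Feature names follow ``<ROI>_F<k>.<Family><params>_<Stat>``, e.g.
``PTV_100PD_F2.GLCM25270.7_Corr`` (direction 270 degrees, offset 7). GLCM
matrices are symmetric, so opposite directions carry identical values; both
are emitted by design, and downstream correlation filtering removes the
redundancy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..grids import ImageVolume, RoiMask
from .gaussfit import gaussfit_feature_names, gaussfit_features
from .intensity import (
    ID_GLOBAL_STATS,
    ID_LOCAL_AGGS,
    ID_LOCAL_STATS,
    GOH_QUANTILES,
    GOH_STATS,
    discretize,
    intensity_direct_features,
    intensity_histogram_features,
)
from .shape import SHAPE_STATS, shape_features
from .texture import (
    GLCM_STATS,
    GLRLM_STATS,
    NGTDM_STATS,
    glcm_features_25d,
    glrlm_features_25d,
    ngtdm_features_25d,
)

__all__ = ["FeatureBankConfig", "bank_feature_names", "extract_roi_features", "extract_all"]


@dataclass
class FeatureBankConfig:
    n_gray_levels: int = 64
    glcm_directions: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
    glcm_offsets: tuple[int, ...] = (1, 4, 7, 10)
    glrlm_directions: tuple[int, ...] = (0, 45, 90, 135)
    local_window: int = 1
    gaussfit_components: tuple[int, ...] = (1, 2, 3)
    hull_directions: int = 100

    def __post_init__(self) -> None:
        if self.n_gray_levels < 8:
            raise ValueError("n_gray_levels must be >= 8")
        for dirs in (self.glcm_directions, self.glrlm_directions):
            if len(set(dirs)) != len(dirs):
                raise ValueError("directions must be unique")

    @property
    def bank_size(self) -> int:
        return (
            len(GLCM_STATS) * len(self.glcm_directions) * len(self.glcm_offsets)
            + len(GLRLM_STATS) * len(self.glrlm_directions)
            + len(NGTDM_STATS)
            + len(ID_GLOBAL_STATS) + len(ID_LOCAL_STATS) * len(ID_LOCAL_AGGS)
            + len(GOH_QUANTILES) + len(GOH_STATS)
            + 3 * sum(self.gaussfit_components)
            + len(SHAPE_STATS)
        )


def bank_feature_names(cfg: FeatureBankConfig | None = None) -> list[str]:
    """Ordered feature names for one ROI (no ROI prefix)."""
    cfg = cfg or FeatureBankConfig()
    names: list[str] = []
    names += [f"F1.GOH{q:g}Quantile" for q in sorted(GOH_QUANTILES)]
    names += [f"F1.GOH_{s}" for s in GOH_STATS]
    for d in cfg.glcm_directions:
        for off in cfg.glcm_offsets:
            names += [f"F2.GLCM25{d}.{off}_{s}" for s in GLCM_STATS]
    for d in cfg.glrlm_directions:
        names += [f"F3.GLRL25{d}_{s}" for s in GLRLM_STATS]
    names += [f"F4.ID_{s}" for s in ID_GLOBAL_STATS]
    names += [f"F4.ID_Local{s}{a}" for s in ID_LOCAL_STATS for a in ID_LOCAL_AGGS]
    names += [f"F5.NID25_{s}" for s in NGTDM_STATS]
    names += [f"F6.{n}" for n in gaussfit_feature_names(cfg.gaussfit_components)]
    names += [f"F8.Shape{s}" for s in SHAPE_STATS]
    return names


def _crop_to_mask(image: np.ndarray, mask: np.ndarray):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return image[sl], mask[sl]


def extract_roi_features(
    image: ImageVolume, roi: RoiMask, cfg: FeatureBankConfig | None = None
) -> dict:
    """All 884 named features for one ROI; degenerate/empty ROIs give NaNs."""
    cfg = cfg or FeatureBankConfig()
    names = bank_feature_names(cfg)
    if roi.degenerate or roi.n_voxels == 0:
        return {n: float("nan") for n in names}

    img, m = _crop_to_mask(image.array, roi.mask)
    out: dict = {}
    goh = intensity_histogram_features(img, m)
    out.update({f"F1.GOH{q:g}Quantile": goh[f"{q:g}Quantile"] for q in sorted(GOH_QUANTILES)})
    out.update({f"F1.GOH_{s}": goh[s] for s in GOH_STATS})

    levels = discretize(img, m, cfg.n_gray_levels)
    # symmetric matrices: compute each direction mod 180 once, emit both names
    cache: dict = {}
    for d in cfg.glcm_directions:
        for off in cfg.glcm_offsets:
            key = (d % 180, off)
            if key not in cache:
                cache[key] = glcm_features_25d(levels, m, key[0], off, cfg.n_gray_levels)
            for s in GLCM_STATS:
                out[f"F2.GLCM25{d}.{off}_{s}"] = cache[key][s]
    for d in cfg.glrlm_directions:
        feats = glrlm_features_25d(levels, m, d, cfg.n_gray_levels)
        out.update({f"F3.GLRL25{d}_{s}": feats[s] for s in GLRLM_STATS})

    idf = intensity_direct_features(img, m, cfg.local_window)
    out.update({f"F4.ID_{s}": idf[s] for s in ID_GLOBAL_STATS})
    out.update(
        {f"F4.ID_Local{s}{a}": idf[f"Local{s}{a}"] for s in ID_LOCAL_STATS for a in ID_LOCAL_AGGS}
    )

    ngt = ngtdm_features_25d(levels, m, cfg.n_gray_levels)
    out.update({f"F5.NID25_{s}": ngt[s] for s in NGTDM_STATS})

    gf = gaussfit_features(img, m, cfg.gaussfit_components)
    out.update({f"F6.{k}": v for k, v in gf.items()})

    shp = shape_features(roi.mask, image.spacing, cfg.hull_directions)
    out.update({f"F8.Shape{s}": shp[s] for s in SHAPE_STATS})
    assert list(out) == names
    return out


def extract_all(
    image: ImageVolume, rois: list[RoiMask], cfg: FeatureBankConfig | None = None
) -> pd.Series:
    """One combined row of ``len(rois) x 884`` ROI-prefixed feature values."""
    cfg = cfg or FeatureBankConfig()
    row: dict = {}
    for roi in rois:
        feats = extract_roi_features(image, roi, cfg)
        row.update({f"{roi.label}_{k}": v for k, v in feats.items()})
    return pd.Series(row)


_GLCM_RE = re.compile(r"F2\.GLCM25(\d+)\.(\d+)_(.+)")
_GLRL_RE = re.compile(r"F3\.GLRL25(\d+)_(.+)")


def compute_single_feature(
    image: np.ndarray, mask: np.ndarray,
    name: str, spacing: tuple[float, float, float],
    cfg: FeatureBankConfig | None = None,
) -> float:
    """Compute one named bank feature on an arbitrary (small) ROI.

    Used by sliding feature maps; ``name`` carries no ROI prefix.
    """
    cfg = cfg or FeatureBankConfig()
    if not np.asarray(mask, bool).any():
        return float("nan")
    if (mo := _GLCM_RE.fullmatch(name)):
        d, off, stat = int(mo[1]), int(mo[2]), mo[3]
        levels = discretize(image, mask, cfg.n_gray_levels)
        return glcm_features_25d(levels, mask, d % 180, off, cfg.n_gray_levels)[stat]
    if (mo := _GLRL_RE.fullmatch(name)):
        levels = discretize(image, mask, cfg.n_gray_levels)
        return glrlm_features_25d(levels, mask, int(mo[1]), cfg.n_gray_levels)[mo[2]]
    if name.startswith("F5.NID25_"):
        levels = discretize(image, mask, cfg.n_gray_levels)
        return ngtdm_features_25d(levels, mask, cfg.n_gray_levels)[name.removeprefix("F5.NID25_")]
    if name.startswith("F4.ID_"):
        key = name.removeprefix("F4.ID_")
        return intensity_direct_features(image, mask, cfg.local_window)[key]
    if name.startswith("F1.GOH"):
        key = name.removeprefix("F1.GOH").removeprefix("_")
        return intensity_histogram_features(image, mask)[key]
    if name.startswith("F6."):
        return gaussfit_features(image, mask, cfg.gaussfit_components)[name.removeprefix("F6.")]
    if name.startswith("F8.Shape"):
        return shape_features(np.asarray(mask, bool), spacing, cfg.hull_directions)[
            name.removeprefix("F8.Shape")
        ]
    raise KeyError(f"unknown feature name {name!r}")
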