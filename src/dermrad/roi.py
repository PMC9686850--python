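"""Dose-gradient ROI construction.

Six ROIs per patient: the PTV sub-volumes receiving >= 100% / 105% / 108%
of the prescribed dose, and the skin sub-volumes receiving >= 20 / 30 /
40 Gy. Thresholds are inclusive (a voxel on the isodose line belongs to the
ROI) and applied to the dose resampled onto the image grid; masks are never
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, ImageVolume, RoiMask

__all__ = ["RoiConfig", "resample_dose", "build_ptv_rois", "build_skin_rois", "build_all_rois"]


@dataclass
class RoiConfig:
    prescription_Gy: float = 50.0
    ptv_levels: tuple[float, ...] = (1.00, 1.05, 1.08)
    skin_levels_Gy: tuple[float, ...] = (20.0, 30.0, 40.0)
    min_voxels: int = 27

    def __post_init__(self) -> None:
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        for levels in (self.ptv_levels, self.skin_levels_Gy):
            if list(levels) != sorted(levels) or len(set(levels)) != len(levels):
                raise ValueError("threshold levels must be strictly increasing")


def resample_dose(dose: DoseGrid, target: ImageVolume) -> DoseGrid:
    """Trilinearly resample the dose onto the image grid (physical space).

    Voxels outside the dose extent get 0 Gy. Raises if the two grids do not
    overlap physically.
    """
    if dose.same_grid(target):
        return DoseGrid(dose.array.copy(), target.spacing, target.origin)

    import SimpleITK as sitk

    def _extent(vol: ImageVolume):
        lo = np.asarray(vol.origin)
        hi = lo + (np.asarray(vol.shape)) * np.asarray(vol.spacing)
        return lo, hi

    lo_d, hi_d = _extent(dose)
    lo_t, hi_t = _extent(target)
    if np.any(hi_d <= lo_t) or np.any(hi_t <= lo_d):
        raise ValueError("dose and image grids have disjoint physical extents")

    src = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(dose.array.astype(np.float64), (2, 1, 0)))
    )
    src.SetSpacing(dose.spacing)
    src.SetOrigin(dose.origin)
    ref = sitk.Image([int(s) for s in target.shape], sitk.sitkFloat64)
    ref.SetSpacing(target.spacing)
    ref.SetOrigin(target.origin)
    out = sitk.Resample(src, ref, sitk.Transform(), sitk.sitkLinear, 0.0)
    arr = np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0))
    return DoseGrid(arr, target.spacing, target.origin)


def _threshold_rois(
    dose: DoseGrid,
    base_mask: np.ndarray,
    thresholds_gy: list[float],
    labels: list[str],
    min_voxels: int,
) -> list[RoiMask]:
    rois = []
    for thr, label in zip(thresholds_gy, labels):
        m = base_mask & (dose.array >= thr)
        rois.append(RoiMask(label, m, degenerate=int(m.sum()) < min_voxels))
    return rois


def build_ptv_rois(dose: DoseGrid, ptv_mask: RoiMask, cfg: RoiConfig) -> list[RoiMask]:
    """PTV_100PD / PTV_105PD / PTV_108PD: PTV voxels at >= level x prescription."""
    if ptv_mask.n_voxels == 0:
        raise ValueError("empty PTV mask")
    thresholds = [f * cfg.prescription_Gy for f in cfg.ptv_levels]
    labels = [f"PTV_{int(round(f * 100))}PD" for f in cfg.ptv_levels]
    return _threshold_rois(dose, ptv_mask.mask, thresholds, labels, cfg.min_voxels)


def build_skin_rois(dose: DoseGrid, skin_mask: RoiMask, cfg: RoiConfig) -> list[RoiMask]:
    """SKIN_20Gy / SKIN_30Gy / SKIN_40Gy: skin voxels at >= the absolute level."""
    if skin_mask.n_voxels == 0:
        raise ValueError("empty skin mask")
    labels = [f"SKIN_{int(round(g))}Gy" for g in cfg.skin_levels_Gy]
    return _threshold_rois(dose, skin_mask.mask, list(cfg.skin_levels_Gy), labels, cfg.min_voxels)


def build_all_rois(dose: DoseGrid, ptv_mask: RoiMask, skin_mask: RoiMask,
                   cfg: RoiConfig | None = None, image: ImageVolume | None = None) -> list[RoiMask]:
    """The six dose-gradient ROIs, resampling dose onto the image grid first."""
    cfg = cfg or RoiConfig()
    if image is not None and not dose.same_grid(image):
        dose = resample_dose(dose, image)
    return build_ptv_rois(dose, ptv_mask, cfg) + build_skin_rois(dose, skin_mask, cfg)


def write_rois(rois: list[RoiMask], reference: ImageVolume, out_dir) -> "pd.DataFrame":
    """Write each mask as NIfTI (label in the filename) plus a summary CSV of
    voxel counts and volumes in cc."""
    from pathlib import Path

    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.diag(list(reference.spacing) + [1.0])
    aff[:3, 3] = reference.origin
    rows = []
    for roi in rois:
        nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), aff),
                 str(out / f"roi_{roi.label}.nii.gz"))
        rows.append({"label": roi.label, "n_voxels": roi.n_voxels,
                     "volume_cc": roi.volume_cc(reference.spacing),
                     "degenerate": roi.degenerate})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "roi_summary.csv", index=False)
    return summary
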