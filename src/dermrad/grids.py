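"""Grid-aligned volume containers.

Arrays are indexed ``(x, y, z)`` with ``z`` the superior-inferior (slice)
axis; all texture families that operate "2.5D" accumulate per-axial-slice
matrices over ``z``. Spacing and origin are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "DoseGrid", "RoiMask", "ROI_LABELS"]

#: Canonical ROI labels: PTV sub-volumes by % of prescription, skin
#: sub-volumes by absolute isodose level.
ROI_LABELS = (
    "PTV_100PD",
    "PTV_105PD",
    "PTV_108PD",
    "SKIN_20Gy",
    "SKIN_30Gy",
    "SKIN_40Gy",
)


@dataclass
class ImageVolume:
    """A 3-D scalar volume (HU for CT) with geometric metadata."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError("volume must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


class DoseGrid(ImageVolume):
    """A 3-D dose distribution in Gy; same geometry semantics as the image."""


@dataclass
class RoiMask:
    """Binary mask on the image grid with a dose-gradient label.

    ``degenerate`` marks masks below the minimum voxel count; downstream
    feature extraction emits nulls for degenerate ROIs instead of failing.
    """

    label: str
    mask: np.ndarray
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_cc(self, spacing: tuple[float, float, float]) -> float:
        return self.n_voxels * float(np.prod(spacing)) / 1000.0
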