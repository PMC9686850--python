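"""Synthetic breast-radiotherapy phantom cohort.

Real planning CTs, dose grids and outcomes for radiation-dermatitis (RD 2+)
modelling are not publicly deposited, so this module generates a fully
self-contained stand-in cohort: a half-ellipsoid "breast" on an elliptic
thorax section, a smooth dose field with an in-PTV hot spot exceeding 108%
of the prescription, class-conditional Gaussian-random-field texture in the
soft tissue (the planted, recoverable signal), and a 29-variable clinical /
dosimetric table whose marginals follow the published cohort description
(214 patients, 144 with RD 2+).

Everything is deterministic under ``CohortSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import DoseGrid, ImageVolume, RoiMask

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "generate_cohort",
    "write_patient",
    "read_patient",
    "write_cohort",
    "inject_missingness",
    "TABLE1_MARGINALS",
    "CLINICAL_COLUMNS",
]

# Per-class marginals of the 29 clinical and dosimetric variables
# (class 0 = grade <=1, n=70; class 1 = grade >=2, n=144). Continuous
# variables carry (mean, sd) per class; categorical carry per-class counts.
# With label association disabled (the default) the two classes are pooled,
# so covariates are independent of the outcome.
TABLE1_MARGINALS: dict[str, dict] = {
    "Age": {"kind": "continuous", "c0": (50.04, 9.44), "c1": (49.48, 9.62)},
    "BMI": {"kind": "continuous", "c0": (22.94, 3.03), "c1": (23.25, 2.70)},
    "Body temperature": {"kind": "continuous", "c0": (36.67, 0.33), "c1": (36.70, 0.35)},
    "Laterality": {"kind": "categorical", "levels": ["Left", "Right"],
                   "c0": [44, 26], "c1": [82, 62]},
    "Quadrant position": {"kind": "categorical",
                          "levels": ["Upper-Outer", "Upper-Inner", "Lower-Outer", "Lower-Inner"],
                          "c0": [17, 26, 13, 14], "c1": [23, 57, 54, 10]},
    "Tumor maximum diameter": {"kind": "continuous", "c0": (1.97, 0.91), "c1": (2.28, 1.68)},
    "Tumor grade": {"kind": "categorical", "levels": ["I", "II", "III"],
                    "c0": [5, 36, 29], "c1": [13, 69, 62]},
    "Histologic type": {"kind": "categorical",
                        "levels": ["DCIS", "IDC", "ILC", "IMC", "LCIS/DCIS"],
                        "c0": [10, 59, 1, 0, 0], "c1": [13, 124, 5, 1, 1]},
    "Overall Stage": {"kind": "categorical",
                      "levels": ["0", "I", "IIA", "IIB", "IIIA", "IIIB", "IIIC", "IV"],
                      "c0": [4, 14, 17, 0, 3, 18, 13, 1], "c1": [9, 16, 31, 1, 12, 30, 40, 5]},
    "T Stage": {"kind": "categorical", "levels": ["Tx~is", "T0", "T1", "T2", "T3", "T4"],
                "c0": [1, 3, 4, 43, 17, 2], "c1": [4, 5, 5, 74, 48, 8]},
    "N Stage": {"kind": "categorical", "levels": ["0", "1", "2", "3"],
                "c0": [36, 18, 11, 5], "c1": [66, 46, 21, 11]},
    "M Stage": {"kind": "categorical", "levels": ["0", "1"], "c0": [70, 0], "c1": [143, 1]},
    "CRP": {"kind": "continuous", "c0": (2.27, 4.19), "c1": (2.36, 5.03), "min": 0.0},
    "ER": {"kind": "categorical", "levels": ["Positive", "Negative"],
           "c0": [55, 15], "c1": [114, 30]},
    "PR": {"kind": "categorical", "levels": ["Positive", "Negative"],
           "c0": [50, 20], "c1": [112, 32]},
    "HER2": {"kind": "categorical", "levels": ["Positive", "Negative"],
             "c0": [14, 56], "c1": [34, 110]},
    "Surgery method": {"kind": "categorical",
                       "levels": ["Lumpectomy", "Mastectomy", "Reconstruction"],
                       "c0": [41, 27, 2], "c1": [84, 59, 1]},
    "Chemotherapy": {"kind": "categorical", "levels": ["No", "Yes"],
                     "c0": [13, 57], "c1": [32, 112]},
    "Hormone therapy": {"kind": "categorical", "levels": ["No", "Yes"],
                        "c0": [44, 26], "c1": [77, 67]},
    "EQD2_all": {"kind": "continuous", "c0": (52.16, 5.18), "c1": (52.66, 4.16)},
    "Lotion application": {"kind": "categorical", "levels": ["No", "Yes"],
                           "c0": [6, 64], "c1": [5, 139]},
    "PTV_mean": {"kind": "continuous", "c0": (5098.71, 325.99), "c1": (5139.06, 317.50)},
    "PTV_max": {"kind": "continuous", "c0": (5773.97, 477.05), "c1": (5839.24, 454.27)},
    "PTV_boost": {"kind": "categorical", "levels": ["Yes", "No"],
                  "c0": [41, 29], "c1": [80, 64]},
    "SKIN_mean": {"kind": "continuous", "c0": (3608.40, 493.26), "c1": (3587.22, 570.25)},
    "SKIN_max": {"kind": "continuous", "c0": (5447.94, 489.98), "c1": (5535.82, 464.63)},
    "SKIN_V20": {"kind": "continuous", "c0": (87.26, 10.00), "c1": (85.65, 12.01), "max": 100.0},
    "SKIN_V30": {"kind": "continuous", "c0": (70.60, 14.74), "c1": (69.69, 15.31), "max": 100.0},
    "SKIN_V40": {"kind": "continuous", "c0": (44.59, 21.24), "c1": (43.83, 20.93), "max": 100.0},
}

CLINICAL_COLUMNS: tuple[str, ...] = tuple(TABLE1_MARGINALS)

# Variables eligible for an optional weak clinical-label association, with
# the per-category score multiplied by the log-odds tilt for RD 2+ patients.
_ASSOCIATION_SCORES = {
    "Hormone therapy": {"No": 0.0, "Yes": 1.0},
    "T Stage": {"Tx~is": 0.0, "T0": 0.1, "T1": 0.2, "T2": 0.5, "T3": 0.8, "T4": 1.0},
    "Quadrant position": {"Upper-Outer": 0.0, "Upper-Inner": 0.0,
                          "Lower-Outer": 1.0, "Lower-Inner": 0.0},
}


@dataclass
class CohortSpec:
    """Controls for the synthetic cohort generator.

    ``effect_size_delta`` scales the class difference in soft-tissue texture:
    RD 2+ patients' random-field amplitude is larger by a factor (1 + delta)
    and its correlation length by (1 + delta/2). ``delta = 0`` makes image
    statistics identically distributed across classes.
    """

    n_patients: int = 214
    n_rd2plus: int = 144
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 5.0)
    prescription_Gy: float = 50.0
    effect_size_delta: float = 1.0
    clinical_marginals: dict | None = None
    seed: int = 0
    # Texture model (soft tissue ~ 40 HU base + correlated Gaussian field).
    base_hu: float = 40.0
    texture_sigma_hu: float = 12.0
    texture_corr_mm: float = 6.0
    patient_log_sd: float = 0.25
    white_noise_hu: float = 5.0
    # Optional weak clinical-label association (log-odds tilt); default off.
    clinical_label_log_odds: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.n_rd2plus > self.n_patients:
            raise ValueError("n_rd2plus must be <= n_patients")
        if any(int(g) < 16 for g in self.grid_shape):
            raise ValueError("degenerate grid: every axis must be >= 16 voxels")
        if self.effect_size_delta < 0:
            raise ValueError("effect_size_delta must be >= 0")
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def marginals(self) -> dict:
        return self.clinical_marginals or TABLE1_MARGINALS


@dataclass
class SyntheticPatient:
    patient_id: str
    image: ImageVolume
    dose: DoseGrid
    ptv_mask: RoiMask
    skin_mask: RoiMask
    clinical: dict
    label: int


def _phantom_masks(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Body, skin-shell and PTV masks of the breast phantom.

    Body = elliptic thorax section union a half-ellipsoid breast protruding
    anteriorly; skin = the outer 5 mm layer of the body; PTV = breast tissue
    with that 5 mm layer eroded away.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    cx, cz = nx * sx / 2.0, nz * sz / 2.0

    # Thorax: ellipse in (x, y), full z extent, pushed posterior (large y).
    ty = ny * sy * 0.68
    thorax = ((X - cx) / (nx * sx * 0.40)) ** 2 + ((Y - ty) / (ny * sy * 0.28)) ** 2 <= 1.0

    # Breast: half-ellipsoid anterior of the chest wall.
    by = ny * sy * 0.42
    breast_full = (
        ((X - cx) / (nx * sx * 0.22)) ** 2
        + ((Y - by) / (ny * sy * 0.20)) ** 2
        + ((Z - cz) / (nz * sz * 0.32)) ** 2
        <= 1.0
    )
    breast = breast_full & (Y <= ty)
    body = thorax | breast

    dist_in = ndimage.distance_transform_edt(body, sampling=spec.spacing_mm)
    skin = body & (dist_in <= 5.0)
    interior = dist_in > 5.0
    ptv = breast & interior
    return body, skin, ptv, breast


def _dose_field(spec: CohortSpec, ptv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Prescription plateau in the PTV, Gaussian hot spot to ~110% of Rx,
    exponential falloff with distance outside the PTV."""
    rx = spec.prescription_Gy
    falloff_mm = 25.0 * float(np.exp(rng.normal(0.0, 0.10)))
    dist = ndimage.distance_transform_edt(~ptv, sampling=spec.spacing_mm)
    dose = rx * np.exp(-dist / falloff_mm)

    # Hot spot centred on a random PTV voxel; amplitude keeps the in-PTV
    # maximum at >= 1.08 x Rx so every isodose ROI is non-empty.
    coords = np.argwhere(ptv)
    centre = coords[rng.integers(len(coords))]
    amp = float(rng.uniform(0.09, 0.11))
    sx, sy, sz = spec.spacing_mm
    dx = (np.arange(spec.grid_shape[0]) - centre[0]) * sx
    dy = (np.arange(spec.grid_shape[1]) - centre[1]) * sy
    dz = (np.arange(spec.grid_shape[2]) - centre[2]) * sz
    r2 = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    dose = dose + rx * amp * np.exp(-r2 / (2.0 * 15.0**2))
    return dose.astype(np.float32)


def _grf(spec: CohortSpec, region: np.ndarray, ell: float,
         rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(spec.grid_shape)
    sig_vox = [max(ell / s, 1e-6) for s in spec.spacing_mm]
    g = ndimage.gaussian_filter(white, sigma=sig_vox)
    sd = g[region].std()
    return g / (sd if sd > 0 else 1.0)


def _texture_image(
    spec: CohortSpec, body: np.ndarray, skin: np.ndarray, breast: np.ndarray,
    label: int, rng: np.random.Generator
) -> np.ndarray:
    """Soft-tissue HU with class-conditional correlated texture.

    The breast/PTV tissue and the skin shell carry *independent* random
    fields whose per-patient amplitude and correlation length are both
    class-conditional, emulating region-specific tissue heterogeneity: the
    two ROI families are correlated with the outcome but not redundant with
    each other. The remaining body tissue gets a label-independent field.
    """
    cls_sigma = (1.0 + spec.effect_size_delta) ** label
    cls_ell = (1.0 + spec.effect_size_delta / 2.0) ** label

    img = np.full(spec.grid_shape, -1000.0, dtype=np.float32)
    img[body] = spec.base_hu + spec.white_noise_hu * rng.standard_normal(int(body.sum()))

    rest = body & ~skin & ~breast
    for region in (breast & ~skin, skin, rest):
        informative = region is not rest
        sigma = spec.texture_sigma_hu
        ell = spec.texture_corr_mm
        if informative:
            sigma *= cls_sigma * float(np.exp(rng.normal(0.0, spec.patient_log_sd)))
            ell *= cls_ell * float(np.exp(rng.normal(0.0, spec.patient_log_sd * 0.6)))
        else:
            sigma *= float(np.exp(rng.normal(0.0, spec.patient_log_sd)))
        if region.any():
            g = _grf(spec, region, ell, rng)
            img[region] += sigma * g[region]
    return img


def _sample_clinical(
    spec: CohortSpec, label: int, rng: np.random.Generator
) -> dict:
    row: dict = {}
    w0, w1 = 70.0, 144.0  # published class sizes used as pooling weights
    tilt = spec.clinical_label_log_odds if label == 1 else 0.0
    for name, m in spec.marginals.items():
        if m["kind"] == "continuous":
            mu0, sd0 = m["c0"]
            mu1, sd1 = m["c1"]
            comp = rng.random() < w1 / (w0 + w1)
            mu, sd = (mu1, sd1) if comp else (mu0, sd0)
            v = float(rng.normal(mu, sd))
            if "min" in m:
                v = max(v, m["min"])
            if "max" in m:
                v = min(v, m["max"])
            row[name] = round(v, 3)
        else:
            counts = np.asarray(m["c0"], float) + np.asarray(m["c1"], float)
            p = counts / counts.sum()
            if tilt and name in _ASSOCIATION_SCORES:
                scores = np.array([_ASSOCIATION_SCORES[name][lv] for lv in m["levels"]])
                p = p * np.exp(tilt * scores)
                p = p / p.sum()
            row[name] = m["levels"][int(rng.choice(len(p), p=p))]
    return row


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate the full synthetic cohort, deterministic under ``spec.seed``."""
    body, skin, ptv, breast = _phantom_masks(spec)
    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[label_rng.permutation(spec.n_patients)[: spec.n_rd2plus]] = 1

    patients: list[SyntheticPatient] = []
    for i, child in enumerate(root.spawn(spec.n_patients + 1)[1:]):
        rng = np.random.default_rng(child)
        label = int(labels[i])
        img = _texture_image(spec, body, skin, breast, label, rng)
        dose = _dose_field(spec, ptv, rng)
        clinical = _sample_clinical(spec, label, rng)
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i:04d}",
                image=ImageVolume(img, spec.spacing_mm),
                dose=DoseGrid(dose, spec.spacing_mm),
                ptv_mask=RoiMask("PTV", ptv.copy()),
                skin_mask=RoiMask("SKIN", skin.copy()),
                clinical=clinical,
                label=label,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# I/O


def _affine(vol: ImageVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def _write_volume(arr: np.ndarray, vol: ImageVolume, path: Path, fmt: str) -> None:
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(arr), _affine(vol)), str(path))
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown volume format {fmt!r}")


def _read_volume(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        aff = img.affine
        spacing = tuple(float(np.abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return arr, spacing, origin
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_patient(patient: SyntheticPatient, out_dir: str | Path, fmt: str = "nifti") -> dict:
    """Write one patient's volumes plus a clinical CSV row and manifest entry.

    Returns the manifest record. Volumes go to ``<dir>/<pid>/`` as
    ``image``, ``dose``, ``ptv_mask`` and ``skin_mask``.
    """
    out_dir = Path(out_dir)
    pdir = out_dir / patient.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if fmt == "nifti" else ".nrrd"
    files = {}
    for name, arr, vol in (
        ("image", patient.image.array.astype(np.float32), patient.image),
        ("dose", patient.dose.array.astype(np.float32), patient.dose),
        ("ptv_mask", patient.ptv_mask.mask.astype(np.uint8), patient.image),
        ("skin_mask", patient.skin_mask.mask.astype(np.uint8), patient.image),
    ):
        path = pdir / f"{name}{ext}"
        _write_volume(arr, vol, path, fmt)
        files[name] = str(path.relative_to(out_dir))

    csv_path = out_dir / "clinical.csv"
    row = {"patient_id": patient.patient_id, **patient.clinical, "RD2plus": patient.label}
    header = not csv_path.exists()
    pd.DataFrame([row]).to_csv(csv_path, mode="a", header=header, index=False)

    manifest_path = out_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {"patients": []}
    record = {"patient_id": patient.patient_id, "files": files, "label": patient.label}
    manifest["patients"] = [
        r for r in manifest["patients"] if r["patient_id"] != patient.patient_id
    ] + [record]
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return record


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path,
                 fmt: str = "nifti", seed: int | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pth in (out_dir / "clinical.csv", out_dir / "manifest.json"):
        if pth.exists():
            pth.unlink()
    for p in patients:
        write_patient(p, out_dir, fmt=fmt)
    if seed is not None:
        manifest_path = out_dir / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["seed"] = seed
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return out_dir


def read_patient(out_dir: str | Path, patient_id: str) -> SyntheticPatient:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    record = next(r for r in manifest["patients"] if r["patient_id"] == patient_id)
    arrays = {}
    spacing = origin = None
    for name, rel in record["files"].items():
        arr, spacing, origin = _read_volume(out_dir / rel)
        arrays[name] = arr
    clin = pd.read_csv(out_dir / "clinical.csv")
    row = clin[clin["patient_id"] == patient_id].iloc[0].to_dict()
    label = int(row.pop("RD2plus"))
    row.pop("patient_id")
    return SyntheticPatient(
        patient_id=patient_id,
        image=ImageVolume(arrays["image"], spacing, origin),
        dose=DoseGrid(arrays["dose"], spacing, origin),
        ptv_mask=RoiMask("PTV", arrays["ptv_mask"] > 0),
        skin_mask=RoiMask("SKIN", arrays["skin_mask"] > 0),
        clinical=row,
        label=label,
    )


def inject_missingness(
    table: pd.DataFrame,
    fraction: float,
    mechanism: str = "MCAR",
    seed: int = 0,
    mar_driver: str = "BMI",
) -> pd.DataFrame:
    """Blank cells completely at random (MCAR) or at a rate driven by an
    observed covariate's tertile (MAR). The driver column itself is never
    blanked under MAR, so missingness depends only on observed data."""
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")
    out = table.copy()
    if fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = [c for c in out.columns if c not in ("patient_id", "RD2plus")]
    if mechanism == "MAR":
        cols = [c for c in cols if c != mar_driver]
    n_rows = len(out)
    n_cells = n_rows * len(cols)
    n_null = int(round(fraction * n_cells))

    if mechanism == "MCAR":
        flat = rng.choice(n_cells, size=n_null, replace=False)
    else:
        driver = pd.to_numeric(out[mar_driver], errors="coerce")
        tert = driver.rank(pct=True).to_numpy()
        row_w = np.where(tert < 1 / 3, 0.5, np.where(tert < 2 / 3, 1.0, 1.5))
        cell_w = np.repeat(row_w, len(cols))
        cell_w = cell_w / cell_w.sum()
        flat = rng.choice(n_cells, size=n_null, replace=False, p=cell_w)
    rows, col_idx = np.divmod(flat, len(cols))
    for r, c in zip(rows, col_idx):
        out.iloc[int(r), out.columns.get_loc(cols[int(c)])] = np.nan
    return out
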