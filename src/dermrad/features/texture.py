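"""2.5D texture matrices: GLCM, GLRLM and NGTDM.

"2.5D" means co-occurrences, runs and neighbourhoods are evaluated within
axial slices only (the z axis is the slice axis) and the per-slice counts
are accumulated into one matrix before any statistic is computed. Inputs are
integer gray-level volumes from :func:`dermrad.features.intensity.discretize`
(levels 1..G inside the mask, anything outside ignored).

All statistics return NaN when the matrix cannot be formed (no valid voxel
pairs / runs / neighbourhoods).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GLCM_STATS",
    "GLRLM_STATS",
    "NGTDM_STATS",
    "glcm_matrix_25d",
    "glcm_features_25d",
    "glrlm_matrix_25d",
    "glrlm_features_25d",
    "ngtdm_tables_25d",
    "ngtdm_features_25d",
]

GLCM_STATS = (
    "AutoCorrelation", "Contrast", "Corr", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Dissimilarity", "Energy", "Entropy", "Homogeneity1",
    "Homogeneity2", "IMC1", "IMC2", "IDMN", "IV", "MaxProbability",
    "SumAverage", "SumEntropy", "SumVariance", "DifferenceEntropy",
    "DifferenceVariance", "Variance",
)

GLRLM_STATS = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)

NGTDM_STATS = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

# In-plane unit steps per direction (degrees); the 2.5D matrices are
# symmetric, so theta and theta+180 produce identical features.
_STEPS = {
    0: (1, 0), 45: (1, 1), 90: (0, 1), 135: (-1, 1),
    180: (-1, 0), 225: (-1, -1), 270: (0, -1), 315: (1, -1),
}


def _pair_indices(levels: np.ndarray, valid: np.ndarray, dx: int, dy: int):
    nx, ny = levels.shape[:2]
    if abs(dx) >= nx or abs(dy) >= ny:
        return None, None
    a = (slice(max(0, -dx), nx - max(0, dx)),
         slice(max(0, -dy), ny - max(0, dy)), slice(None))
    b = (slice(max(0, dx), nx - max(0, -dx)),
         slice(max(0, dy), ny - max(0, -dy)), slice(None))
    both = valid[a] & valid[b]
    return levels[a][both], levels[b][both]


def glcm_matrix_25d(
    levels: np.ndarray, mask: np.ndarray, direction_deg: int, offset: int, n_levels: int
) -> np.ndarray | None:
    """Symmetrised, normalised co-occurrence matrix accumulated over slices.

    Returns None if the (direction, offset) pair produces no voxel pairs.
    """
    if direction_deg not in _STEPS:
        raise ValueError(f"unsupported GLCM direction {direction_deg}")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    ux, uy = _STEPS[direction_deg]
    ia, ib = _pair_indices(levels, np.asarray(mask, bool), ux * offset, uy * offset)
    if ia is None or ia.size == 0:
        return None
    counts = np.bincount((ia - 1) * n_levels + (ib - 1), minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(float)
    mat = mat + mat.T  # symmetrise
    return mat / mat.sum()


def _nan_stats(names) -> dict:
    return {name: float("nan") for name in names}


def glcm_features_25d(
    levels: np.ndarray, mask: np.ndarray, direction_deg: int, offset: int, n_levels: int
) -> dict:
    """The 22 co-occurrence statistics for one (direction, offset) pair."""
    P = glcm_matrix_25d(levels, mask, direction_deg, offset, n_levels)
    if P is None:
        return _nan_stats(GLCM_STATS)
    G = n_levels
    i = np.arange(1, G + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float(i @ px)
    sig_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    # symmetric matrix: marginals coincide
    mu_y, sig_y, py = mu_x, sig_x, px

    nz = P > 0
    logP = np.zeros_like(P)
    logP[nz] = np.log2(P[nz])
    entropy = float(-(P[nz] * logP[nz]).sum())

    pxy = np.outer(px, py)
    nz_m = (pxy > 0) & nz
    hxy1 = float(-(P[nz_m] * np.log2(pxy[nz_m])).sum())
    nz_o = pxy > 0
    hxy2 = float(-(pxy[nz_o] * np.log2(pxy[nz_o])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())

    diff = I - J
    absdiff = np.abs(diff)
    autocorr = float((I * J * P).sum())

    # sum / difference distributions
    p_sum = np.bincount((I + J).ravel(), weights=P.ravel(), minlength=2 * G + 1)[2:]
    k_sum = np.arange(2, 2 * G + 1)
    p_dif = np.bincount(absdiff.ravel(), weights=P.ravel(), minlength=G)
    k_dif = np.arange(G)
    sa = float(k_sum @ p_sum)
    nz_s = p_sum > 0
    nz_d = p_dif > 0
    mu_d = float(k_dif @ p_dif)

    off_diag = absdiff > 0
    denom_hxy = max(hx, hx)  # HX == HY by symmetry
    corr = float((autocorr - mu_x * mu_y) / (sig_x * sig_y)) if sig_x * sig_y > 0 else 0.0

    return {
        "AutoCorrelation": autocorr,
        "Contrast": float((diff**2 * P).sum()),
        "Corr": corr,
        "ClusterProminence": float(((I + J - mu_x - mu_y) ** 4 * P).sum()),
        "ClusterShade": float(((I + J - mu_x - mu_y) ** 3 * P).sum()),
        "ClusterTendency": float(((I + J - mu_x - mu_y) ** 2 * P).sum()),
        "Dissimilarity": float((absdiff * P).sum()),
        "Energy": float((P**2).sum()),
        "Entropy": entropy,
        "Homogeneity1": float((P / (1.0 + absdiff)).sum()),
        "Homogeneity2": float((P / (1.0 + diff**2)).sum()),
        "IMC1": float((entropy - hxy1) / denom_hxy) if denom_hxy > 0 else 0.0,
        "IMC2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))),
        "IDMN": float((P / (1.0 + diff**2 / G**2)).sum()),
        "IV": float((P[off_diag] / diff[off_diag] ** 2).sum()),
        "MaxProbability": float(P.max()),
        "SumAverage": sa,
        "SumEntropy": float(-(p_sum[nz_s] * np.log2(p_sum[nz_s])).sum()),
        "SumVariance": float(((k_sum - sa) ** 2) @ p_sum),
        "DifferenceEntropy": float(-(p_dif[nz_d] * np.log2(p_dif[nz_d])).sum()),
        "DifferenceVariance": float(((k_dif - mu_d) ** 2) @ p_dif),
        "Variance": float(((I - mu_x) ** 2 * P).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM


def _shear(levels_masked: np.ndarray, anti: bool) -> np.ndarray:
    """Shear each axial slice so that 45deg (or 135deg) lines become columns
    traversed along axis 0."""
    nx, ny, nz = levels_masked.shape
    out = np.zeros((nx, ny + nx - 1, nz), dtype=levels_masked.dtype)
    for r in range(nx):
        col = (nx - 1 - r) if not anti else r
        out[r, col:col + ny, :] = levels_masked[r, :, :]
    return out


def _run_counts(lines: np.ndarray, n_levels: int) -> np.ndarray | None:
    """Run-length counts R[level, length-1] from an array whose last axis is
    the run axis; zeros (out-of-mask) break runs."""
    L = lines.shape[-1]
    flat = np.concatenate(
        [lines.reshape(-1, L), np.zeros((lines.size // L, 1), dtype=lines.dtype)], axis=1
    ).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    values = flat[starts]
    keep = values >= 1
    values, lengths = values[keep], lengths[keep]
    if values.size == 0:
        return None
    max_len = int(lengths.max())
    counts = np.bincount(
        (values - 1) * max_len + (lengths - 1), minlength=n_levels * max_len
    )
    return counts.reshape(n_levels, max_len).astype(float)


def glrlm_matrix_25d(
    levels: np.ndarray, mask: np.ndarray, direction_deg: int, n_levels: int
) -> np.ndarray | None:
    """Accumulated run-length matrix over axial slices along one direction."""
    lm = np.where(np.asarray(mask, bool), levels, 0).astype(np.int64)
    if direction_deg == 0:
        lines = np.moveaxis(lm, 0, -1)
    elif direction_deg == 90:
        lines = np.moveaxis(lm, 1, -1)
    elif direction_deg == 45:
        lines = np.moveaxis(_shear(lm, anti=False), 0, -1)
    elif direction_deg == 135:
        lines = np.moveaxis(_shear(lm, anti=True), 0, -1)
    else:
        raise ValueError(f"unsupported GLRLM direction {direction_deg}")
    return _run_counts(np.ascontiguousarray(lines), n_levels)


def glrlm_features_25d(
    levels: np.ndarray, mask: np.ndarray, direction_deg: int, n_levels: int
) -> dict:
    """The 11 run-length statistics for one in-plane direction."""
    R = glrlm_matrix_25d(levels, mask, direction_deg, n_levels)
    if R is None:
        return _nan_stats(GLRLM_STATS)
    G, Lmax = R.shape
    i = np.arange(1, G + 1)[:, None].astype(float)
    j = np.arange(1, Lmax + 1)[None, :].astype(float)
    nr = R.sum()
    np_vox = float((R * j).sum())
    return {
        "SRE": float((R / j**2).sum() / nr),
        "LRE": float((R * j**2).sum() / nr),
        "GLN": float((R.sum(axis=1) ** 2).sum() / nr),
        "RLN": float((R.sum(axis=0) ** 2).sum() / nr),
        "RP": float(nr / np_vox),
        "LGRE": float((R / i**2).sum() / nr),
        "HGRE": float((R * i**2).sum() / nr),
        "SRLGE": float((R / (i**2 * j**2)).sum() / nr),
        "SRHGE": float((R * i**2 / j**2).sum() / nr),
        "LRLGE": float((R * j**2 / i**2).sum() / nr),
        "LRHGE": float((R * i**2 * j**2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_tables_25d(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray, int] | None:
    """Amadasun-King s(i) and count n(i) tables from in-slice 8-neighbourhoods.

    A voxel contributes only if it has at least one in-mask neighbour in its
    own slice; the neighbourhood average excludes the centre voxel.
    """
    m = np.asarray(mask, bool)
    lv = np.where(m, levels, 0).astype(float)
    nb_sum = np.zeros_like(lv)
    nb_cnt = np.zeros_like(lv)
    nx, ny, _ = lv.shape
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            a = (slice(max(0, -dx), nx - max(0, dx)),
                 slice(max(0, -dy), ny - max(0, dy)), slice(None))
            b = (slice(max(0, dx), nx - max(0, -dx)),
                 slice(max(0, dy), ny - max(0, -dy)), slice(None))
            nb_sum[a] += lv[b] * m[b]
            nb_cnt[a] += m[b]
    valid = m & (nb_cnt > 0)
    if not valid.any():
        return None
    centre = levels[valid].astype(float)
    avg = nb_sum[valid] / nb_cnt[valid]
    dev = np.abs(centre - avg)
    idx = levels[valid].astype(int) - 1
    s = np.bincount(idx, weights=dev, minlength=n_levels)
    n = np.bincount(idx, minlength=n_levels).astype(float)
    return s, n, int(valid.sum())


#: Sentinel cap for coarseness of perfectly homogeneous regions (1/0 guard).
COARSENESS_CAP = 1e6


def ngtdm_features_25d(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    """The 5 neighbourhood gray-tone difference statistics."""
    tables = ngtdm_tables_25d(levels, mask, n_levels)
    if tables is None:
        return _nan_stats(NGTDM_STATS)
    s, n, n_valid = tables
    p = n / n_valid
    present = p > 0
    gl = np.arange(1, n_levels + 1, dtype=float)
    ng = int(present.sum())

    ps = float(p @ s)
    coarseness = min(1.0 / ps, COARSENESS_CAP) if ps > 0 else COARSENESS_CAP

    if ng > 1:
        ii = gl[present]
        pi = p[present]
        si = s[present]
        dif2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dif2).sum() / (ng * (ng - 1)) * s.sum() / n_valid
        )
        ipi = ii * pi
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        absdif = np.abs(ii[:, None] - ii[None, :])
        psum = pi[:, None] + pi[None, :]
        complexity = float(
            (absdif * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / psum).sum()
            / n_valid
        )
        s_tot = float(s.sum())
        strength = float((psum * dif2).sum() / s_tot) if s_tot > 0 else 0.0
    else:
        contrast = busyness = strength = 0.0
        complexity = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": strength,
    }
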