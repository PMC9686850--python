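"""Texture-matrix families against brute-force enumeration oracles."""

import numpy as np
import pytest

from dermrad.features.texture import (
    COARSENESS_CAP,
    glcm_features_25d,
    glcm_matrix_25d,
    glrlm_matrix_25d,
    glrlm_features_25d,
    ngtdm_features_25d,
    ngtdm_tables_25d,
)

_STEPS = {0: (1, 0), 45: (1, 1), 90: (0, 1), 135: (-1, 1)}


def brute_glcm(levels, mask, direction, offset, G):
    """Naive per-slice pair enumeration, symmetrised and normalised."""
    ux, uy = _STEPS[direction % 180]
    dx, dy = ux * offset, uy * offset
    mat = np.zeros((G, G))
    nx, ny, nz = levels.shape
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                if not mask[x, y, z]:
                    continue
                x2, y2 = x + dx, y + dy
                if 0 <= x2 < nx and 0 <= y2 < ny and mask[x2, y2, z]:
                    i, j = levels[x, y, z] - 1, levels[x2, y2, z] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1
    return mat / mat.sum() if mat.sum() else None


def brute_glrlm(levels, mask, direction, G):
    """Naive run listing per slice line; masked-out voxels break runs."""
    runs = []
    nx, ny, nz = levels.shape
    lm = np.where(mask, levels, 0)
    for z in range(nz):
        sl = lm[:, :, z]
        lines = []
        if direction == 0:
            lines = [sl[:, y] for y in range(ny)]
        elif direction == 90:
            lines = [sl[x, :] for x in range(nx)]
        elif direction == 45:
            # step (+1,+1): lines of constant x - y
            lines = [np.diagonal(sl, off).copy() for off in range(-nx + 1, ny)]
        elif direction == 135:
            # step (-1,+1): lines of constant x + y
            lines = [np.diagonal(sl[::-1], off).copy() for off in range(-nx + 1, ny)]
        for line in lines:
            i = 0
            while i < len(line):
                if line[i] == 0:
                    i += 1
                    continue
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                runs.append((line[i], j - i))
                i = j
    if not runs:
        return None
    max_len = max(l for _, l in runs)
    R = np.zeros((G, max_len))
    for v, l in runs:
        R[v - 1, l - 1] += 1
    return R


def brute_ngtdm(levels, mask, G):
    """Naive per-voxel in-slice 8-neighbourhood tables."""
    nx, ny, nz = levels.shape
    s = np.zeros(G)
    n = np.zeros(G)
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                if not mask[x, y, z]:
                    continue
                nb = [levels[x + dx, y + dy, z]
                      for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                      if (dx, dy) != (0, 0)
                      and 0 <= x + dx < nx and 0 <= y + dy < ny
                      and mask[x + dx, y + dy, z]]
                if not nb:
                    continue
                lv = levels[x, y, z]
                s[lv - 1] += abs(lv - np.mean(nb))
                n[lv - 1] += 1
    total = int(n.sum())
    return (s, n, total) if total else None


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    G = 6
    levels = rng.integers(1, G + 1, size=(8, 8, 3))
    mask = rng.random((8, 8, 3)) > 0.25
    return levels, mask, G


# ---------------------------------------------------------------------- GLCM

@pytest.mark.parametrize("direction", [0, 45, 90, 135])
@pytest.mark.parametrize("offset", [1, 2, 4])
def test_glcm_matrix_matches_brute_force(toy, direction, offset):
    levels, mask, G = toy
    fast = glcm_matrix_25d(levels, mask, direction, offset, G)
    slow = brute_glcm(levels, mask, direction, offset, G)
    np.testing.assert_array_equal(fast, slow)


def test_glcm_constant_roi():
    levels = np.ones((4, 4, 2), int)
    mask = np.ones((4, 4, 2), bool)
    f = glcm_features_25d(levels, mask, 0, 1, 8)
    assert f["Contrast"] == 0.0
    assert f["Energy"] == 1.0
    assert f["Dissimilarity"] == 0.0


def test_glcm_checkerboard_contrast_one():
    # alternating levels 1/2: every horizontal neighbour pair differs by 1
    x, y = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
    levels = ((x + y) % 2 + 1)[:, :, None]
    mask = np.ones(levels.shape, bool)
    f = glcm_features_25d(levels, mask, 0, 1, 2)
    assert f["Contrast"] == pytest.approx(1.0)


def test_glcm_opposite_directions_identical(toy):
    levels, mask, G = toy
    a = glcm_features_25d(levels, mask, 45, 2, G)
    b = glcm_features_25d(levels, mask, 225 % 180, 2, G)
    assert a == b


def test_glcm_offset_beyond_extent_gives_nulls():
    levels = np.ones((3, 3, 1), int)
    mask = np.ones((3, 3, 1), bool)
    f = glcm_features_25d(levels, mask, 0, 5, 4)
    assert all(np.isnan(v) for v in f.values())


def test_glcm_hand_enumerated_2x2():
    # slice [[1,2],[1,1]], direction 0 (x axis), offset 1:
    # pairs (1,1),(2,1) -> symmetrised counts {(1,1):2,(1,2):1,(2,1):1}
    levels = np.array([[1, 2], [1, 1]])[:, :, None]
    mask = np.ones(levels.shape, bool)
    P = glcm_matrix_25d(levels, mask, 0, 1, 2)
    np.testing.assert_allclose(P, np.array([[0.5, 0.25], [0.25, 0.0]]))


# --------------------------------------------------------------------- GLRLM

@pytest.mark.parametrize("direction", [0, 45, 90, 135])
def test_glrlm_matrix_matches_brute_force(toy, direction):
    levels, mask, G = toy
    fast = glrlm_matrix_25d(levels, mask, direction, G)
    slow = brute_glrlm(levels, mask, direction, G)
    np.testing.assert_array_equal(fast, slow)


def test_glrlm_constant_row_single_run():
    n = 7
    levels = np.full((n, 1, 1), 3)
    mask = np.ones(levels.shape, bool)
    f = glrlm_features_25d(levels, mask, 0, 4)
    assert f["RP"] == pytest.approx(1.0 / n)
    R = glrlm_matrix_25d(levels, mask, 0, 4)
    assert R[2, n - 1] == 1 and R.sum() == 1


def test_glrlm_alternating_row_sre_one():
    levels = np.array([1, 2, 1, 2, 1, 2]).reshape(-1, 1, 1)
    mask = np.ones(levels.shape, bool)
    f = glrlm_features_25d(levels, mask, 0, 2)
    assert f["SRE"] == pytest.approx(1.0)


def test_glrlm_5x5_hand_enumeration():
    sl = np.array([
        [1, 1, 2, 2, 2],
        [1, 3, 3, 1, 1],
        [2, 2, 2, 2, 1],
        [3, 3, 1, 1, 1],
        [1, 2, 1, 2, 1],
    ])
    levels = sl[:, :, None]
    mask = np.ones(levels.shape, bool)
    # direction 90 = along y (rows as written): hand-listed runs per row
    R = glrlm_matrix_25d(levels, mask, 90, 3)
    expected = np.zeros((3, 4))
    hand_runs = [(1, 2), (2, 3), (1, 1), (3, 2), (1, 2), (2, 4), (1, 1),
                 (3, 2), (1, 3), (1, 1), (2, 1), (1, 1), (2, 1), (1, 1)]
    for v, l in hand_runs:
        expected[v - 1, l - 1] += 1
    np.testing.assert_array_equal(R, expected)


# --------------------------------------------------------------------- NGTDM

def test_ngtdm_matches_brute_force(toy):
    levels, mask, G = toy
    s, n, tot = ngtdm_tables_25d(levels, mask, G)
    s2, n2, tot2 = brute_ngtdm(levels, mask, G)
    np.testing.assert_allclose(s, s2, atol=1e-9)
    np.testing.assert_array_equal(n, n2)
    assert tot == tot2


def test_ngtdm_constant_region():
    levels = np.ones((5, 5, 2), int)
    mask = np.ones(levels.shape, bool)
    f = ngtdm_features_25d(levels, mask, 4)
    assert f["Contrast"] == 0.0
    assert f["Coarseness"] == COARSENESS_CAP


def test_ngtdm_single_bright_centre():
    levels = np.ones((3, 3, 1), int)
    levels[1, 1, 0] = 5
    mask = np.ones(levels.shape, bool)
    s, n, tot = ngtdm_tables_25d(levels, mask, 5)
    # centre: 8 neighbours all level 1 -> s(5) = |5 - 1| = 4
    assert s[4] == pytest.approx(4.0)
    # corner voxel: neighbours {1,1,5} -> |1 - 7/3|; edge: {1,1,1,1,5} -> |1-9/5|
    corner = abs(1 - 7 / 3)
    edge = abs(1 - 9 / 5)
    assert s[0] == pytest.approx(4 * corner + 4 * edge)


def test_ngtdm_identity_relabel_invariance(toy):
    levels, mask, G = toy
    a = ngtdm_features_25d(levels, mask, G)
    b = ngtdm_features_25d(levels.copy(), mask.copy(), G)
    assert a == b
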