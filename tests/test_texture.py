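"""GLCM construction and Haralick-style statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from blastograde import texture as tex
from blastograde.errors import EmptyRegionError


def brute_force_glcm(quantized, mask, d=1, angles=tex.DEFAULT_ANGLES):
    """Exhaustive pair enumeration over all pixels and angles."""
    counts = np.zeros((8, 8))
    rows, cols = quantized.shape
    for angle in angles:
        dr, dc = tex.ANGLE_OFFSETS[angle]
        dr, dc = dr * d, dc * d
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                    counts[quantized[r, c], quantized[r2, c2]] += 1
                    counts[quantized[r2, c2], quantized[r, c]] += 1
    return counts / counts.sum()


def brute_force_stats(p):
    contrast = energy = homog = num = 0.0
    mu_i = sum(i * p[i, j] for i in range(8) for j in range(8))
    mu_j = sum(j * p[i, j] for i in range(8) for j in range(8))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(8) for j in range(8))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(8) for j in range(8))
    for i in range(8):
        for j in range(8):
            contrast += (i - j) ** 2 * p[i, j]
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
            num += (i - mu_i) * (j - mu_j) * p[i, j]
    corr = 1.0 if var_i * var_j == 0 else num / np.sqrt(var_i * var_j)
    return contrast, corr, energy, homog


@pytest.mark.parametrize("value,level", [(0, 0), (31, 0), (32, 1), (100, 3), (255, 7)])
def test_quantization_bins(value, level):
    raster = np.full((2, 2), value, dtype=np.uint8)
    assert tex.quantize8(raster, np.ones((2, 2), bool))[0, 0] == level


def test_quantize_empty_mask_rejected():
    with pytest.raises(EmptyRegionError):
        tex.quantize8(np.zeros((2, 2), np.uint8), np.zeros((2, 2), bool))


def test_horizontal_pair_example():
    q = np.array([[1, 1], [1, 3]], dtype=np.uint8)
    glcm = tex.compute_glcm(q, np.ones((2, 2), bool), d=1, angles=(0,))
    assert glcm.P[1, 1] == pytest.approx(0.5)
    assert glcm.P[1, 3] == pytest.approx(0.25)
    assert glcm.P[3, 1] == pytest.approx(0.25)
    stats = tex.texture_stats(glcm)
    assert stats.contrast == pytest.approx(2.0)
    assert stats.energy == pytest.approx(0.375)
    assert stats.homogeneity == pytest.approx(2.0 / 3.0)


def test_constant_region_degenerate_stats():
    q = np.full((5, 5), 4, dtype=np.uint8)
    glcm = tex.compute_glcm(q, np.ones((5, 5), bool))
    assert glcm.P[4, 4] == pytest.approx(1.0)
    stats = tex.texture_stats(glcm)
    assert (stats.contrast, stats.energy, stats.homogeneity) == (0.0, 1.0, 1.0)
    assert stats.correlation == 1.0  # degenerate-variance convention


def test_mask_with_no_valid_pair_rejected():
    mask = np.zeros((4, 4), bool)
    mask[0, 0] = mask[3, 3] = True  # no neighbouring pair at d=1
    with pytest.raises(EmptyRegionError):
        tex.compute_glcm(np.zeros((4, 4), np.uint8), mask, d=1, angles=(0,))


@given(st.integers(0, 10_000))
def test_glcm_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    q = rng.integers(0, 8, size=(9, 9)).astype(np.uint8)
    mask = rng.random((9, 9)) < 0.7
    if not mask.any():
        mask[0, 0] = mask[0, 1] = True
    try:
        glcm = tex.compute_glcm(q, mask)
    except EmptyRegionError:
        return
    np.testing.assert_array_equal(glcm.P, brute_force_glcm(q, mask))
    assert glcm.P.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(glcm.P, glcm.P.T)
    stats = tex.texture_stats(glcm)
    expect = brute_force_stats(glcm.P)
    np.testing.assert_allclose(
        [stats.contrast, stats.correlation, stats.energy, stats.homogeneity],
        expect, atol=1e-10)


def test_angle_averaged_stats_invariant_under_rot90():
    rng = np.random.default_rng(4)
    raster = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    mask = rng.random((16, 16)) < 0.8
    a = tex.region_texture(raster, mask)
    b = tex.region_texture(np.rot90(raster).copy(), np.rot90(mask).copy())
    for fieldname in ("contrast", "correlation", "energy", "homogeneity"):
        assert getattr(a, fieldname) == pytest.approx(getattr(b, fieldname), abs=1e-12)


def test_homogeneity_one_iff_diagonal():
    q = np.repeat(np.arange(8, dtype=np.uint8), 4).reshape(8, 4)
    # vertical neighbours differ -> off-diagonal mass -> homogeneity < 1
    glcm = tex.compute_glcm(q, np.ones_like(q, bool), angles=(90,))
    assert tex.texture_stats(glcm).homogeneity < 1
    # horizontal neighbours equal -> purely diagonal -> homogeneity == 1
    glcm = tex.compute_glcm(q, np.ones_like(q, bool), angles=(0,))
    assert np.count_nonzero(glcm.P - np.diag(np.diag(glcm.P))) == 0
    assert tex.texture_stats(glcm).homogeneity == pytest.approx(1.0)
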