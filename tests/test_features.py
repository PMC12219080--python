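"""Quantisation, GLCM/GLRLM builders vs brute-force oracles, descriptors."""

import numpy as np
import pytest

from mammocad.features import (DIRECTIONS, FeatureVector, assemble_hybrid,
                               compute_glcm, compute_glrlm, first_order_features,
                               glcm_features, glrlm_features,
                               hybrid_feature_names, quantize)
from mammocad.io_formats import GrayImage
from mammocad.segmentation import BinaryMask, RoiBox

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(levels, Ng, direction, symmetric):
    """Double-loop pair counting oracle."""
    dr, dc = OFFSETS[direction]
    h, w = levels.shape
    counts = np.zeros((Ng, Ng))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w:
                counts[levels[i, j] - 1, levels[i2, j2] - 1] += 1
                if symmetric:
                    counts[levels[i2, j2] - 1, levels[i, j] - 1] += 1
    return counts / counts.sum()


def brute_glrlm(levels, Ng, direction):
    """Line-walking run counter oracle."""
    h, w = levels.shape
    if direction == 0:
        lines = [levels[i, :] for i in range(h)]
    elif direction == 90:
        lines = [levels[:, j] for j in range(w)]
    elif direction == 135:
        lines = [np.diagonal(levels, k) for k in range(-(h - 1), w)]
    else:  # 45: walk up-right
        flipped = levels[::-1]
        lines = [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    lmax = {0: w, 90: h}.get(direction, min(h, w))
    R = np.zeros((Ng, lmax), dtype=int)
    for line in lines:
        run_val, run_len = None, 0
        for v in list(line) + [None]:
            if v == run_val:
                run_len += 1
            else:
                if run_val is not None:
                    R[run_val - 1, run_len - 1] += 1
                run_val, run_len = v, 1
    return R


class TestQuantize:
    def test_full_range_identity_binning(self):
        px = np.arange(256, dtype=np.uint8).reshape(16, 16)
        q = quantize(GrayImage(px), 256)
        assert np.array_equal(q.levels, px.astype(np.int64) + 1)

    def test_constant_maps_to_bin_one(self):
        q = quantize(GrayImage(np.full((4, 4), 77, np.uint8)), 8)
        assert (q.levels == 1).all()

    def test_uniform_range_gives_equal_bins(self):
        px = np.arange(256, dtype=np.uint8).reshape(16, 16)
        q = quantize(GrayImage(px), 4)
        counts = np.bincount(q.levels.reshape(-1), minlength=5)[1:]
        assert counts.tolist() == [64, 64, 64, 64]


class TestGLCM:
    def test_hand_enumerated_row(self):
        from mammocad.features import QuantizedImage

        q = QuantizedImage(np.array([[1, 1, 2, 2]]), 2)
        M = compute_glcm(q, 0, symmetric=False)
        expected = np.array([[1, 1], [0, 1]]) / 3
        assert np.allclose(M.P, expected)

    def test_constant_image_point_mass(self):
        q = quantize(GrayImage(np.full((5, 5), 9, np.uint8)), 4)
        M = compute_glcm(q, 0)
        assert M.P[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    @pytest.mark.parametrize("symmetric", [False, True])
    def test_matches_brute_force_oracle(self, rng, direction, symmetric):
        for _ in range(50):
            levels = rng.integers(1, 5, (8, 8))
            from mammocad.features import QuantizedImage

            q = QuantizedImage(levels, 4)
            M = compute_glcm(q, direction, symmetric)
            assert np.array_equal(M.P, brute_glcm(levels, 4, direction,
                                                  symmetric))
            assert M.P.sum() == pytest.approx(1.0, abs=1e-12)
            if symmetric:
                assert np.array_equal(M.P, M.P.T)

    def test_rotation_maps_0_to_90(self, rng):
        from mammocad.features import QuantizedImage

        levels = rng.integers(1, 5, (8, 8))
        rotated = np.rot90(levels)  # 90 deg counter-clockwise
        a = compute_glcm(QuantizedImage(levels, 4), 0, symmetric=False).P
        b = compute_glcm(QuantizedImage(rotated, 4), 90, symmetric=False).P
        assert np.array_equal(a, b)

    def test_too_small_region_raises(self):
        from mammocad.features import QuantizedImage

        with pytest.raises(ValueError, match="pair"):
            compute_glcm(QuantizedImage(np.array([[1]]), 2), 0)


class TestGlcmFeatures:
    def test_point_mass_degenerate_values(self):
        from mammocad.features import GLCMatrix

        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        with pytest.warns(UserWarning, match="correlation"):
            v = glcm_features(GLCMatrix(P, 0))
        assert v["glcm_energy_d0"] == 1.0
        assert v["glcm_contrast_d0"] == 0.0
        assert v["glcm_entropy_d0"] == 0.0
        assert v["glcm_homogeneity_d0"] == 1.0
        assert v["glcm_shade_d0"] == 0.0

    def test_uniform_2x2_closed_form(self):
        from mammocad.features import GLCMatrix

        P = np.full((2, 2), 0.25)
        v = glcm_features(GLCMatrix(P, 0))
        assert v["glcm_energy_d0"] == pytest.approx(0.25)
        assert v["glcm_entropy_d0"] == pytest.approx(2.0)
        assert v["glcm_contrast_d0"] == pytest.approx(0.5)

    def test_matches_naive_summation_oracle(self, rng):
        from mammocad.features import GLCMatrix

        P = rng.random((6, 6))
        P /= P.sum()
        v = glcm_features(GLCMatrix(P, 45))
        Ng = 6
        energy = sum(P[i, j] ** 2 for i in range(Ng) for j in range(Ng))
        entropy = -sum(P[i, j] * np.log2(P[i, j]) for i in range(Ng)
                       for j in range(Ng) if P[i, j] > 0)
        contrast = sum((i - j) ** 2 * P[i, j] for i in range(Ng)
                       for j in range(Ng))
        homog = sum(P[i, j] / (1 + abs(i - j)) for i in range(Ng)
                    for j in range(Ng))
        pi = P.sum(axis=1)
        pj = P.sum(axis=0)
        mi = sum((i + 1) * pi[i] for i in range(Ng))
        mj = sum((j + 1) * pj[j] for j in range(Ng))
        si = np.sqrt(sum((i + 1 - mi) ** 2 * pi[i] for i in range(Ng)))
        sj = np.sqrt(sum((j + 1 - mj) ** 2 * pj[j] for j in range(Ng)))
        corr = sum((i + 1 - mi) * (j + 1 - mj) * P[i, j] for i in range(Ng)
                   for j in range(Ng)) / (si * sj)
        shade = sum((i + 1 + j + 1 - mi - mj) ** 3 * P[i, j]
                    for i in range(Ng) for j in range(Ng))
        expected = [energy, entropy, contrast, homog, corr, shade]
        assert np.allclose(v.values, expected, atol=1e-12)


class TestGLRLM:
    def test_hand_enumerated_row(self):
        from mammocad.features import QuantizedImage

        q = QuantizedImage(np.array([[5, 5, 5, 2]]), 5)
        R = compute_glrlm(q, 0)
        assert R.Nr == 2
        assert R.R[4, 2] == 1    # level 5, length 3
        assert R.R[1, 0] == 1    # level 2, length 1

    def test_checkerboard_all_runs_length_one(self):
        from mammocad.features import QuantizedImage

        levels = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        q = QuantizedImage(levels, 2)
        R = compute_glrlm(q, 0)
        assert R.Nr == 36
        assert R.R[:, 1:].sum() == 0
        v = glrlm_features(R)
        assert v["glrlm_sre_d0"] == pytest.approx(1.0)
        assert v["glrlm_lre_d0"] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_brute_force_oracle(self, rng, direction):
        from mammocad.features import QuantizedImage

        for _ in range(50):
            levels = rng.integers(1, 5, (8, 8))
            q = QuantizedImage(levels, 4)
            R = compute_glrlm(q, direction)
            assert np.array_equal(R.R, brute_glrlm(levels, 4, direction))
            assert R.Nr == R.R.sum()
            # pixel conservation: every pixel belongs to exactly one run
            j = np.arange(1, R.Lmax + 1)
            assert (R.R * j).sum() == levels.size

    def test_single_run_closed_form(self):
        from mammocad.features import QuantizedImage

        q = QuantizedImage(np.ones((1, 6), dtype=int), 2)
        v = glrlm_features(compute_glrlm(q, 0))
        assert v["glrlm_sre_d0"] == pytest.approx(1 / 36)
        assert v["glrlm_lre_d0"] == pytest.approx(36)
        assert v["glrlm_gln_d0"] == pytest.approx(1.0)
        assert v["glrlm_lgre_d0"] == pytest.approx(1.0)

    def test_glrlm_descriptor_oracle(self, rng):
        from mammocad.features import QuantizedImage

        levels = rng.integers(1, 5, (8, 8))
        q = QuantizedImage(levels, 4)
        R = compute_glrlm(q, 90)
        v = glrlm_features(R)
        nr = R.Nr
        sre = sum(R.R[i, j] / (j + 1) ** 2 for i in range(4)
                  for j in range(R.Lmax)) / nr
        lre = sum(R.R[i, j] * (j + 1) ** 2 for i in range(4)
                  for j in range(R.Lmax)) / nr
        lgre = sum(R.R[i, j] / (i + 1) ** 2 for i in range(4)
                   for j in range(R.Lmax)) / nr
        hgre = sum(R.R[i, j] * (i + 1) ** 2 for i in range(4)
                   for j in range(R.Lmax)) / nr
        gln = sum(R.R[i, :].sum() ** 2 for i in range(4)) / nr
        assert np.allclose(v.values, [sre, lre, lgre, hgre, gln], atol=1e-12)


class TestFirstOrder:
    def test_constant_region(self):
        img = GrayImage(np.full((5, 5), 128, np.uint8))
        with pytest.warns(UserWarning, match="skewness"):
            v = first_order_features(img)
        assert v["fo_mean"] == 128
        assert v["fo_skewness"] == 0
        assert v["fo_entropy"] == 0
        assert v["fo_uniformity"] == 1
        assert v["fo_smoothness"] == 0

    def test_two_valued_closed_form(self):
        px = np.zeros((2, 2), dtype=np.uint8)
        px[0] = 255
        v = first_order_features(GrayImage(px))
        assert v["fo_mean"] == pytest.approx(127.5)
        assert v["fo_entropy"] == pytest.approx(1.0)
        assert v["fo_uniformity"] == pytest.approx(0.5)
        assert v["fo_smoothness"] == pytest.approx(0.2)

    def test_matches_two_pass_oracle(self, rng):
        px = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        v = first_order_features(GrayImage(px))
        vals = px.astype(float).reshape(-1)
        mean = vals.mean()
        sd = vals.std()
        skew = np.mean((vals - mean) ** 3) / sd ** 3
        assert v["fo_mean"] == pytest.approx(mean, abs=1e-10)
        assert v["fo_skewness"] == pytest.approx(skew, abs=1e-10)
        sn2 = (sd / 255) ** 2
        assert v["fo_smoothness"] == pytest.approx(1 - 1 / (1 + sn2), abs=1e-12)

    def test_mask_selection(self, rng):
        px = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        m = np.zeros((8, 8), np.uint8)
        m[:4] = 1
        v = first_order_features(GrayImage(px), BinaryMask(m))
        assert v["fo_mean"] == pytest.approx(px[:4].mean())


class TestAssembleHybrid:
    def test_canonical_49_vector(self, rng):
        img = GrayImage(rng.integers(0, 256, (32, 32)).astype(np.uint8))
        v = assemble_hybrid(img, RoiBox(4, 28, 4, 28), Ng=8)
        assert len(v.values) == 49
        assert v.names == hybrid_feature_names()
        assert not np.isnan(v.values).any()

    def test_deterministic(self, rng):
        img = GrayImage(rng.integers(0, 256, (32, 32)).astype(np.uint8))
        a = assemble_hybrid(img, Ng=8)
        b = assemble_hybrid(img, Ng=8)
        assert np.array_equal(a.values, b.values)

    def test_nan_free_on_generator_output(self):
        from mammocad.synthetic import PhantomParams, generate_phantom

        for label in ("normal", "abnormal"):
            img, _ = generate_phantom(PhantomParams(seed=3), label)
            v = assemble_hybrid(img)
            assert not np.isnan(v.values).any()

    def test_feature_vector_rejects_nan(self):
        with pytest.raises(ValueError, match="NaN"):
            FeatureVector(("a",), np.array([np.nan]))
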