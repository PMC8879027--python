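"""Texture-matrix computations checked against exhaustive brute-force oracles."""

import numpy as np
import pytest

from histotex import (
    ORIENTATIONS,
    CooccurrenceMatrix,
    QuantizedImage,
    compute_glcm,
    compute_glrm,
    quantize,
    render_textural_image,
    texturize_image,
)
from histotex.datasets import LabeledImage

from conftest import random_quantized_images

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels: np.ndarray, G: int, theta: int, d: int = 1) -> np.ndarray:
    """Exhaustive pixel-pair enumeration, one pair at a time."""
    counts = np.zeros((G, G), dtype=int)
    dr, dc = OFFSETS[theta][0] * d, OFFSETS[theta][1] * d
    n, m = levels.shape
    for r in range(n):
        for c in range(m):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n and 0 <= c2 < m:
                counts[levels[r, c], levels[r2, c2]] += 1
    return counts


def glrm_bruteforce(levels: np.ndarray, G: int, theta: int) -> np.ndarray:
    """Independent run scanner: walk each scan line pixel by pixel."""
    n, m = levels.shape
    L = max(n, m)
    Q = np.zeros((G, L), dtype=int)
    if theta == 0:
        lines = [levels[r, :] for r in range(n)]
    elif theta == 90:
        lines = [levels[:, c] for c in range(m)]
    elif theta == 135:
        lines = [np.diagonal(levels, k) for k in range(-(n - 1), m)]
    else:  # 45: anti-diagonals
        lines = [np.diagonal(levels[::-1], k) for k in range(-(n - 1), m)]
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            Q[line[i], j - i] += 1
            i = j + 1
    return Q


class TestQuantize:
    def test_bin_edges_follow_floor_rule(self):
        # G=8 bin width 32: 0 -> 0, 31 -> 0, 32 -> 1, 255 -> 7
        gray = np.array([[0, 31], [32, 255]], dtype=np.uint8)
        img = np.repeat(gray[:, :, None], 3, axis=2)
        q = quantize(img, G=8)
        assert q.levels.tolist() == [[0, 0], [1, 7]]

    def test_constant_white_maps_to_top_bin(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(quantize(img, G=8).levels == 7)

    def test_g256_is_identity_on_grayscale(self, rng):
        gray = rng.integers(0, 256, size=(12, 9)).astype(np.uint8)
        assert np.array_equal(quantize(gray, G=256).levels, gray)

    def test_luminance_weights(self):
        # pure red pixel: 0.299 * 200 = 59.8 -> level floor(59.8 * 8 / 256) = 1
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0, 0] = 200
        assert quantize(img, G=8).levels[0, 0] == 1

    def test_rejects_degenerate_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2, 3), dtype=np.uint8), G=1)

    def test_idempotent_after_rescale(self, rng):
        q = quantize(rng.integers(0, 256, size=(16, 16)).astype(np.uint8), G=8)
        # rescale levels back to [0, 255] bin centers, then quantize again
        rescaled = (q.levels * 32 + 16).astype(np.uint8)
        q2 = quantize(rescaled, G=8)
        assert np.array_equal(q.levels, q2.levels)


class TestGLCM:
    def test_constant_image_counts_only_diagonal(self):
        q = QuantizedImage(levels=np.full((2, 2), 3), G=8)
        m = compute_glcm(q, theta=0, distance=1)
        expected = np.zeros((8, 8), dtype=int)
        expected[3, 3] = 2
        assert np.array_equal(m.counts, expected)

    def test_checkerboard_horizontal_pairs(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        m = compute_glcm(QuantizedImage(levels=board, G=2), theta=0)
        assert m.counts[0, 1] == 6 and m.counts[1, 0] == 6
        assert m.counts[0, 0] == 0 and m.counts[1, 1] == 0

    @pytest.mark.parametrize("theta", ORIENTATIONS)
    def test_normalized_sums_to_one(self, theta, rng):
        q = QuantizedImage(levels=rng.integers(0, 8, size=(10, 14)), G=8)
        m = compute_glcm(q, theta=theta)
        assert m.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("theta", ORIENTATIONS)
    @pytest.mark.parametrize("distance", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, theta, distance):
        for q in random_quantized_images(20, shape=(9, 12), seed=theta * 10 + distance):
            expected = glcm_bruteforce(q.levels, q.G, theta, distance)
            got = compute_glcm(q, theta=theta, distance=distance)
            assert np.array_equal(got.counts, expected)

    def test_matches_scikit_image(self):
        """Independent library cross-check.  scikit-image measures angles in
        image coordinates (row axis down), so its 45/90/135-degree offsets are
        the reversed pairs of ours: equal counts up to a transpose."""
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        angles = {
            0: (0.0, False),
            45: (3 * np.pi / 4, True),
            90: (np.pi / 2, True),
            135: (np.pi / 4, True),
        }
        for q in random_quantized_images(20, shape=(16, 16), seed=99):
            for theta, (ang, transpose) in angles.items():
                ref = graycomatrix(
                    q.levels.astype(np.uint8), [1], [ang], levels=8,
                    symmetric=False, normed=False,
                )[:, :, 0, 0]
                if transpose:
                    ref = ref.T
                assert np.array_equal(compute_glcm(q, theta=theta).counts, ref)

    def test_transpose_relates_0_and_90_degrees(self, rng):
        q = QuantizedImage(levels=rng.integers(0, 8, size=(11, 7)), G=8)
        qt = QuantizedImage(levels=q.levels.T, G=8)
        assert np.array_equal(compute_glcm(qt, 0).counts, compute_glcm(q, 90).counts.T)

    def test_symmetric_accumulation(self, rng):
        q = QuantizedImage(levels=rng.integers(0, 8, size=(8, 8)), G=8)
        asym = compute_glcm(q, 0).counts
        sym = compute_glcm(q, 0, symmetric=True).counts
        assert np.array_equal(sym, asym + asym.T)

    def test_invalid_inputs(self):
        q = QuantizedImage(levels=np.zeros((3, 3), dtype=int), G=4)
        with pytest.raises(ValueError):
            compute_glcm(q, theta=30)
        with pytest.raises(ValueError):
            compute_glcm(q, theta=0, distance=0)
        # a distance with zero valid pairs is an explicit error
        with pytest.raises(ValueError, match="no valid pixel pairs"):
            compute_glcm(q, theta=0, distance=3)


class TestGLRM:
    def test_constant_image_one_run_per_row(self):
        q = QuantizedImage(levels=np.full((3, 5), 6), G=8)
        r = compute_glrm(q, theta=0)
        expected = np.zeros((8, 5), dtype=int)
        expected[6, 4] = 3  # three rows, each a single run of length 5
        assert np.array_equal(r.Q, expected)

    def test_checkerboard_forces_unit_runs(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        r = compute_glrm(QuantizedImage(levels=board, G=2), theta=0)
        assert r.Q[0, 0] == 8 and r.Q[1, 0] == 8
        assert r.Q[:, 1:].sum() == 0

    @pytest.mark.parametrize("theta", ORIENTATIONS)
    def test_pixel_conservation(self, theta):
        for q in random_quantized_images(20, shape=(13, 9), seed=theta):
            r = compute_glrm(q, theta=theta)
            lengths = np.arange(1, r.Q.shape[1] + 1)
            assert int((r.Q * lengths).sum()) == q.levels.size

    @pytest.mark.parametrize("theta", ORIENTATIONS)
    def test_matches_bruteforce_scanner(self, theta):
        for q in random_quantized_images(50, shape=(16, 16), seed=1000 + theta):
            assert np.array_equal(compute_glrm(q, theta).Q, glrm_bruteforce(q.levels, q.G, theta))

    def test_L_is_max_dimension_with_trailing_zeros_kept(self):
        q = QuantizedImage(levels=np.arange(12).reshape(3, 4) % 8, G=8)
        r = compute_glrm(q, theta=0)
        assert r.Q.shape == (8, 4) and r.L == 4


class TestPropertyInvariants:
    """Structure-independent invariants over arbitrary quantized grids."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    grids = arrays(
        np.int64,
        st.tuples(st.integers(2, 12), st.integers(2, 12)),
        elements=st.integers(0, 7),
    )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(levels=grids, theta=st.sampled_from(ORIENTATIONS))
    def test_glcm_total_equals_valid_pair_count(self, levels, theta):
        n, m = levels.shape
        q = QuantizedImage(levels=levels, G=8)
        counts = compute_glcm(q, theta).counts
        expected_pairs = {
            0: n * (m - 1), 90: (n - 1) * m, 45: (n - 1) * (m - 1), 135: (n - 1) * (m - 1),
        }[theta]
        assert counts.sum() == expected_pairs

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(levels=grids, theta=st.sampled_from(ORIENTATIONS))
    def test_glrm_conserves_pixels_and_counts_by_level(self, levels, theta):
        q = QuantizedImage(levels=levels, G=8)
        r = compute_glrm(q, theta)
        lengths = np.arange(1, r.Q.shape[1] + 1)
        # run lengths weighted by level histogram: each level's pixels are
        # exactly covered by that level's runs
        per_level = (r.Q * lengths).sum(axis=1)
        hist = np.bincount(levels.ravel(), minlength=8)
        assert np.array_equal(per_level, hist)


class TestRendering:
    def _matrices(self, q):
        return [compute_glcm(q, t) for t in ORIENTATIONS]

    def test_constant_image_renders_single_hot_block(self):
        q = QuantizedImage(levels=np.full((8, 8), 2), G=8)
        img = render_textural_image(self._matrices(q), "glcm", target_size=(64, 64))
        # the (2,2) cell block is the unique maximum; every other block minimal
        blocks = img.pixels.reshape(8, 8, 8, 8, 3)
        hot = blocks[2, :, 2, :, :]
        cold = blocks[0, :, 0, :, :]
        assert not np.array_equal(hot[0, 0], cold[0, 0])
        # all non-(2,2) cells share the colormap minimum
        mask = np.ones((8, 8), bool)
        mask[2, 2] = False
        minima = blocks[mask][:, 0, 0, :]
        assert (minima == minima[0]).all()

    @pytest.mark.parametrize("mode", ["matrix", "tiled", "local"])
    def test_output_shape_matches_target(self, mode, rng):
        q = QuantizedImage(levels=rng.integers(0, 8, size=(40, 40)), G=8)
        img = render_textural_image(
            self._matrices(q), "glcm", render_mode=mode, target_size=(96, 80), quantized=q
        )
        assert img.pixels.shape == (96, 80, 3)

    def test_rendering_is_deterministic(self, rng):
        q = QuantizedImage(levels=rng.integers(0, 8, size=(20, 20)), G=8)
        a = render_textural_image(self._matrices(q), "glcm", target_size=(64, 64))
        b = render_textural_image(self._matrices(q), "glcm", target_size=(64, 64))
        assert np.array_equal(a.pixels, b.pixels)

    def test_degenerate_all_equal_matrices_render_mid_colormap(self):
        mats = [
            CooccurrenceMatrix(counts=np.ones((8, 8), dtype=int), theta=t) for t in ORIENTATIONS
        ]
        img = render_textural_image(mats, "glcm", target_size=(32, 32))
        assert np.isfinite(img.pixels).all()
        assert (img.pixels == img.pixels[0, 0]).all()  # uniform mid-colormap

    def test_shape_and_orientation_validation(self):
        q = QuantizedImage(levels=np.zeros((4, 4), dtype=int), G=4)
        mats = self._matrices(q)
        with pytest.raises(ValueError, match="4 matrices"):
            render_textural_image(mats[:3], "glcm")
        with pytest.raises(ValueError, match="orientations"):
            render_textural_image([mats[0]] * 4, "glcm")

    def test_isotropic_field_rotation_stability(self):
        """For isotropic noise the orientation-mean GLCM is rotation-stable."""
        rng = np.random.default_rng(7)
        levels = rng.integers(0, 8, size=(128, 128))
        q = QuantizedImage(levels=levels, G=8)
        q_rot = QuantizedImage(levels=np.rot90(levels).copy(), G=8)
        mean = np.mean([compute_glcm(q, t).normalized for t in ORIENTATIONS], axis=0)
        mean_rot = np.mean([compute_glcm(q_rot, t).normalized for t in ORIENTATIONS], axis=0)
        assert np.abs(mean - mean_rot).max() < 5e-3

    def test_texturize_preserves_label_and_id(self, tiny_dataset):
        out = texturize_image(tiny_dataset[0], "glrm", target_size=(64, 64))
        assert isinstance(out, LabeledImage)
        assert out.label == tiny_dataset[0].label
        assert out.image_id == tiny_dataset[0].image_id
        assert out.pixels.shape == (64, 64, 3)
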