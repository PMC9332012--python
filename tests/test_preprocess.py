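import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tillersight.preprocess import (
    DegenerateImageWarning,
    ThresholdConfig,
    binarize_green,
    crop,
    decorrelation_stretch,
    remove_small_components,
)


def _channel_corr(flat: np.ndarray) -> np.ndarray:
    c = np.corrcoef(flat, rowvar=False)
    return c - np.diag(np.diag(c))


class TestDecorrelationStretch:
    def test_constant_image_returned_unchanged_with_warning(self):
        img = np.full((16, 16, 3), 128, dtype=np.uint8)
        with pytest.warns(DegenerateImageWarning):
            out = decorrelation_stretch(img)
        np.testing.assert_array_equal(out, img)

    def test_correlated_channels_are_decorrelated(self):
        # B is a noisy copy of R: strong off-diagonal covariance going in
        rng = np.random.default_rng(0)
        r = rng.uniform(40, 200, size=(64, 64))
        g = rng.uniform(40, 200, size=(64, 64))
        b = r + rng.normal(0, 5, size=(64, 64))
        img = np.clip(np.stack([r, g, b], axis=-1), 0, 255).astype(np.uint8)
        out = decorrelation_stretch(img, quantize=False)
        assert np.abs(_channel_corr(out.reshape(-1, 3))).max() < 1e-6

    def test_matches_independent_eigendecomposition_oracle(self):
        # recompute the whitening transform from scratch and compare outputs
        rng = np.random.default_rng(1)
        base = rng.uniform(30, 220, size=(32, 32, 1))
        img = np.clip(base + rng.normal(0, 20, size=(32, 32, 3)), 0, 255).astype(np.uint8)
        out = decorrelation_stretch(img, quantize=False)

        flat = img.reshape(-1, 3).astype(float)
        mu = flat.mean(0)
        cov = np.cov(flat, rowvar=False)
        lam, vec = np.linalg.eigh(cov)
        expected = (flat - mu) @ (vec @ np.diag(lam**-0.5) @ vec.T) * np.sqrt(
            np.diag(cov)
        ) + mu
        np.testing.assert_allclose(out.reshape(-1, 3), expected, rtol=1e-9)
        # per-channel std restored
        np.testing.assert_allclose(
            out.reshape(-1, 3).std(axis=0), flat.std(axis=0), rtol=1e-6
        )

    def test_uncorrelated_unit_variance_input_preserved_up_to_affine(self):
        rng = np.random.default_rng(2)
        flat = rng.normal(0, 1, size=(4096, 3))
        img = np.clip(flat * 20 + 128, 0, 255).astype(np.uint8).reshape(64, 64, 3)
        out = decorrelation_stretch(img, quantize=False).reshape(-1, 3)
        src = img.reshape(-1, 3).astype(float)
        for ch in range(3):
            r = np.corrcoef(src[:, ch], out[:, ch])[0, 1]
            assert r > 0.999

    def test_quantized_output_dtype_and_range(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(20, 30, 3), dtype=np.uint8)
        out = decorrelation_stretch(img)
        assert out.dtype == np.uint8 and out.shape == img.shape


class TestBinarizeGreen:
    def test_uniform_image_all_plant_at_k1(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        mask = binarize_green(img, ThresholdConfig(k=1.0))
        assert mask.all()

    def test_two_level_image_splits_at_mean(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[:, :5, 1] = 100
        img[:, 5:, 1] = 200
        mask = binarize_green(img, ThresholdConfig(k=1.0))  # mean green = 150
        assert not mask[:, :5].any() and mask[:, 5:].all()

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        cfg = ThresholdConfig(k=0.9)
        mask = binarize_green(img, cfg)
        thr = 0.9 * img[:, :, 1].mean()
        for r in range(32):
            for c in range(32):
                assert mask[r, c] == (img[r, c, 1] >= thr)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        k1=st.floats(0.5, 2.0),
        k2=st.floats(0.5, 2.0),
    )
    def test_monotone_in_k(self, seed, k1, k2):
        # a higher threshold ratio can only shrink the plant mask
        if k1 > k2:
            k1, k2 = k2, k1
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        lo = binarize_green(img, ThresholdConfig(k=k1))
        hi = binarize_green(img, ThresholdConfig(k=k2))
        assert (hi <= lo).all()

    def test_k_outside_validated_range_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(k=0.2)


def _flood_fill_areas(mask: np.ndarray) -> list[set]:
    """Independent 8-connectivity labelling by BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp, stack = set(), [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


class TestRemoveSmallComponents:
    def test_area_boundary_equal_survives_smaller_removed(self):
        # "less than the threshold" is removed: 499 px goes, 500 px stays
        mask = np.zeros((60, 100), dtype=bool)
        mask[5:25, 5:30] = True  # 20 x 25 = 500 px
        mask[30:50, 40:65] = True  # 500 px ...
        mask[30, 40] = False  # ... minus one = 499 px
        out = remove_small_components(mask, 500)
        assert out[5:25, 5:30].all()
        assert not out[30:50, 40:65].any()

    def test_empty_mask_passthrough(self):
        mask = np.zeros((10, 10), dtype=bool)
        assert not remove_small_components(mask, 500).any()

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((120, 120), dtype=bool)
        for _ in range(50):
            r, c = rng.integers(0, 110, size=2)
            hgt, wid = rng.integers(1, 12, size=2)
            mask[r : r + hgt, c : c + wid] = True
        min_area = 40
        out = remove_small_components(mask, min_area)
        expected = np.zeros_like(mask)
        for comp in _flood_fill_areas(mask):
            if len(comp) >= min_area:
                for r, c in comp:
                    expected[r, c] = True
        np.testing.assert_array_equal(out, expected)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), a1=st.integers(0, 60), a2=st.integers(0, 60))
    def test_idempotent_and_antitone_in_min_area(self, seed, a1, a2):
        if a1 > a2:
            a1, a2 = a2, a1
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) > 0.6
        out1 = remove_small_components(mask, a1)
        np.testing.assert_array_equal(out1, remove_small_components(out1, a1))
        out2 = remove_small_components(mask, a2)
        assert (out2 <= out1).all()
        assert (out2 <= mask).all()  # no pixel added


def test_crop_bounds_checked():
    img = np.zeros((10, 10, 3), dtype=np.uint8)
    assert crop(img, 2, 3, 4, 5).shape == (4, 5, 3)
    with pytest.raises(ValueError):
        crop(img, 8, 8, 5, 5)
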