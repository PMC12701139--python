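import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrenalseg import (
    AugmentConfig,
    CtVolume,
    MaskVolume,
    PreprocessConfig,
    SliceDataset,
    SliceItem,
    apply_clahe,
    augment,
    clip_hounsfield,
    normalize,
    preprocess_volume,
    resize_slice,
    select_slices,
)
from adrenalseg.preprocess import _transform_pair


class TestClip:
    def test_elementwise_window(self):
        vol = CtVolume(np.array([[[-100.0, 20.0, 300.0]]]))
        out = clip_hounsfield(vol, PreprocessConfig(hu_low=10, hu_high=60))
        np.testing.assert_array_equal(out.voxels, [[[10.0, 20.0, 60.0]]])

    def test_within_window_unchanged_and_idempotent(self, rng):
        vox = rng.uniform(10, 60, size=(3, 4, 4)).astype(np.float32)
        vol = CtVolume(vox)
        once = clip_hounsfield(vol)
        np.testing.assert_array_equal(once.voxels, vox)
        np.testing.assert_array_equal(
            clip_hounsfield(once).voxels, once.voxels
        )

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(hu_low=60, hu_high=10)


class TestNormalize:
    def test_window_endpoints_and_midpoint(self):
        vol = CtVolume(np.array([[[10.0, 35.0, 60.0]]]))
        out = normalize(clip_hounsfield(vol))
        np.testing.assert_allclose(out.voxels, [[[0.0, 0.5, 1.0]]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_clipped_volume_maps_into_unit_range(self, seed):
        r = np.random.default_rng(seed)
        vol = CtVolume(r.normal(30, 40, size=(3, 6, 6)).astype(np.float32))
        out = normalize(clip_hounsfield(vol))
        assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0

    def test_order_preserving(self, rng):
        v = rng.uniform(10, 60, size=(1, 5, 5)).astype(np.float32)
        out = normalize(CtVolume(v)).voxels
        assert np.array_equal(np.argsort(v.ravel()), np.argsort(out.ravel()))


class TestClahe:
    def test_constant_image_stays_flat(self):
        out = apply_clahe(np.full((64, 64), 0.4))
        assert out.max() - out.min() < 0.05

    def test_low_contrast_range_expands(self, rng):
        img = np.where(rng.random((64, 64)) < 0.5, 0.45, 0.55)
        out = apply_clahe(img)
        assert out.max() - out.min() >= img.max() - img.min()
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_tile_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="tile grid"):
            apply_clahe(np.zeros((4, 4)), PreprocessConfig(clahe_tile_grid=(8, 8)))

    def test_full_pipeline_range(self, rng):
        vol = CtVolume(rng.normal(30, 50, size=(2, 64, 64)).astype(np.float32))
        out = preprocess_volume(vol)
        assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0


class TestSelectSlices:
    def _pair(self, fg_slices, n=20, hw=8):
        mask = np.zeros((n, hw, hw), dtype=np.uint8)
        for k in fg_slices:
            mask[k, 3:5, 3:5] = 1
        vol = CtVolume(np.random.default_rng(0).random((n, hw, hw)).astype(np.float32),
                       patient_id="scanA")
        return vol, MaskVolume(mask)

    def test_exact_slices_kept_in_order(self):
        vol, mask = self._pair({5, 6, 7})
        ds = select_slices(vol, mask)
        assert len(ds) == 3
        assert all(item.scan_id == "scanA" for item in ds)
        for item, k in zip(ds, [5, 6, 7]):
            np.testing.assert_array_equal(item.image, vol.voxels[k])

    def test_empty_mask_empty_dataset(self):
        vol, mask = self._pair(set())
        assert len(select_slices(vol, mask)) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_count_matches_bruteforce(self, seed):
        r = np.random.default_rng(seed)
        mask = (r.random((10, 6, 6)) < 0.05).astype(np.uint8)
        vol = CtVolume(r.random((10, 6, 6)).astype(np.float32))
        expected = sum(1 for k in range(10) if mask[k].sum() > 0)
        assert len(select_slices(vol, MaskVolume(mask))) == expected

    def test_shape_mismatch_rejected(self):
        vol, _ = self._pair({1})
        with pytest.raises(ValueError):
            select_slices(vol, MaskVolume(np.zeros((3, 8, 8))))


class TestResize:
    def test_image_shape_and_range(self, rng):
        img = rng.random((24, 24)).astype(np.float32)
        out = resize_slice(img, (16, 16))
        assert out.shape == (16, 16)
        assert 0.0 <= out.min() and out.max() <= 1.0 + 1e-6

    def test_label_stays_binary_and_roughly_scales(self):
        lab = np.zeros((32, 32), dtype=np.uint8)
        lab[8:24, 8:24] = 1
        out = resize_slice(lab, (16, 16), is_label=True)
        assert set(np.unique(out)) <= {0, 1}
        # a half-width square stays a half-width square
        assert out.sum() == pytest.approx(8 * 8, rel=0.3)


def _training_dataset(n=6, hw=16, seed=0):
    r = np.random.default_rng(seed)
    ds = SliceDataset()
    for i in range(n):
        img = r.random((hw, hw)).astype(np.float32)
        lab = np.zeros((hw, hw), dtype=np.uint8)
        lab[6:10, 6:10] = 1
        ds.append(SliceItem(img, lab, f"scan{i % 3}"))
    return ds


class TestAugment:
    def test_zero_copies_is_identity(self):
        ds = _training_dataset()
        out = augment(ds, AugmentConfig(copies_per_slice=0))
        assert len(out) == len(ds)
        for a, b in zip(out, ds):
            np.testing.assert_array_equal(a.image, b.image)

    def test_size_formula(self):
        ds = _training_dataset(n=5)
        out = augment(ds, AugmentConfig(copies_per_slice=2, seed=1))
        assert len(out) == 5 * 3
        assert sum(item.augmented for item in out) == 10

    def test_deterministic_under_seed(self):
        ds = _training_dataset()
        a = augment(ds, AugmentConfig(copies_per_slice=2, seed=9))
        b = augment(ds, AugmentConfig(copies_per_slice=2, seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)
            np.testing.assert_array_equal(x.label, y.label)

    def test_flip_only_preserves_foreground_count(self):
        ds = _training_dataset()
        for item in ds:
            img, lab = _transform_pair(item.image, item.label, 0.0, True, False)
            assert lab.sum() == item.label.sum()
            np.testing.assert_array_equal(img, item.image[:, ::-1])
            img, lab = _transform_pair(item.image, item.label, 0.0, False, True)
            assert lab.sum() == item.label.sum()

    def test_labels_stay_binary_and_nonempty(self):
        ds = _training_dataset()
        out = augment(ds, AugmentConfig(copies_per_slice=3, seed=2))
        for item in out:
            assert set(np.unique(item.label)) <= {0, 1}
            assert item.label.any()

    def test_empty_label_rejected(self):
        ds = SliceDataset([
            SliceItem(np.zeros((8, 8), np.float32), np.zeros((8, 8), np.uint8), "s")
        ])
        with pytest.raises(ValueError, match="nonempty"):
            augment(ds, AugmentConfig(copies_per_slice=1))
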