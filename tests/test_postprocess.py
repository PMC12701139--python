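from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrenalseg import (
    ComponentFilterConfig,
    CtVolume,
    MaskVolume,
    ProbVolume,
    TtaConfig,
    binarize,
    predict_volume,
    remove_unconnected,
    tta_predict,
)


def bfs_components(mask):
    """Independent 26-connectivity component labelling by breadth-first search."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            z, y, x = q.popleft()
            comp.append((z, y, x))
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        q.append(n)
        comps.append(comp)
    return comps


class TestTta:
    def test_flip_equivariant_predictor_unchanged(self, rng):
        vol = CtVolume(rng.random((3, 8, 8)).astype(np.float32))
        pointwise = lambda x: np.clip(x * 0.8 + 0.1, 0, 1)
        np.testing.assert_array_equal(
            tta_predict(pointwise, vol).voxels,
            predict_volume(pointwise, vol).voxels,
        )

    def test_orientation_sensitive_predictor_averages(self, rng):
        vol = CtVolume(rng.random((2, 6, 6)).astype(np.float32))
        originals = {vol.voxels[k].tobytes() for k in range(2)}

        def flips_only(x):
            # 1 on the three flipped views, 0 on the upright view
            return np.zeros_like(x) if x.tobytes() in originals else np.ones_like(x)

        out = tta_predict(flips_only, vol)
        np.testing.assert_allclose(out.voxels, 0.75)

    def test_flip_identities(self, rng):
        x = rng.random((6, 7))
        np.testing.assert_array_equal(x[:, ::-1][:, ::-1], x)
        np.testing.assert_array_equal(x[::-1, :][::-1, :], x)
        # up/down then left/right equals a 180-degree rotation
        np.testing.assert_array_equal(x[::-1, :][:, ::-1], np.rot90(x, 2))

    def test_disabled_tta_is_plain_prediction(self, rng):
        vol = CtVolume(rng.random((2, 6, 6)).astype(np.float32))
        pred = lambda x: np.full_like(x, 0.2)
        out = tta_predict(pred, vol, TtaConfig(enabled=False))
        np.testing.assert_allclose(out.voxels, 0.2)

    def test_shape_changing_predictor_rejected(self, rng):
        vol = CtVolume(rng.random((1, 6, 6)).astype(np.float32))
        with pytest.raises(ValueError, match="shape"):
            tta_predict(lambda x: x[:3, :3], vol)


class TestBinarize:
    def test_uniform_above_threshold(self):
        prob = ProbVolume(np.full((2, 3, 3), 0.75, dtype=np.float32))
        assert binarize(prob, 0.5).foreground_count() == 18

    def test_at_threshold_is_foreground(self):
        prob = ProbVolume(np.full((1, 2, 2), 0.5, dtype=np.float32))
        assert binarize(prob, 0.5).foreground_count() == 4

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           threshold=st.floats(0.05, 0.95))
    def test_count_matches_bruteforce(self, seed, threshold):
        r = np.random.default_rng(seed)
        vox = r.random((3, 5, 5)).astype(np.float32)
        got = binarize(ProbVolume(vox), threshold).foreground_count()
        expected = sum(1 for v in vox.ravel() if v >= threshold)
        assert got == expected

    def test_invalid_threshold_rejected(self):
        prob = ProbVolume(np.zeros((1, 2, 2), dtype=np.float32))
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                binarize(prob, bad)


class TestRemoveUnconnected:
    def test_single_component_unchanged(self):
        vox = np.zeros((5, 5, 5), dtype=np.uint8)
        vox[1:4, 1:4, 1:4] = 1
        mask = MaskVolume(vox)
        np.testing.assert_array_equal(remove_unconnected(mask).voxels, vox)

    def test_largest_of_two_survives(self):
        vox = np.zeros((6, 10, 10), dtype=np.uint8)
        vox[1:5, 1:6, 1:6] = 1  # 100 voxels
        vox[0, 8, 8] = vox[0, 8, 9] = vox[0, 9, 8] = 1  # 3 voxels
        out = remove_unconnected(MaskVolume(vox))
        assert out.foreground_count() == 100
        assert out.voxels[0, 8, 8] == 0

    def test_tie_break_keeps_first_in_scan_order(self):
        vox = np.zeros((3, 8, 8), dtype=np.uint8)
        vox[1, 1:3, 1:3] = 1  # 4 voxels, min coord (1,1,1)
        vox[1, 5:7, 5:7] = 1  # 4 voxels, min coord (1,5,5)
        out = remove_unconnected(MaskVolume(vox))
        assert out.foreground_count() == 4
        assert out.voxels[1, 1, 1] == 1 and out.voxels[1, 5, 5] == 0

    def test_empty_input_empty_output(self):
        mask = MaskVolume(np.zeros((3, 4, 4)))
        assert remove_unconnected(mask).foreground_count() == 0

    def test_min_size_policy(self):
        vox = np.zeros((4, 8, 8), dtype=np.uint8)
        vox[1, 1:3, 1:4] = 1  # 6 voxels
        vox[3, 6, 6] = 1  # 1 voxel
        cfg = ComponentFilterConfig(policy="min-size", min_size=2)
        out = remove_unconnected(MaskVolume(vox), cfg)
        assert out.foreground_count() == 6

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bfs_oracle_and_invariants(self, seed):
        r = np.random.default_rng(seed)
        vox = (r.random((6, 8, 8)) < 0.08).astype(np.uint8)
        mask = MaskVolume(vox)
        out = remove_unconnected(mask)
        # keep-largest semantics against an independent BFS labelling
        comps = bfs_components(vox)
        if comps:
            best = max(len(c) for c in comps)
            winners = [c for c in comps if len(c) == best]
            expected = min(len(c) for c in winners) if len(winners) > 1 else best
            assert out.foreground_count() == best
            got = set(map(tuple, np.argwhere(out.voxels)))
            assert any(got == set(c) for c in winners)
        else:
            assert out.foreground_count() == 0
        # output is a subset of the input (monotone-decreasing)
        assert np.all(out.voxels <= vox)
        # idempotence
        np.testing.assert_array_equal(
            remove_unconnected(out).voxels, out.voxels
        )

    def test_connectivity_matters(self):
        # two voxels touching only at a corner: joined at 26, split at 6
        vox = np.zeros((3, 3, 3), dtype=np.uint8)
        vox[0, 0, 0] = vox[1, 1, 1] = 1
        mask = MaskVolume(vox)
        assert remove_unconnected(mask, ComponentFilterConfig(connectivity=26)
                                  ).foreground_count() == 2
        assert remove_unconnected(mask, ComponentFilterConfig(connectivity=6)
                                  ).foreground_count() == 1

    def test_per_slice_mode(self):
        vox = np.zeros((2, 6, 6), dtype=np.uint8)
        vox[0, 0:2, 0:2] = 1  # 4 voxels on slice 0
        vox[1, 4, 4] = 1      # 1 voxel on slice 1 (disconnected in 2D)
        out = remove_unconnected(MaskVolume(vox), ComponentFilterConfig(mode="2d"))
        # per-slice keep-largest keeps the largest component of every slice
        assert out.foreground_count() == 5
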