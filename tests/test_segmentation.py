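from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from roqa.segmentation import (
    BinaryVolume,
    SegmentationParams,
    ball_closing,
    binary_smoothing,
    border_kill,
    fill_holes,
    label_particles,
    nlm_denoise,
    segment_volume,
    sieve_volume,
    threshold_band,
    white_top_hat,
)
from roqa.volume_io import IntensityVolume

# ---------------------------------------------------------------- oracles


def brute_force_opening(data: np.ndarray, k: int) -> np.ndarray:
    """Erosion then dilation with a k-cube, straight from the definition
    (min/max over the structuring-element window, reflect boundary)."""
    r = k // 2
    offsets = [
        (dz, dy, dx)
        for dz in range(-r, k - r)
        for dy in range(-r, k - r)
        for dx in range(-r, k - r)
    ]

    def sweep(a, fn):
        padded = np.pad(a, r + (k - r - 1), mode="reflect")
        stack = [
            padded[
                r + (k - r - 1) + dz : r + (k - r - 1) + dz + a.shape[0],
                r + (k - r - 1) + dy : r + (k - r - 1) + dy + a.shape[1],
                r + (k - r - 1) + dx : r + (k - r - 1) + dx + a.shape[2],
            ]
            for dz, dy, dx in offsets
        ]
        return fn(np.stack(stack), axis=0)

    return sweep(sweep(data, np.min), np.max)


def bfs_components_26(mask: np.ndarray) -> int:
    """Count 26-connected components by breadth-first flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    nbrs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        q = deque([start])
        seen[start] = True
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in nbrs:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p] and not seen[p]:
                    seen[p] = True
                    q.append(p)
    return count


def bfs_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill-holes oracle: flood the background 6-connectedly from the
    border; unreached background is hole."""
    bg = ~mask
    reach = np.zeros_like(mask, dtype=bool)
    q = deque()
    for idx in np.argwhere(bg):
        z, y, x = idx
        if 0 in idx or z == mask.shape[0] - 1 or y == mask.shape[1] - 1 or x == mask.shape[2] - 1:
            if not reach[z, y, x]:
                reach[z, y, x] = True
                q.append((z, y, x))
    nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in nbrs:
            p = (z + dz, y + dy, x + dx)
            if all(0 <= p[i] < mask.shape[i] for i in range(3)) and bg[p] and not reach[p]:
                reach[p] = True
                q.append(p)
    return mask | (bg & ~reach)


# ---------------------------------------------------------------- WTH


class TestWhiteTopHat:
    def test_constant_volume_maps_to_zero(self):
        v = IntensityVolume(np.full((9, 9, 9), 7000, dtype=np.uint16), (1, 1, 1))
        assert white_top_hat(v, 3).data.max() == 0

    def test_single_bright_voxel_survives_fully(self):
        data = np.zeros((9, 9, 9), dtype=np.uint16)
        data[4, 4, 4] = 10000
        v = IntensityVolume(data, (1, 1, 1))
        out = white_top_hat(v, 3).data
        assert out[4, 4, 4] == 10000
        assert out.sum() == 10000

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            data = rng.integers(0, 65535, size=(12, 12, 12), dtype=np.uint16)
            v = IntensityVolume(data, (1, 1, 1))
            expected = data.astype(np.int64) - brute_force_opening(data.astype(np.int64), 3)
            np.testing.assert_array_equal(white_top_hat(v, 3).data.astype(np.int64), expected)

    def test_kernel_larger_than_volume_is_error(self):
        v = IntensityVolume(np.zeros((4, 4, 4), dtype=np.uint16), (1, 1, 1))
        with pytest.raises(ValueError):
            white_top_hat(v, 5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(np.uint16, (6, 6, 6), elements=st.integers(0, 65535)))
    def test_anti_extensive_property(self, data):
        # 0 <= WTH(v) <= v voxelwise for any input
        v = IntensityVolume(data, (1, 1, 1))
        out = white_top_hat(v, 3).data
        assert (out >= 0).all()
        assert (out <= data).all()


# ---------------------------------------------------------------- thresholds


class TestThresholdBand:
    def test_dry_scaffold_limits_inclusive(self):
        v = IntensityVolume(np.array([[[0, 2699, 2700, 65535]]], dtype=np.uint16), (1, 1, 1))
        mask = threshold_band(v, 2700, 65535).mask
        np.testing.assert_array_equal(mask, [[[False, False, True, True]]])

    def test_full_band_accepts_everything(self, small_volume):
        assert threshold_band(small_volume, 0, 65535).mask.all()

    def test_lower_above_upper_is_error(self, small_volume):
        with pytest.raises(ValueError):
            threshold_band(small_volume, 10, 5)


# ---------------------------------------------------------------- cleaning


class TestFillHoles:
    def test_hollow_shell_becomes_solid(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        mask[2:5, 2:5, 2:5] = False
        out = fill_holes(BinaryVolume(mask, (1, 1, 1))).mask
        assert out[1:6, 1:6, 1:6].all()

    def test_idempotent_on_solid_sphere(self, sphere_mask):
        b = BinaryVolume(sphere_mask, (1, 1, 1))
        once = fill_holes(b).mask
        np.testing.assert_array_equal(once, sphere_mask)

    def test_open_cavity_touching_border_unchanged(self):
        # C-shaped cavity open to the border must not be filled
        mask = np.ones((7, 7, 7), dtype=bool)
        mask[3, 3, 0:5] = False  # tunnel to the x=0 face
        out = fill_holes(BinaryVolume(mask, (1, 1, 1))).mask
        np.testing.assert_array_equal(out, bfs_fill_holes(mask))
        assert not out[3, 3, 0]

    def test_matches_bfs_oracle_on_seeded_masks(self, rng):
        for _ in range(10):
            mask = rng.random((10, 10, 10)) < 0.5
            out = fill_holes(BinaryVolume(mask, (1, 1, 1))).mask
            np.testing.assert_array_equal(out, bfs_fill_holes(mask))
            assert (out | ~mask).all() or (out >= mask).all()  # never shrinks


class TestLabelParticles:
    def test_corner_touch_is_one_particle(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert label_particles(BinaryVolume(mask, (1, 1, 1))).n_particles == 1

    def test_gap_separates_particles(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 3] = True
        assert label_particles(BinaryVolume(mask, (1, 1, 1))).n_particles == 2

    def test_matches_bfs_oracle_on_seeded_masks(self, rng):
        for _ in range(10):
            mask = rng.random((12, 12, 12)) < 0.25
            lv = label_particles(BinaryVolume(mask, (1, 1, 1)))
            assert lv.n_particles == bfs_components_26(mask)

    def test_labels_consecutive_from_one(self, rng):
        mask = rng.random((12, 12, 12)) < 0.2
        lv = label_particles(BinaryVolume(mask, (1, 1, 1)))
        ids = np.unique(lv.labels)
        np.testing.assert_array_equal(ids, np.arange(lv.n_particles + 1))


class TestBorderKill:
    def test_face_spanning_particle_removed(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 2, 2] = True
        lv = label_particles(BinaryVolume(mask, (1, 1, 1)))
        assert border_kill(lv).n_particles == 0

    def test_interior_particle_kept(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        lv = label_particles(BinaryVolume(mask, (1, 1, 1)))
        assert border_kill(lv).n_particles == 1

    def test_mixed_fixture(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[0, 1, 1] = True  # touches z face
        mask[4, 4, 0] = True  # touches x face
        for p in [(2, 2, 2), (2, 6, 6), (6, 2, 6)]:
            mask[p] = True
        lv = label_particles(BinaryVolume(mask, (1, 1, 1)))
        assert lv.n_particles == 5
        assert border_kill(lv).n_particles == 3


class TestSieveVolume:
    def test_high_pass_on_isotropic_voxels(self):
        mask = np.zeros((20, 20, 20), dtype=np.int32)
        mask[1, 1, 1:6] = 1  # 5 voxels
        mask[5, 1:5, 1:6] = 2  # 20 voxels
        mask[10:14, 1:6, 1:6] = 3  # 100 voxels
        from roqa.segmentation import LabelVolume

        lv = LabelVolume(mask, (1, 1, 1))
        assert sieve_volume(lv, 15.0).n_particles == 2

    def test_boundary_volume_retained(self):
        mask = np.zeros((6, 6, 6), dtype=np.int32)
        mask[1, 1:4, 1:6] = 1  # 15 voxels = 15 um3 at 1 um isotropic
        from roqa.segmentation import LabelVolume

        assert sieve_volume(LabelVolume(mask, (1, 1, 1)), 15.0).n_particles == 1

    def test_clsm_band_pass(self):
        from roqa.segmentation import LabelVolume

        labels = np.zeros((20, 20, 20), dtype=np.int32)
        sizes = {1: 100, 2: 120, 3: 2290, 4: 2300}
        start = 0
        flat = labels.reshape(-1)
        for lab, n in sizes.items():
            flat[start : start + n] = lab
            start += n + 50
        lv = LabelVolume(labels, (1, 1, 1))
        out = sieve_volume(lv, 120.0, 2290.0)
        assert out.n_particles == 2

    def test_relabeling_preserves_voxel_sets(self, rng):
        from roqa.segmentation import LabelVolume

        mask = rng.random((14, 14, 14)) < 0.2
        lv = label_particles(BinaryVolume(mask, (1, 1, 1)))
        sieved = sieve_volume(lv, 3.0)
        # every surviving particle's voxel set equals some original set
        orig = {
            frozenset(map(tuple, np.argwhere(lv.labels == i)))
            for i in range(1, lv.n_particles + 1)
        }
        for i in range(1, sieved.n_particles + 1):
            assert frozenset(map(tuple, np.argwhere(sieved.labels == i))) in orig


# ---------------------------------------------------------------- filters


class TestNlmDenoise:
    def test_constant_volume_is_fixed_point(self):
        v = IntensityVolume(np.full((12, 12, 12), 5000, dtype=np.uint16), (1, 1, 1))
        np.testing.assert_array_equal(nlm_denoise(v, search=4).data, v.data)

    def test_reduces_noise_on_flat_region(self, rng):
        data = (5000 + rng.normal(0, 500, (16, 16, 16))).clip(0, 65535).astype(np.uint16)
        v = IntensityVolume(data, (1, 1, 1))
        out = nlm_denoise(v, search=5).data
        assert out[4:12, 4:12, 4:12].std() < data[4:12, 4:12, 4:12].std()

    def test_shrinks_isolated_spike(self, rng):
        data = (5000 + rng.normal(0, 100, (12, 12, 12))).astype(np.float64)
        data[6, 6, 6] = 15000
        v = IntensityVolume(data.clip(0, 65535).astype(np.uint16), (1, 1, 1))
        out = nlm_denoise(v, search=4).data
        assert out[6, 6, 6] < 15000 - 1000


class TestClsmOps:
    def test_ball_closing_connects_near_spheres(self):
        from tests.conftest import voxelized_ellipsoid

        s = voxelized_ellipsoid((3, 3, 3), pad=0)  # solid 7-wide ball
        n = s.shape[0]
        mask = np.zeros((n + 4, 2 * n + 5, n + 4), dtype=bool)
        mask[2:-2, 2 : 2 + n, 2:-2] = s
        mask[2:-2, 3 + n : 3 + 2 * n, 2:-2] = s  # one-voxel gap along y
        b = BinaryVolume(mask, (1, 1, 1))
        assert label_particles(b).n_particles == 2
        closed = ball_closing(b, 3)
        assert label_particles(closed).n_particles == 1

    def test_smoothing_removes_isolated_voxel(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        out = binary_smoothing(BinaryVolume(mask, (1, 1, 1)), 3, 0.5)
        assert not out.mask.any()

    def test_smoothing_keeps_cube_interior(self):
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True
        out = binary_smoothing(BinaryVolume(mask, (1, 1, 1)), 3, 0.5)
        assert out.mask[3:11, 3:11, 3:11].all()

    def test_closing_never_removes_foreground(self, rng):
        mask = rng.random((12, 12, 12)) < 0.3
        out = ball_closing(BinaryVolume(mask, (1, 1, 1)), 3)
        assert (out.mask | ~mask).all()


# ---------------------------------------------------------------- chain


class TestFullChain:
    def test_deterministic(self, rng):
        data = rng.integers(0, 20000, size=(24, 24, 24), dtype=np.uint16)
        v = IntensityVolume(data, (1, 1, 1))
        p = SegmentationParams(wth_kernel=3, wth_lower=5000, min_volume_um3=2)
        a = segment_volume(v, p)
        b = segment_volume(v, p)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_counts_interior_ellipsoids_exactly(self):
        from roqa.synthetic import SceneSpec, generate_scene

        spec = SceneSpec(
            n_nuclei=4, shape=(96, 96, 96), blur_sigma_um=0, noise_sd=0, seed=3
        )
        vol, truth = generate_scene(spec)
        p = SegmentationParams(wth_kernel=31, wth_lower=3500, min_volume_um3=15)
        lv = segment_volume(vol, p)
        assert lv.n_particles == 4

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(wth_lower=10, wth_upper=5)
        with pytest.raises(ValueError):
            SegmentationParams(wth_kernel=0)
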