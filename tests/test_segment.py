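from collections import deque

import numpy as np
import pytest
from scipy import ndimage as ndi

from panorex.errors import ConfigError, SegmentationEmptyError
from panorex.phantom import PhantomSpec, generate_phantom
from panorex.segment import (
    SegmentationConfig,
    connect_regions,
    largest_component,
    segment_arch,
    select_reference_slice,
    smooth_mask,
    threshold_volume,
)
from panorex.volume import CTVolume

CFG = SegmentationConfig()


def _volume(vox):
    return CTVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))


def _random_mask(rng, shape=(40, 40), p=0.2):
    return rng.random(shape) < p


def _blob_mask(rng, shape=(60, 60), n_disks=4):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, bool)
    for _ in range(n_disks):
        cy, cx = rng.uniform(10, shape[0] - 10, 2)
        r = rng.uniform(3, 8)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _flood_fill_components(mask):
    """Brute-force 8-connected labeling by BFS (oracle)."""
    labels = np.zeros(mask.shape, int)
    current = 0
    for r0, c0 in zip(*np.nonzero(mask)):
        if labels[r0, c0]:
            continue
        current += 1
        queue = deque([(r0, c0)])
        labels[r0, c0] = current
        while queue:
            r, c = queue.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not labels[rr, cc]
                    ):
                        labels[rr, cc] = current
                        queue.append((rr, cc))
    return labels, current


class TestThreshold:
    def test_inclusive_boundary_at_enamel_level(self):
        vox = np.full((3, 16, 16), -1000.0)
        vox[1, 8, 8] = 1500.0
        out = threshold_volume(_volume(vox), 1500.0)
        assert out.sum() == 1 and out[1, 8, 8]

    def test_all_air_gives_empty(self):
        assert not threshold_volume(_volume(np.full((2, 16, 16), -1000.0)), 1500).any()

    def test_low_threshold_gives_full(self):
        assert threshold_volume(_volume(np.zeros((2, 16, 16))), -2000).all()

    def test_monotone_in_threshold(self, rng):
        vol = _volume(rng.normal(500, 700, size=(4, 20, 20)))
        for lo, hi in [(-500, 0), (0, 800), (800, 1500)]:
            assert not (threshold_volume(vol, hi) & ~threshold_volume(vol, lo)).any()


class TestReferenceSlice:
    def test_argmax_and_tie_breaking(self):
        vox = np.full((3, 16, 16), -1000.0)
        vox[0, 0, :5] = 2000
        vox[1, 0, :9] = 2000
        vox[2, 0, :2] = 2000
        assert select_reference_slice(threshold_volume(_volume(vox), 1500)) == 1
        vox2 = np.full((3, 16, 16), -1000.0)
        vox2[0, 0, :4] = 2000
        vox2[1, 0, :4] = 2000
        vox2[2, 0, :1] = 2000
        assert select_reference_slice(threshold_volume(_volume(vox2), 1500)) == 0

    def test_agrees_with_per_slice_sum_oracle(self, rng):
        for _ in range(50):
            binary = rng.random((5, 12, 12)) < 0.3
            if binary.sum() == 0:
                continue
            oracle = max(
                range(5), key=lambda z: (sum(binary[z].ravel()), -z)
            )
            assert select_reference_slice(binary) == oracle

    def test_empty_volume_raises(self):
        with pytest.raises(SegmentationEmptyError):
            select_reference_slice(np.zeros((3, 16, 16), bool))


class TestConnectRegions:
    def test_bridges_15px_gap(self):
        mask = np.zeros((40, 60), bool)
        mask[20, 20] = mask[20, 35] = True
        out = connect_regions(mask, CFG)
        _, n = _flood_fill_components(out)
        assert n == 1

    def test_extensive_on_random_masks(self, rng):
        for _ in range(50):
            mask = _random_mask(rng, (30, 30))
            assert (connect_regions(mask, CFG) | mask).sum() == connect_regions(mask, CFG).sum()

    def test_single_pixel_dilates_to_footprint_rectangle(self):
        """Direct set arithmetic: floor-center origin puts a 20x20 footprint
        at offsets -9..+10 around the seed pixel."""
        mask = np.zeros((41, 41), bool)
        mask[20, 20] = True
        out = connect_regions(mask, CFG)
        expected = np.zeros_like(mask)
        expected[20 - 9 : 20 + 11, 20 - 9 : 20 + 11] = True
        np.testing.assert_array_equal(out, expected)

    def test_monotone_in_input(self, rng):
        small = _random_mask(rng, (30, 30), p=0.05)
        big = small | _random_mask(rng, (30, 30), p=0.05)
        assert not (connect_regions(small, CFG) & ~connect_regions(big, CFG)).any()


class TestSmoothMask:
    def test_constants_are_fixed_points(self):
        assert smooth_mask(np.ones((32, 32), bool), CFG).all()
        assert not smooth_mask(np.zeros((32, 32), bool), CFG).any()

    def test_isolated_pixel_vanishes_at_sigma4(self):
        # peak of the blurred impulse is ~1/(2*pi*sigma^2) ~ 0.01 << 0.5
        impulse = np.zeros((41, 41))
        impulse[20, 20] = 1.0
        assert ndi.gaussian_filter(impulse, 4.0).max() < 0.5
        mask = np.zeros((41, 41), bool)
        mask[20, 20] = True
        assert not smooth_mask(mask, CFG).any()

    def test_rarely_splits_dilated_blobs(self, rng):
        """Smoothing merges rather than splits: component count after
        dilation does not increase in >= 95% of random blob masks."""
        kept = 0
        total = 100
        for _ in range(total):
            dilated = connect_regions(_blob_mask(rng), CFG)
            _, n_before = _flood_fill_components(dilated)
            smoothed = smooth_mask(dilated, CFG)
            _, n_after = _flood_fill_components(smoothed)
            kept += n_after <= n_before
        assert kept >= 95


class TestLargestComponent:
    def test_keeps_biggest_of_three(self):
        mask = np.zeros((30, 30), bool)
        mask[1:7, 1:6] = True  # 30 px
        mask[10:14, 10:13] = True  # 12 px
        mask[20, 20:23] = True  # 3 px
        out = largest_component(mask)
        assert out.sum() == 30 and out[1:7, 1:6].all()

    def test_single_component_identity(self):
        mask = np.zeros((20, 20), bool)
        mask[5:9, 5:9] = True
        np.testing.assert_array_equal(largest_component(mask), mask)

    def test_agrees_with_flood_fill_oracle(self, rng):
        for _ in range(50):
            mask = _random_mask(rng, (15, 15), p=0.35)
            if not mask.any():
                continue
            labels, n = _flood_fill_components(mask)
            sizes = np.bincount(labels.ravel())[1:]
            out = largest_component(mask)
            assert out.sum() == sizes.max()
            lab_out = set(np.unique(labels[out]))
            assert len(lab_out) == 1  # a single oracle component was kept
            assert not (out & ~mask).any()

    def test_output_connected_subset(self, rng):
        for _ in range(20):
            mask = _random_mask(rng, (20, 20), p=0.3)
            if not mask.any():
                continue
            out = largest_component(mask)
            assert not (out & ~mask).any()
            _, n = _flood_fill_components(out)
            assert n == 1

    def test_empty_mask_raises(self):
        with pytest.raises(SegmentationEmptyError):
            largest_component(np.zeros((10, 10), bool))


class TestSegmentArch:
    def test_phantom_yields_single_component(self, default_phantom):
        volume, _ = default_phantom
        index, mask = segment_arch(volume)
        _, n = _flood_fill_components(mask)
        assert n == 1
        z0, z1 = (15, 45)
        assert z0 <= index < z1  # reference slice lies in the tooth slab

    def test_missing_teeth_still_one_component(self, missing_teeth_phantom):
        volume, _ = missing_teeth_phantom
        _, mask = segment_arch(volume)
        _, n = _flood_fill_components(mask)
        assert n == 1

    def test_toothless_phantom_raises(self):
        spec = PhantomSpec(missing_teeth=frozenset(range(14)), n_slices=8)
        volume, _ = generate_phantom(spec)
        with pytest.raises(SegmentationEmptyError):
            segment_arch(volume)


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SegmentationConfig(gaussian_sigma=0.0)
    with pytest.raises(ConfigError):
        SegmentationConfig(rebinarize_level=1.5)
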