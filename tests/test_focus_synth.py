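"""Synthetic data generators: mask partitions, defocus blending, textured
raw images, exposure stacks, dataset writing."""

import json

import numpy as np
import pytest
from scipy import ndimage

from nfuse import focus_synth as fsynth


class TestBasalMasks:
    def test_partition_counts_and_tiling(self):
        parts = fsynth.make_basal_masks((64, 64))
        for k, p in enumerate(parts, start=1):
            assert p.shape[0] == k
            np.testing.assert_array_equal(p.sum(axis=0), np.ones((64, 64)))

    def test_regions_are_connected(self):
        for p in fsynth.make_basal_masks((32, 48)):
            for region in p:
                _, n = ndimage.label(region)
                assert n == 1

    def test_halves_split_128(self):
        p2 = fsynth.make_basal_masks((128, 128))[1]
        assert p2[0].sum() == 128 * 64 and p2[1].sum() == 128 * 64

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            fsynth.make_basal_masks((4, 4))


class TestShapeMasks:
    def test_deterministic_per_seed(self):
        a = fsynth.make_shape_mask((64, 64), seed=42)
        b = fsynth.make_shape_mask((64, 64), seed=42)
        np.testing.assert_array_equal(a, b)

    def test_binary_values(self):
        m = fsynth.make_shape_mask((48, 48), seed=3)
        assert set(np.unique(m)) <= {0, 1}

    def test_coverage_contract_over_100_seeds(self):
        area = 128 * 128
        for seed in range(100):
            frac = fsynth.make_shape_mask((128, 128), seed).sum() / area
            assert 0.15 <= frac <= 0.60, seed

    def test_connected(self):
        for seed in range(10):
            m = fsynth.make_shape_mask((64, 64), seed)
            _, n = ndimage.label(m)
            assert n == 1


class TestComposePartition:
    def test_m2_with_whole_frame_basal_is_shape_and_complement(self):
        shape = fsynth.make_shape_mask((32, 32), seed=5)
        basal = fsynth.make_basal_masks((32, 32))[0]
        ms = fsynth.compose_partition(2, basal, shape)
        got = {m.tobytes() for m in ms.masks}
        assert got == {shape.astype(np.uint8).tobytes(),
                       (1 - shape).astype(np.uint8).tobytes()}

    @pytest.mark.parametrize("m", [2, 4, 6, 8])
    def test_exact_partition_any_m(self, m):
        shape = fsynth.make_shape_mask((64, 64), seed=m)
        basal = fsynth.make_basal_masks((64, 64))[2]
        ms = fsynth.compose_partition(m, basal, shape, seed=m)
        assert ms.M == m
        np.testing.assert_array_equal(ms.masks.sum(axis=0), np.ones((64, 64)))

    def test_m4_from_two_region_basal_pixel_enumeration(self):
        shape = fsynth.make_shape_mask((32, 32), seed=9)
        basal = fsynth.make_basal_masks((32, 32))[1]
        ms = fsynth.compose_partition(4, basal, shape, seed=9)
        assert ms.M == 4
        # pairwise disjoint and covering, pixel by pixel
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.any(ms.masks[i] & ms.masks[j])
        np.testing.assert_array_equal(np.bitwise_or.reduce(ms.masks), 1)

    @pytest.mark.parametrize("m", [1, 9])
    def test_m_out_of_range(self, m):
        basal = fsynth.make_basal_masks((32, 32))[0]
        with pytest.raises(ValueError):
            fsynth.compose_partition(m, basal, np.ones((32, 32), dtype=np.uint8))


class TestMaskSetInvariants:
    def test_rejects_non_partition(self):
        with pytest.raises(ValueError, match="partition"):
            fsynth.MaskSet(np.ones((2, 8, 8), dtype=np.uint8))

    def test_rejects_tiny_region(self):
        masks = np.zeros((2, 32, 32), dtype=np.uint8)
        masks[0, 0, 0] = 1
        masks[1] = 1 - masks[0]
        with pytest.raises(ValueError, match="1%"):
            fsynth.MaskSet(masks)


class TestFocusSet:
    def test_defocus_selection_pixelwise(self):
        clear = fsynth.make_synthetic_raw(1, (32, 32))
        fs = fsynth.synthesize_focus_set(clear, M=3, seed=1)
        for d, p in zip(fs.defocused, fs.masks.masks.astype(bool)):
            np.testing.assert_array_equal(d[p], fs.clear[p])
            np.testing.assert_array_equal(d[~p], fs.blurred[~p])

    def test_oracle_reconstruction_is_exact(self):
        clear = fsynth.make_synthetic_raw(2, (32, 32))
        fs = fsynth.synthesize_focus_set(clear, M=4, seed=2)
        recon = (fs.defocused * fs.masks.masks).sum(axis=0)
        np.testing.assert_array_equal(recon, fs.clear)

    def test_sigma_within_range_and_reproducible(self):
        clear = fsynth.make_synthetic_raw(3, (32, 32))
        a = fsynth.synthesize_focus_set(clear, M=2, seed=7)
        b = fsynth.synthesize_focus_set(clear, M=2, seed=7)
        assert 1.0 <= a.sigma <= 2.0
        assert a.sigma == b.sigma
        np.testing.assert_array_equal(a.defocused, b.defocused)

    def test_explicit_sigma_out_of_range_rejected(self):
        clear = fsynth.make_synthetic_raw(4, (32, 32))
        with pytest.raises(ValueError):
            fsynth.synthesize_focus_set(clear, M=2, sigma=3.0)


class TestSyntheticRaw:
    def test_deterministic(self):
        np.testing.assert_array_equal(
            fsynth.make_synthetic_raw(11, (32, 32)), fsynth.make_synthetic_raw(11, (32, 32))
        )

    def test_range(self):
        img = fsynth.make_synthetic_raw(12, (48, 48))
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_blur_reduces_gradient_energy(self):
        for seed in range(5):
            img = fsynth.make_synthetic_raw(seed, (64, 64))
            blurred = ndimage.gaussian_filter(img, 2.0)

            def energy(a):
                gy, gx = np.gradient(a)
                return np.hypot(gy, gx).mean()

            assert energy(blurred) < energy(img)


class TestExposureSet:
    def test_monotone_in_gain_before_clipping(self):
        es = fsynth.make_exposure_set(5, (32, 32), K=4)
        raw = es.gains[:, None, None] * es.radiance
        for k in range(3):
            assert (raw[k + 1] >= raw[k]).all()

    def test_lowest_gain_unclipped_equals_rendering(self):
        es = fsynth.make_exposure_set(6, (32, 32), K=3)
        raw0 = es.gains[0] * es.radiance
        assert raw0.max() <= 1.0
        np.testing.assert_array_equal(es.ldrs[0], raw0)

    def test_unclipped_union_covers_frame(self):
        for seed in range(20):
            es = fsynth.make_exposure_set(seed, (32, 32), K=3)
            unclipped = ((es.ldrs > 0) & (es.ldrs < 1)).any(axis=0)
            assert unclipped.mean() >= 0.95

    def test_needs_two_exposures(self):
        with pytest.raises(ValueError):
            fsynth.make_exposure_set(0, (16, 16), K=1)


class TestDatasetWriter:
    def test_bit_reproducible_trees(self, tmp_path):
        m1 = fsynth.write_focus_dataset(tmp_path / "a", 2, size=32, seed=7)
        m2 = fsynth.write_focus_dataset(tmp_path / "b", 2, size=32, seed=7)
        assert m1["sets"] == m2["sets"]
        for p1 in sorted((tmp_path / "a").rglob("*")):
            p2 = tmp_path / "b" / p1.relative_to(tmp_path / "a")
            if p1.is_file():
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_manifest_and_masks_round_trip(self, tmp_path):
        from nfuse import color

        fsynth.write_focus_dataset(tmp_path / "d", 2, min_m=3, max_m=3, size=32, seed=1)
        manifest = json.loads((tmp_path / "d" / "manifest.json").read_text())
        assert all(s["M"] == 3 for s in manifest["sets"])
        masks = np.stack(
            [
                color.read_image(tmp_path / "d" / "set_0000" / f"mask_{i}.png").pixels
                for i in range(3)
            ]
        )
        np.testing.assert_array_equal(masks.sum(axis=0), np.ones((32, 32)))
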