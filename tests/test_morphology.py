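"""Morphological operators vs brute-force set-definition oracles, and the
seven-step lung-mask extraction pipeline on phantoms."""

import numpy as np
import pytest

from lungseg import (
    CTSlice,
    PhantomSpec,
    StructuringElement,
    binarize_hu,
    clear_border,
    close,
    dice,
    dilate,
    disk_footprint,
    erode,
    extract_lung_mask,
    fill_holes,
    generate_phantom,
    generate_phantom_parts,
    jitter_spec,
    keep_largest_k,
    label_components,
)
from conftest import (
    brute_clear_border,
    brute_dilate,
    brute_erode,
    brute_fill_holes,
    brute_label,
    random_masks,
)


class TestBinarize:
    def test_threshold_is_strict(self, flat_slice):
        assert binarize_hu(flat_slice(-1000.0))[0, 0] == 1
        assert binarize_hu(flat_slice(0.0))[0, 0] == 0
        assert binarize_hu(flat_slice(-604.0))[0, 0] == 0  # strict <

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        ct = CTSlice(rng.uniform(-1200, 400, (20, 20)).astype(np.float32),
                     source="phantom")
        low = binarize_hu(ct, -800.0)
        high = binarize_hu(ct, -400.0)
        assert np.all(low <= high)


class TestOperatorExamples:
    def test_clear_border_keeps_interior(self):
        m = np.zeros((5, 5), np.uint8)
        m[2, 2] = 1
        np.testing.assert_array_equal(clear_border(m), m)
        np.testing.assert_array_equal(clear_border(np.ones((5, 5), np.uint8)),
                                      np.zeros((5, 5), np.uint8))

    def test_label_connectivity(self):
        m = np.zeros((5, 5), np.uint8)
        m[1, 1] = m[2, 2] = 1
        assert label_components(m, connectivity=8).n_labels == 1
        assert label_components(m, connectivity=4).n_labels == 2
        assert label_components(np.zeros((3, 3), np.uint8)).n_labels == 0

    def test_keep_largest_two_by_area(self):
        m = np.zeros((30, 30), np.uint8)
        m[1:6, 1:11] = 1     # area 50
        m[10:15, 1:9] = 1    # area 40
        m[20, 1:4] = 1       # area 3
        kept = keep_largest_k(label_components(m), k=2)
        assert kept.sum() == 90
        assert label_components(kept).n_labels == 2
        # fewer components than k: unchanged
        single = np.zeros((5, 5), np.uint8)
        single[2, 2] = 1
        np.testing.assert_array_equal(
            keep_largest_k(label_components(single), k=2), single
        )

    def test_erode_isolated_pixel_vanishes(self):
        m = np.zeros((5, 5), np.uint8)
        m[2, 2] = 1
        assert erode(m, StructuringElement(2)).sum() == 0
        assert erode(np.zeros((4, 4), np.uint8), StructuringElement(1)).sum() == 0

    def test_dilate_single_pixel_gives_disk_cross(self):
        m = np.zeros((5, 5), np.uint8)
        m[2, 2] = 1
        out = dilate(m, StructuringElement(1))
        expected = np.zeros((5, 5), np.uint8)
        for dy, dx in [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]:
            expected[2 + dy, 2 + dx] = 1
        np.testing.assert_array_equal(out, expected)

    def test_close_fills_slit(self):
        m = np.ones((40, 40), np.uint8)
        m[:, 19:22] = 0  # 3-px slit
        out = close(m, StructuringElement(10))
        assert np.all(out[10:30, 19:22] == 1)
        assert np.all(out >= m)

    def test_fill_holes_ring(self):
        ring = np.ones((5, 5), np.uint8)
        ring[1:4, 1:4] = 0
        ring[2, 2] = 0
        np.testing.assert_array_equal(fill_holes(ring), np.ones((5, 5), np.uint8))
        open_shape = np.zeros((5, 5), np.uint8)
        open_shape[2, 1:4] = 1
        np.testing.assert_array_equal(fill_holes(open_shape), open_shape)

    def test_disk_footprint_definition(self):
        fp = disk_footprint(2)
        dy, dx = np.mgrid[-2:3, -2:3]
        np.testing.assert_array_equal(fp, (dy**2 + dx**2 <= 4).astype(np.uint8))


class TestOracleEquivalence:
    """All operators equal the brute-force set definitions on random masks."""

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_erode_dilate_close_match_oracle(self, radius):
        rng = np.random.default_rng(100 + radius)
        selem = StructuringElement(radius)
        fp = selem.footprint
        for mask in random_masks(rng, 12):
            np.testing.assert_array_equal(erode(mask, selem), brute_erode(mask, fp))
            np.testing.assert_array_equal(dilate(mask, selem), brute_dilate(mask, fp))
            # closing composes the two oracles on the infinite-plane
            # embedding (pad by r so the frame does not clip the dilation)
            padded = np.pad(mask, radius)
            expected = brute_erode(brute_dilate(padded, fp), fp)[
                radius:-radius, radius:-radius
            ]
            np.testing.assert_array_equal(close(mask, selem), expected)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_clear_border_and_label_match_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for mask in random_masks(rng, 15):
            np.testing.assert_array_equal(
                clear_border(mask, connectivity),
                brute_clear_border(mask, connectivity),
            )
            _, n = brute_label(mask, connectivity)
            assert label_components(mask, connectivity).n_labels == n

    def test_fill_holes_matches_oracle(self):
        rng = np.random.default_rng(8)
        for mask in random_masks(rng, 15):
            np.testing.assert_array_equal(fill_holes(mask), brute_fill_holes(mask))

    def test_duality_and_extensivity(self):
        rng = np.random.default_rng(9)
        selem = StructuringElement(2)
        for mask in random_masks(rng, 10, max_size=16):
            er, di = erode(mask, selem), dilate(mask, selem)
            assert np.all(er <= mask) and np.all(mask <= di)
            # dilation of the complement = complement of erosion (padded so
            # the frame border does not enter the duality)
            pad = 3
            padded = np.pad(mask, pad)
            np.testing.assert_array_equal(
                dilate(1 - padded, selem), 1 - erode(padded, selem)
            )
            cl = close(mask, selem)
            np.testing.assert_array_equal(close(cl, selem), cl)  # idempotent


class TestExtractLungMask:
    def test_recovers_phantom_truth(self, default_phantom):
        ct, truth = default_phantom
        result = extract_lung_mask(ct)
        assert dice(result.mask, truth) >= 0.95
        assert not result.needs_review
        assert result.n_components >= 2

    def test_wall_nodule_fully_contained(self):
        spec = PhantomSpec(seed=17, attach_nodule=True, nodule_radius=8.0)
        ct, _, parts = generate_phantom_parts(spec)
        result = extract_lung_mask(ct)
        nodule = parts["nodule"].astype(bool)
        assert nodule.sum() > 0
        assert np.all(result.mask[nodule] == 1)

    def test_all_air_slice_flagged_empty(self, flat_slice):
        with pytest.warns(UserWarning, match="manual review"):
            result = extract_lung_mask(flat_slice(-1000.0, shape=(32, 32)))
        assert result.mask.sum() == 0
        assert result.needs_review

    def test_pipeline_is_pure(self, default_phantom):
        ct, _ = default_phantom
        a = extract_lung_mask(ct)
        b = extract_lung_mask(ct)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_border_blob_removed(self):
        # an extra low-HU blob touching the frame must vanish at step 2
        spec = PhantomSpec(seed=4, noise_sd=0.0)
        ct, truth = generate_phantom(spec)
        pixels = ct.pixels.copy()
        pixels[:6, :6] = spec.lung_hu
        doctored = CTSlice(pixels, source="phantom")
        result = extract_lung_mask(doctored)
        assert np.all(result.mask[:6, :6] == 0)
        assert dice(result.mask, truth) >= 0.95

    def test_jittered_specs_still_recovered(self):
        rng = np.random.default_rng(0)
        for i in range(3):
            spec = jitter_spec(PhantomSpec(seed=40 + i), 0.2, rng)
            ct, truth = generate_phantom(spec)
            assert dice(extract_lung_mask(ct).mask, truth) >= 0.95
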