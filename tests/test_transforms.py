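"""Transform semantics: neutral identities, group structure, mask policy."""

import itertools

import numpy as np
import pytest

from segsense import (
    GrayImage,
    LabelMask,
    Sample,
    adjust_brightness,
    adjust_contrast,
    crop,
    dihedral,
    resize,
    rotate,
    zoom,
)
from segsense.phantom import PhantomSpec, make_phantom
from segsense.transforms import registry_with_size_neutrals


class TestRotate:
    def test_neutral_is_exact_identity(self, asym_sample):
        out = rotate(asym_sample, 0)
        assert np.array_equal(out.image.pixels, asym_sample.image.pixels)
        assert np.array_equal(out.mask.labels, asym_sample.mask.labels)

    def test_quarter_turns_invert_exactly(self, asym_sample):
        out = rotate(rotate(asym_sample, 90), 270)
        assert np.array_equal(out.image.pixels, asym_sample.image.pixels)

    def test_90cw_permutation_on_2x2(self):
        a, b, c, d = 0.1, 0.2, 0.3, 0.4
        img = GrayImage(np.array([[a, b], [c, d]]))
        out = rotate(Sample(img), 90)
        assert np.allclose(out.image.pixels, [[c, a], [d, b]])

    def test_shape_preserved_and_corners_zero(self, phantom_sample):
        out = rotate(phantom_sample, 45)
        assert out.image.shape == phantom_sample.image.shape
        assert out.image.pixels[0, 0] == 0.0

    def test_mask_label_conservation(self, phantom_sample):
        for angle in (17, 45, 120, 275):
            out = rotate(phantom_sample, angle)
            assert set(np.unique(out.mask.labels)) <= set(
                np.unique(phantom_sample.mask.labels)) | {0}


class TestDihedral:
    def test_identity_element(self, asym_sample):
        out = dihedral(asym_sample, 0)
        assert np.array_equal(out.image.pixels, asym_sample.image.pixels)

    def test_eight_distinct_orientations(self, asym_sample):
        arrays = [dihedral(asym_sample, k).image.pixels for k in range(8)]
        for i, j in itertools.combinations(range(8), 2):
            assert not np.array_equal(arrays[i], arrays[j])

    def test_every_element_has_inverse(self, asym_sample):
        for k in range(8):
            once = dihedral(asym_sample, k)
            assert any(
                np.array_equal(dihedral(once, kk).image.pixels,
                               asym_sample.image.pixels)
                for kk in range(8)
            )

    def test_group_closure_all_64_compositions(self, asym_sample):
        orientations = [dihedral(asym_sample, k).image.pixels for k in range(8)]
        for k1, k2 in itertools.product(range(8), repeat=2):
            composed = dihedral(dihedral(asym_sample, k1), k2).image.pixels
            assert any(np.array_equal(composed, o) for o in orientations)

    def test_out_of_range_k_rejected(self, asym_sample):
        with pytest.raises(ValueError):
            dihedral(asym_sample, 8)


class TestCrop:
    def test_full_size_is_identity_on_square(self, phantom_sample):
        out = crop(phantom_sample, min(phantom_sample.image.shape))
        assert np.array_equal(out.image.pixels, phantom_sample.image.pixels)

    def test_central_2x2_of_4x4(self):
        img = GrayImage(np.arange(16, dtype=float).reshape(4, 4) / 15)
        out = crop(Sample(img), 2)
        assert np.allclose(out.image.pixels * 15, [[5, 6], [9, 10]])

    def test_oversize_crop_pads_with_zero_border(self):
        h = 6
        img = GrayImage(np.ones((h, h)))
        out = crop(Sample(img), h + 10)
        assert out.image.shape == (h + 10, h + 10)
        assert np.all(out.image.pixels[:5, :] == 0)
        assert np.all(out.image.pixels[5:5 + h, 5:5 + h] == 1)

    def test_nonpositive_size_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            crop(phantom_sample, 0)


class TestZoom:
    def test_neutral_identity(self, phantom_sample):
        out = zoom(phantom_sample, 1.0)
        assert np.abs(out.image.pixels - phantom_sample.image.pixels).max() < 1e-6

    def test_2x_zoom_quadruples_disk_area(self):
        sample = make_phantom(PhantomSpec(center=(0.5, 0.5), rv_offset=-34,
                                          noise_sd=0.0))
        out = zoom(sample, 2.0)
        before = int((sample.mask.labels == 1).sum())
        after = int((out.mask.labels == 1).sum())
        assert 3.5 <= after / before <= 4.5

    def test_shrink_never_invents_labels(self, phantom_sample):
        out = zoom(phantom_sample, 0.5)
        assert set(np.unique(out.mask.labels)) <= set(
            np.unique(phantom_sample.mask.labels)) | {0}

    def test_nonpositive_scale_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            zoom(phantom_sample, 0.0)


class TestResize:
    def test_same_size_identity(self, phantom_sample):
        out = resize(phantom_sample, phantom_sample.image.shape[0])
        assert np.abs(out.image.pixels - phantom_sample.image.pixels).max() < 1e-6

    def test_upscaling_doubles_disk_diameter(self):
        sample = make_phantom(PhantomSpec(size=64, radii=(16, 20), rv_offset=-26,
                                          rv_radius=6, noise_sd=0.0))
        out = resize(sample, 128)
        row = sample.mask.labels[32]
        width_before = int((row == 1).sum())
        width_after = int((out.mask.labels[64] == 1).sum())
        assert abs(width_after - 2 * width_before) <= 2

    def test_resize_to_one_pixel_defined(self, phantom_sample):
        out = resize(phantom_sample, 1)
        assert out.image.shape == (1, 1)
        assert out.mask.shape == (1, 1)

    def test_nonpositive_size_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            resize(phantom_sample, 0)


class TestIntensity:
    def test_brightness_neutral_and_saturation(self, phantom_sample):
        assert np.array_equal(
            adjust_brightness(phantom_sample, 0.0).image.pixels,
            phantom_sample.image.pixels,
        )
        assert np.all(adjust_brightness(phantom_sample, 1.0).image.pixels == 1.0)

    def test_brightness_add_and_clip(self):
        img = GrayImage(np.array([[0.0, 0.5, 0.9]]))
        out = adjust_brightness(Sample(img), 0.25)
        assert np.allclose(out.image.pixels, [[0.25, 0.75, 1.0]])

    def test_contrast_affine_about_midgray(self):
        img = GrayImage(np.array([[0.25, 0.5, 0.75]]))
        out = adjust_contrast(Sample(img), 2.0)
        assert np.allclose(out.image.pixels, [[0.0, 0.5, 1.0]])

    def test_contrast_neutral_and_saturation(self):
        img = GrayImage(np.array([[0.4, 0.6]]))
        assert np.array_equal(adjust_contrast(Sample(img), 1.0).image.pixels,
                              img.pixels)
        assert np.allclose(adjust_contrast(Sample(img), 100.0).image.pixels,
                           [[0.0, 1.0]])

    def test_nonpositive_contrast_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            adjust_contrast(phantom_sample, 0.0)

    def test_mask_object_untouched(self, phantom_sample):
        out = adjust_brightness(phantom_sample, 0.3)
        assert out.mask is phantom_sample.mask


class TestRegistry:
    def test_mask_policy_dichotomy(self, registry):
        geometric = {"rotate", "dihedral", "flip", "crop", "zoom", "resize"}
        intensity = {"brightness", "contrast", "spike"}
        for name, spec in registry.items():
            assert spec.is_geometric == (name in geometric)
        assert geometric | intensity == set(registry)

    def test_neutral_value_identity_for_all(self, phantom_sample):
        reg = registry_with_size_neutrals(phantom_sample)
        for name, spec in reg.items():
            out = spec.apply(phantom_sample, spec.neutral_value)
            assert np.abs(out.image.pixels - phantom_sample.image.pixels).max() < 1e-6, name
            if spec.is_geometric:
                assert np.array_equal(out.mask.labels, phantom_sample.mask.labels), name
            else:
                assert out.mask is phantom_sample.mask, name

    def test_geometric_label_conservation(self, phantom_sample, registry):
        reg = registry_with_size_neutrals(phantom_sample)
        in_labels = set(np.unique(phantom_sample.mask.labels))
        for name, spec in reg.items():
            if not spec.is_geometric:
                continue
            for value in spec.default_grid:
                out = spec.apply(phantom_sample, value)
                assert set(np.unique(out.mask.labels)) <= in_labels | {0}, (name, value)
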