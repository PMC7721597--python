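"""Colour-code encoding/decoding of tissue masks and dataset filtering."""

import numpy as np
import pytest

from kneeseg.label_codec import (
    DEFAULT_SCHEME,
    LabelImage,
    LabelScheme,
    TissueMask,
    decode_tissue_mask,
    encode_labels,
    filter_dataset,
    is_noise_only,
    load_label_png,
    load_mask_nifti,
    save_label_png,
    save_mask_nifti,
    stack_slices,
)


def mask(arr, spacing=(1.0, 1.0), name="femur"):
    return TissueMask(np.asarray(arr, dtype=bool), spacing, name)


def blank(shape=(4, 4)):
    return np.zeros(shape, dtype=bool)


class TestScheme:
    def test_default_codes(self):
        # blue: bones + ACL; green: cartilages + PCL; red: muscles
        expected = {
            "femur": (2, 50), "tibia": (2, 100), "patella": (2, 150),
            "acl": (2, 200), "femoral_cartilage": (1, 50),
            "tibial_cartilage": (1, 100), "patellar_cartilage": (1, 150),
            "pcl": (1, 200), "vastus_medialis": (0, 100),
            "medial_gastrocnemius": (0, 200),
        }
        for tissue, chcode in expected.items():
            assert DEFAULT_SCHEME.lookup(tissue) == chcode
        assert DEFAULT_SCHEME.tolerance == 20

    def test_ambiguous_codes_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            LabelScheme(entries=(("a", "blue", 50), ("b", "blue", 80)))

    def test_code_zero_reserved(self):
        with pytest.raises(ValueError):
            LabelScheme(entries=(("a", "blue", 0),))

    def test_unknown_tissue(self):
        with pytest.raises(KeyError):
            DEFAULT_SCHEME.lookup("meniscus")


class TestEncode:
    def test_single_femur_pixel_gets_blue_50(self):
        m = blank()
        m[1, 2] = True
        label = encode_labels({"femur": mask(m)})
        assert tuple(label.data[1, 2]) == (0, 0, 50)
        assert label.data.sum() == 50

    def test_empty_masks_give_all_zero(self):
        label = encode_labels({"femur": mask(blank()), "pcl": mask(blank(), name="pcl")})
        assert not label.data.any()

    def test_cross_channel_overlap_allowed(self):
        m = blank()
        m[0, 0] = True
        label = encode_labels({
            "femur": mask(m),
            "femoral_cartilage": mask(m.copy(), name="femoral_cartilage"),
        })
        assert tuple(label.data[0, 0]) == (0, 50, 50)

    def test_same_channel_overlap_is_error(self):
        m = blank()
        m[0, 0] = True
        with pytest.raises(ValueError, match="same channel"):
            encode_labels({"femur": mask(m), "tibia": mask(m.copy(), name="tibia")})

    def test_shape_mismatch_and_unknown_name(self):
        with pytest.raises(ValueError, match="shape"):
            encode_labels({"femur": mask(blank((4, 4))),
                           "tibia": mask(blank((5, 5)), name="tibia")})
        with pytest.raises(KeyError):
            encode_labels({"meniscus": mask(blank(), name="meniscus")})


class TestDecode:
    def test_tolerance_band(self):
        # |60-50| = 10 inside; |75-50| = 25 and |75-100| = 25 outside both;
        # bounds are inclusive: 70 decodes, 71 does not
        data = np.zeros((1, 4, 3), dtype=np.uint8)
        data[0, :, 2] = [60, 75, 70, 71]
        label = LabelImage(data)
        femur = decode_tissue_mask(label, "femur").data[0]
        tibia = decode_tissue_mask(label, "tibia").data[0]
        assert femur.tolist() == [True, False, True, False]
        assert tibia.tolist() == [False, False, False, False]

    def test_all_zero_label_decodes_empty_everywhere(self):
        label = LabelImage(np.zeros((3, 3, 3), dtype=np.uint8))
        for tissue in DEFAULT_SCHEME.tissues:
            assert not decode_tissue_mask(label, tissue).data.any()

    def test_roundtrip_random_mask_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            masks = _random_valid_masks(rng)
            label = encode_labels(masks)
            for tissue, m in masks.items():
                decoded = decode_tissue_mask(label, tissue)
                np.testing.assert_array_equal(decoded.data, m.data)

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        label = LabelImage(data)
        for tissue in ("femur", "pcl", "vastus_medialis"):
            prev = None
            for tol in (5, 10, 20):
                entries = DEFAULT_SCHEME.entries
                scheme = LabelScheme(entries=entries, tolerance=tol)
                cur = decode_tissue_mask(label, tissue, scheme).data
                if prev is not None:
                    assert (prev <= cur).all()  # smaller tolerance ⊆ larger
                prev = cur

    def test_within_channel_decodes_disjoint(self):
        rng = np.random.default_rng(2)
        data = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        label = LabelImage(data)
        for pair in (("femur", "tibia"), ("femur", "patella"),
                     ("tibial_cartilage", "pcl")):
            a = decode_tissue_mask(label, pair[0]).data
            b = decode_tissue_mask(label, pair[1]).data
            assert not (a & b).any()


def _random_valid_masks(rng, shape=(16, 16)):
    """Random mask per tissue, disjoint within each channel by construction."""
    claimed = {ch: np.zeros(shape, dtype=bool) for ch in range(3)}
    masks = {}
    for name, channel, _ in DEFAULT_SCHEME.entries:
        ch = {"red": 0, "green": 1, "blue": 2}[channel]
        m = rng.random(shape) < 0.15
        m &= ~claimed[ch]
        claimed[ch] |= m
        masks[name] = TissueMask(m, (1.0, 1.0), name)
    return masks


class TestStacking:
    def test_stack_shape_and_order(self):
        slices = []
        for k in range(3):
            m = blank()
            m[k, :] = True
            slices.append(mask(m))
        vol = stack_slices(slices, slice_spacing=2.0)
        assert vol.data.shape == (3, 4, 4)
        assert vol.spacing == (2.0, 1.0, 1.0)
        for k in range(3):
            np.testing.assert_array_equal(vol.data[k], slices[k].data)
        assert vol.data.sum() == sum(s.data.sum() for s in slices)

    def test_stack_errors(self):
        with pytest.raises(ValueError):
            stack_slices([], 1.0)
        with pytest.raises(ValueError, match="shape"):
            stack_slices([mask(blank((4, 4))), mask(blank((5, 5)))], 1.0)


class TestNoiseOnly:
    def test_detection_is_strict(self):
        zero = LabelImage(np.zeros((4, 4, 3), dtype=np.uint8))
        assert is_noise_only(zero)
        one = np.zeros((4, 4, 3), dtype=np.uint8)
        one[2, 2, 1] = 1
        assert not is_noise_only(LabelImage(one))

    def test_filtering_counts_and_order(self):
        zero = LabelImage(np.zeros((4, 4, 3), dtype=np.uint8))
        m = blank()
        m[0, 0] = True
        full = encode_labels({"femur": mask(m)})
        pairs = [(0, full), (1, zero), (2, full), (3, zero), (4, full)]
        kept = filter_dataset(pairs, keep_noise_only=False)
        assert [s for s, _ in kept] == [0, 2, 4]
        assert filter_dataset(pairs, keep_noise_only=True) == pairs
        assert filter_dataset([], keep_noise_only=False) == []


class TestIO:
    def test_label_png_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        label = LabelImage(rng.integers(0, 256, (8, 8, 3)).astype(np.uint8),
                           subject_id="subj01", slice_index=7)
        path = tmp_path / "subj01_0007.png"
        save_label_png(label, path)
        back = load_label_png(path)
        np.testing.assert_array_equal(back.data, label.data)
        assert back.subject_id == "subj01"
        assert back.slice_index == 7

    def test_nifti_roundtrip_preserves_spacing(self, tmp_path):
        rng = np.random.default_rng(4)
        vol = TissueMask(rng.random((5, 6, 7)) < 0.3, (1.0, 0.29, 0.29), "femur")
        path = tmp_path / "femur.nii"
        save_mask_nifti(vol, path)
        back = load_mask_nifti(path, tissue_name="femur")
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing == pytest.approx(vol.spacing)
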