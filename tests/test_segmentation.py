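import numpy as np
import pytest

from crabgrade.evaluation import mask_iou
from crabgrade.io_annotations import (
    PolygonAnnotation,
    Sex,
    ValidationError,
    rasterize_polygon,
)
from crabgrade.segmentation import (
    DEFAULT_BACKGROUND_RGB,
    Integrity,
    SegmentationResult,
    augment_joint,
    check_integrity,
    classify_sex,
    segment_baseline,
)
from crabgrade.synthetic import PhantomSpec, generate_phantom

BG = DEFAULT_BACKGROUND_RGB


def blank(h=100, w=100):
    img = np.empty((h, w, 3), np.uint8)
    img[:] = BG
    return img


class TestBaselineSegmenter:
    def test_background_only_empty_list(self):
        assert segment_baseline(blank()) == []

    def test_phantom_carapace_iou(self, male_phantom):
        results = segment_baseline(male_phantom.dorsal_image)
        assert results[0].class_label == "carapace"
        assert mask_iou(results[0].mask, male_phantom.carapace_mask) >= 0.95

    def test_min_region_px_separates_blobs(self):
        img = blank()
        img[10:40, 10:40] = (0, 0, 0)  # 900 px
        img[60:66, 60:66] = (0, 0, 0)  # 36 px
        results = segment_baseline(img, min_region_px=100)
        assert len(results) == 1
        assert results[0].mask.sum() == 900

    def test_results_sorted_largest_first_with_confidence_one(self):
        img = blank()
        img[5:25, 5:25] = (0, 0, 0)
        img[50:90, 50:90] = (0, 0, 0)
        results = segment_baseline(img, min_region_px=10)
        sizes = [r.mask.sum() for r in results]
        assert sizes == sorted(sizes, reverse=True)
        assert all(r.confidence == 1.0 for r in results)

    def test_deterministic(self, male_phantom):
        r1 = segment_baseline(male_phantom.dorsal_image)
        r2 = segment_baseline(male_phantom.dorsal_image)
        assert [r.class_label for r in r1] == [r.class_label for r in r2]
        assert all(np.array_equal(a.mask, b.mask) for a, b in zip(r1, r2))

    def test_phantom_component_classes(self, male_phantom):
        from collections import Counter

        counts = Counter(r.class_label for r in segment_baseline(male_phantom.dorsal_image))
        assert counts["carapace"] == 1
        assert counts["calibration_marker"] == 1
        assert counts["limb"] == 10

    def test_bbox_tightly_bounds_mask(self, male_phantom):
        for r in segment_baseline(male_phantom.dorsal_image):
            rows, cols = np.nonzero(r.mask)
            assert r.bbox == (cols.min(), rows.min(), cols.max(), rows.max())


class TestSexClassification:
    @staticmethod
    def flap_mask(kind, half_w=40, canvas=140):
        c = canvas / 2
        if kind == "triangle":
            pts = [(c - half_w, c - 30), (c + half_w, c - 30), (c, c + 35)]
        elif kind == "semicircle":
            phi = np.linspace(np.pi, 2 * np.pi, 49)
            pts = [(c + half_w * np.cos(p), c - half_w * np.sin(p)) for p in phi]
        else:  # circle
            phi = np.linspace(0, 2 * np.pi, 72, endpoint=False)
            pts = [(c + half_w * np.cos(p), c + half_w * np.sin(p)) for p in phi]
        ann = PolygonAnnotation(
            label="abdomen_male", points=tuple(pts), image_width=canvas, image_height=canvas
        )
        return rasterize_polygon(ann)

    def test_triangular_flap_is_male(self):
        sex, score = classify_sex(self.flap_mask("triangle"))
        assert sex is Sex.male
        assert 0 <= score <= 1

    def test_semicircular_flap_is_female(self):
        sex, _ = classify_sex(self.flap_mask("semicircle"))
        assert sex is Sex.female

    def test_circle_is_maximally_female(self):
        sex, score = classify_sex(self.flap_mask("circle"))
        assert sex is Sex.female
        assert score == pytest.approx(1.0, abs=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            classify_sex(np.zeros((10, 10), bool))

    def test_phantom_flaps_agree_with_truth(self):
        """Flap-shape sex call matches the generator over varied phantoms."""
        rng = np.random.default_rng(88)
        for k in range(40):
            sex = Sex.male if k % 2 == 0 else Sex.female
            a = float(rng.uniform(2.5, 3.6))
            ph = generate_phantom(
                PhantomSpec(
                    seed=9000 + k,
                    sex=sex,
                    carapace_semiaxes_cm=(a, a * float(rng.uniform(0.75, 0.95))),
                    noise_sigma=2.0,
                )
            )
            results = segment_baseline(ph.ventral_image)
            called, _ = classify_sex(results[0].mask)
            assert called is sex


class TestIntegrity:
    @staticmethod
    def limbs(n):
        out = []
        for _ in range(n):
            m = np.zeros((5, 5), bool)
            m[1:4, 1:4] = True
            out.append(m)
        return out

    def test_full_count_intact(self):
        assert check_integrity(self.limbs(10)) is Integrity.intact

    def test_missing_limbs_incomplete(self):
        assert check_integrity(self.limbs(8)) is Integrity.incomplete

    def test_configurable_expectation(self):
        assert check_integrity(self.limbs(8), expected_limb_count=8) is Integrity.intact

    def test_phantom_with_missing_limbs(self):
        ph = generate_phantom(PhantomSpec(seed=3, n_limbs_missing=2, noise_sigma=0.0))
        limbs = [r.mask for r in segment_baseline(ph.dorsal_image) if r.class_label == "limb"]
        assert len(limbs) == 8
        assert check_integrity(limbs) is Integrity.incomplete


class TestAugmentJoint:
    @staticmethod
    def scene():
        img = blank(128, 128)
        pts = [(40.0, 50.0), (90.0, 45.0), (95.0, 80.0), (50.0, 90.0)]
        ann = PolygonAnnotation(
            label="carapace", points=tuple(pts), image_width=128, image_height=128
        )
        img[rasterize_polygon(ann)] = (60, 90, 50)
        return img, [ann]

    def test_full_turn_is_identity_on_polygons(self):
        img, anns = self.scene()
        _, out = augment_joint(img, anns, [{"op": "rotate", "deg": 360.0}])
        assert np.allclose(out[0].points, anns[0].points, atol=1e-6)

    def test_double_flip_is_identity(self):
        img, anns = self.scene()
        ops = [{"op": "flip", "axis": "horizontal"}, {"op": "flip", "axis": "horizontal"}]
        _, out = augment_joint(img, anns, ops)
        assert np.allclose(out[0].points, anns[0].points, atol=1e-9)

    def test_scale_quadruples_area(self):
        img, anns = self.scene()
        # shrink so the scaled polygon stays inside the canvas
        _, shrunk = augment_joint(img, anns, [{"op": "scale", "s": 0.5}])
        _, scaled = augment_joint(img, shrunk, [{"op": "scale", "s": 2.0}])
        a0 = rasterize_polygon(shrunk[0]).sum()
        a1 = rasterize_polygon(scaled[0]).sum()
        assert a1 / a0 == pytest.approx(4.0, rel=0.02)

    def test_nonpositive_scale_rejected(self):
        img, anns = self.scene()
        with pytest.raises(ValidationError):
            augment_joint(img, anns, [{"op": "scale", "s": 0.0}])

    def test_noise_leaves_polygons_untouched(self):
        img, anns = self.scene()
        out_img, out = augment_joint(img, anns, [{"op": "noise", "sigma": 5.0}], seed=1)
        assert out[0].points == anns[0].points
        assert not np.array_equal(out_img, img)

    def test_noise_seeded_reproducible(self):
        img, anns = self.scene()
        ops = [{"op": "noise", "sigma": 5.0}]
        img1, _ = augment_joint(img, anns, ops, seed=7)
        img2, _ = augment_joint(img, anns, ops, seed=7)
        assert np.array_equal(img1, img2)

    @pytest.mark.parametrize("theta,s", [(15.0, 1.0), (-45.0, 1.0), (30.0, 0.6), (10.0, 1.4)])
    def test_raster_polygon_correspondence(self, theta, s):
        """Warping the mask vs rasterizing the warped polygon: IoU >= 0.9."""
        from crabgrade.evaluation import mask_iou

        img, anns = self.scene()
        mask = rasterize_polygon(anns[0])
        ops = [{"op": "rotate", "deg": theta}, {"op": "scale", "s": s}]
        warped_mask, _ = augment_joint(mask, anns, ops)
        _, out_anns = augment_joint(img, anns, ops)
        assert mask_iou(warped_mask, rasterize_polygon(out_anns[0])) >= 0.9
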