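"""Unsupervised extraction: edge detection, opening, fill/select, QC."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import circle_perimeter
from skimage.feature import canny as reference_canny

from pollenseg.pseudolabel import (
    ExtractionConfig,
    canny_edges,
    extract_pseudo_mask,
    fill_and_select,
    open_contours,
    qc_mask,
)
from pollenseg.synth import SyntheticSpec, generate_sample

from conftest import iou

CFG = ExtractionConfig()


class TestCannyEdges:
    def test_constant_image_has_no_edges(self):
        img = np.full((40, 40), 128, dtype=np.uint8)
        assert not canny_edges(img, CFG).any()

    def test_step_edge_localized_within_one_column(self):
        c = 20
        img = np.zeros((40, 40), dtype=np.uint8)
        img[:, c:] = 200
        edges = canny_edges(img, CFG)
        rows, cols = np.nonzero(edges)
        assert len(cols) > 0
        assert (np.abs(cols - c) <= 1).all()

    def test_weak_edges_survive_only_when_linked_to_strong(self):
        # a step of 30 produces gradients between the two thresholds only
        img = np.zeros((40, 40), dtype=np.uint8)
        img[:, 20:] = 30
        assert not canny_edges(img, CFG).any()

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            canny_edges(np.zeros((4, 4, 3)), CFG)

    def test_agrees_with_reference_canny_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        ious = []
        for _ in range(50):
            f = ndi.gaussian_filter(rng.normal(size=(32, 32)), 2.5)
            f = (f - f.min()) / (f.max() - f.min())
            img = (f * 255).astype(np.uint8)
            mine = canny_edges(img, CFG)
            ref = reference_canny(
                img.astype(float) / 255.0,
                sigma=CFG.sigma,
                low_threshold=CFG.low_threshold / 255.0,
                high_threshold=CFG.high_threshold / 255.0,
            )
            ious.append(iou(mine, ref))
        assert min(ious) >= 0.9


class TestOpenContours:
    def test_isolated_pixel_removed(self):
        e = np.zeros((20, 20), dtype=bool)
        e[10, 10] = True
        assert not open_contours(e, ExtractionConfig(open_radius=1)).any()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(size=(40, 40)) > 0.7
        once = open_contours(e, CFG)
        assert np.array_equal(once, open_contours(once, CFG))

    def test_closed_contour_area_preserved(self):
        e = np.zeros((60, 60), dtype=bool)
        rr, cc = circle_perimeter(30, 30, 20)
        e[rr, cc] = True
        opened = open_contours(e, ExtractionConfig(open_radius=2))
        before, _ = fill_and_select(e, CFG)
        after, _ = fill_and_select(opened, CFG)
        assert abs(after.sum() - before.sum()) <= 0.1 * before.sum()


class TestFillAndSelect:
    def test_circle_contour_fills_to_disk(self):
        e = np.zeros((40, 40), dtype=bool)
        rr, cc = circle_perimeter(20, 20, 10)
        e[rr, cc] = True
        mask, found = fill_and_select(e, CFG)
        assert found
        assert mask.sum() == pytest.approx(np.pi * 100, rel=0.15)

    def test_small_speck_filtered_by_relative_area(self):
        e = np.zeros((60, 60), dtype=bool)
        rr, cc = circle_perimeter(25, 25, 10)
        e[rr, cc] = True
        e[50:54, 50:54] = True  # tiny closed square speck
        e[51:53, 51:53] = False
        mask, found = fill_and_select(e, ExtractionConfig(area_keep_frac=0.5))
        assert found
        assert mask[25, 25] and not mask[51, 51]

    def test_equal_area_ties_both_kept(self):
        e = np.zeros((40, 80), dtype=bool)
        for c0 in (20, 60):
            rr, cc = circle_perimeter(20, c0, 10)
            e[rr, cc] = True
        mask, found = fill_and_select(e, ExtractionConfig(area_keep_frac=1.0))
        assert found
        assert mask[20, 20] and mask[20, 60]

    def test_no_closed_region_returns_empty_with_flag(self):
        e = np.zeros((30, 30), dtype=bool)
        e[15, 5:25] = True  # open line encloses nothing
        mask, found = fill_and_select(e, CFG)
        assert not found and not mask.any()

    def test_output_inside_union_of_closed_regions(self):
        # monotonicity: foreground never exceeds the filled input regions
        rng = np.random.default_rng(2)
        for _ in range(20):
            e = ndi.binary_dilation(rng.uniform(size=(32, 32)) > 0.92)
            mask, _ = fill_and_select(e, CFG)
            labels, _ = ndi.label(~e, structure=ndi.generate_binary_structure(2, 1))
            border_ids = np.unique(np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
            background = np.isin(labels, border_ids[border_ids > 0])
            assert not (mask & background).any()


class TestQC:
    def test_accepts_reasonable_fraction(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:27, 5:27] = True  # fraction ~0.30
        res = qc_mask(m, CFG)
        assert res.accepted and res.reason is None

    def test_rejects_empty(self):
        res = qc_mask(np.zeros((10, 10), dtype=bool), CFG)
        assert not res.accepted and res.reason == "empty"

    def test_rejects_too_large(self):
        m = np.ones((20, 20), dtype=bool)
        m[0, 0] = False
        res = qc_mask(m, CFG)
        assert not res.accepted and res.reason == "too_large"

    def test_rejects_multi_component(self):
        m = np.zeros((64, 64), dtype=bool)
        m[4:24, 4:24] = True
        m[40:60, 40:60] = True
        res = qc_mask(m, CFG)
        assert not res.accepted and res.reason == "multi_component"


class TestExtractPseudoMask:
    def test_clean_sample_high_iou(self, clean_sample):
        mask, qc = extract_pseudo_mask(clean_sample.image, CFG)
        assert qc.accepted
        assert iou(mask, clean_sample.gt_mask) >= 0.9

    def test_constant_image_rejected(self):
        mask, qc = extract_pseudo_mask(np.full((64, 64), 100, dtype=np.uint8), CFG)
        assert not qc.accepted and not mask.any()

    def test_detached_impurities_absent_from_mask(self):
        # impurity components clear of the particle must never enter the mask
        # (those touching its rim merge with the contour — the failure mode the
        # activation-map refinement stage exists to fix)
        spec = SyntheticSpec(impurity_count_range=(5, 5), overlap_prob=0.0, noise_sd=0.0, seed=2)
        s = generate_sample(spec)
        mask, qc = extract_pseudo_mask(s.image, CFG)
        comp, n = ndi.label(s.impurity_mask)
        dist = ndi.distance_transform_edt(~s.gt_mask)
        detached = [comp == i for i in range(1, n + 1) if dist[comp == i].min() > 5]
        assert qc.accepted
        assert detached, "fixture must contain clearly detached impurities"
        for blob in detached:
            assert not (mask & blob).any()

    def test_retained_component_contains_particle_centroid(self):
        hits = 0
        total = 0
        for seed in range(100):
            s = generate_sample(SyntheticSpec(class_id=seed % 3, seed=seed))
            mask, qc = extract_pseudo_mask(s.image, CFG)
            if not qc.accepted:
                continue
            total += 1
            rr, cc = np.nonzero(s.gt_mask)
            hits += bool(mask[int(rr.mean()), int(cc.mean())])
        assert total >= 50  # extraction succeeds on most study-condition samples
        assert hits == total
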