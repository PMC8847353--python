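"""ROI rubric scoring, automated placement, and rank-based AUC."""

import itertools

import numpy as np
import pytest

import patquant as pq
from patquant.roi_scoring import PlacementSpec


def make_cmap(counts, spacing=(0.06, 0.06), valid=None):
    return pq.CompositionMap(
        counts=np.asarray(counts, dtype=np.int16), n_slices=3,
        channel="pat_lipid", valid=valid, spacing=spacing,
    )


def full_roi(cmap, label="non_cancerous"):
    """ROI covering the whole (square-pixel) map."""
    h, w = cmap.counts.shape
    return pq.ROIBox("s", "anterior", 1, origin_mm=(0.0, 0.0),
                     side_mm=h * 0.06, label=label)


class TestVascularLipidRubric:
    def test_all_zero_roi_scores_1(self):
        cmap = make_cmap(np.zeros((11, 11)))
        assert pq.score_roi_vascular_lipid(cmap, full_roi(cmap)).score == 1

    def test_60pct_count2_scores_3(self):
        counts = np.zeros((10, 10), int)
        counts[:6, :] = 2  # 60% of pixels at count 2
        cmap = make_cmap(counts)
        assert pq.score_roi_vascular_lipid(cmap, full_roi(cmap)).score == 3

    def test_30pct_count2_scores_2(self):
        counts = np.zeros((10, 10), int)
        counts[:3, :] = 2  # fails the 50% clause but has positives
        cmap = make_cmap(counts)
        assert pq.score_roi_vascular_lipid(cmap, full_roi(cmap)).score == 2

    def test_count1_only_scores_2(self):
        counts = np.ones((10, 10), int)
        cmap = make_cmap(counts)
        assert pq.score_roi_vascular_lipid(cmap, full_roi(cmap)).score == 2

    def test_exactly_50pct_count2_scores_3(self):
        counts = np.zeros((10, 10), int)
        counts[:5, :] = 2
        cmap = make_cmap(counts)
        assert pq.score_roi_vascular_lipid(cmap, full_roi(cmap)).score == 3


class TestNucleiRubric:
    def test_all_zero_roi_scores_1(self):
        cmap = make_cmap(np.zeros((11, 11)))
        assert pq.score_roi_nuclei(cmap, full_roi(cmap)).score == 1

    def test_single_count2_pixel_scores_3(self):
        counts = np.zeros((11, 11), int)
        counts[5, 5] = 2
        cmap = make_cmap(counts)
        assert pq.score_roi_nuclei(cmap, full_roi(cmap)).score == 3

    def test_count1_pixels_only_score_2(self):
        counts = np.zeros((11, 11), int)
        counts[2:4, 2:4] = 1
        cmap = make_cmap(counts)
        assert pq.score_roi_nuclei(cmap, full_roi(cmap)).score == 2


class TestRubricProperties:
    @pytest.mark.parametrize("scorer", [pq.score_roi_vascular_lipid,
                                        pq.score_roi_nuclei])
    def test_all_S_roi_scores_3(self, scorer):
        cmap = make_cmap(np.full((10, 10), 3))
        assert scorer(cmap, full_roi(cmap)).score == 3

    @pytest.mark.parametrize("scorer", [pq.score_roi_vascular_lipid,
                                        pq.score_roi_nuclei])
    def test_raising_a_count_never_lowers_the_score(self, rng, scorer):
        for _ in range(30):
            counts = rng.integers(0, 4, (8, 8))
            cmap = make_cmap(counts)
            base = scorer(cmap, full_roi(cmap)).score
            bumped = counts.copy()
            i, j = rng.integers(0, 8, 2)
            bumped[i, j] = min(3, bumped[i, j] + 1)
            assert scorer(make_cmap(bumped), full_roi(cmap)).score >= base

    def test_roi_outside_map_rejected(self):
        cmap = make_cmap(np.zeros((8, 8)))
        roi = pq.ROIBox("s", "anterior", 1, origin_mm=(0.3, 0.3), side_mm=0.66)
        with pytest.raises(ValueError, match="outside"):
            pq.score_roi_vascular_lipid(cmap, roi)

    def test_mostly_masked_roi_rejected(self):
        counts = np.zeros((11, 11), int)
        valid = np.zeros((11, 11), bool)
        valid[:2, :] = True  # well under 50% valid
        cmap = make_cmap(counts, valid=valid)
        with pytest.raises(ValueError, match="valid"):
            pq.score_roi_vascular_lipid(cmap, full_roi(cmap))

    def test_unknown_rubric_rejected(self):
        cmap = make_cmap(np.zeros((11, 11)))
        with pytest.raises(ValueError, match="rubric"):
            pq.score_roi(cmap, full_roi(cmap), "texture")


class TestPlacement:
    def _label_maps_from_phantom(self, phantom):
        from patquant.pipeline import _labels_on_grid
        from patquant.volume_io import default_regions

        truth, ant, post = phantom
        maps = {}
        for side, chans in (("anterior", ant), ("posterior", post)):
            grid = _labels_on_grid(truth, chans["pat_lipid"], side)
            for r in default_regions(grid.shape[0], 5, side=side):
                maps[("s", side, r.region_index)] = grid[r.histology_slice]
        return maps

    def test_20_plus_30_rois_placed_nonoverlapping_with_correct_labels(
        self, phantom_default
    ):
        maps = self._label_maps_from_phantom(phantom_default)
        spec = PlacementSpec(n_cancerous=20, n_non_cancerous=30)
        rois = pq.place_rois(
            maps, (0.05, 0.05), spec, seed=11,
            carcinoma_label=pq.CARCINOMA,
            content_labels=(pq.ADIPOSE, pq.STROMA, pq.DUCT_WALL, pq.VESSEL),
        )
        assert len(rois) == 50
        assert sum(r.label == "cancerous" for r in rois) == 20
        # label audit: cancerous ROI centers sit on carcinoma
        for r in rois:
            lab = maps[(r.sample_id, r.side, r.region_index)]
            ci = int(round(r.origin_mm[0] / 0.05)) + 6
            cj = int(round(r.origin_mm[1] / 0.05)) + 6
            if r.label == "cancerous":
                assert lab[ci, cj] == pq.CARCINOMA
            else:
                win = lab[ci - 6 : ci + 7, cj - 6 : cj + 7]
                assert not (win == pq.CARCINOMA).any()
        # overlap audit within each map
        for key in maps:
            boxes = [r for r in rois
                     if (r.sample_id, r.side, r.region_index) == key]
            for a, b in itertools.combinations(boxes, 2):
                sep = max(abs(a.origin_mm[0] - b.origin_mm[0]),
                          abs(a.origin_mm[1] - b.origin_mm[1]))
                assert sep >= a.side_mm - 0.051  # disjoint up to one pixel

    def test_carcinoma_free_phantom_rejects_cancerous_request(self):
        maps = {("s", "anterior", 1): np.full((40, 40), pq.STROMA)}
        with pytest.raises(ValueError, match="insufficient"):
            pq.place_rois(maps, (0.05, 0.05), PlacementSpec(5, 0), seed=1,
                          carcinoma_label=pq.CARCINOMA,
                          content_labels=(pq.STROMA,))

    def test_same_seed_reproducible(self, phantom_default):
        maps = self._label_maps_from_phantom(phantom_default)
        spec = PlacementSpec(n_cancerous=5, n_non_cancerous=5)
        kw = dict(carcinoma_label=pq.CARCINOMA,
                  content_labels=(pq.ADIPOSE, pq.STROMA))
        a = pq.place_rois(maps, (0.05, 0.05), spec, seed=11, **kw)
        b = pq.place_rois(maps, (0.05, 0.05), spec, seed=11, **kw)
        assert a == b


class TestAUC:
    def test_identical_scores_give_half(self):
        assert pq.auc_from_scores([2] * 10, ["cancerous"] * 4 +
                                  ["non_cancerous"] * 6) == 0.5

    def test_perfect_separation_with_lipid_polarity(self):
        scores = [1] * 5 + [3] * 5
        labels = ["cancerous"] * 5 + ["non_cancerous"] * 5
        assert pq.auc_from_scores(scores, labels, polarity="lower_positive") == 1.0

    def test_six_observation_ties_match_pairwise_oracle(self):
        scores = np.array([1, 2, 2, 3, 1, 2])
        labels = np.array(["cancerous", "cancerous", "non_cancerous",
                           "non_cancerous", "non_cancerous", "cancerous"])
        # brute force: mean over all (positive, negative) pairs with ties = 1/2
        pos = scores[labels == "cancerous"]
        neg = scores[labels == "non_cancerous"]
        oracle = np.mean([
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        ])
        assert pq.auc_from_scores(scores, labels) == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pq.auc_from_scores([1, 2], ["cancerous", "cancerous"])

    def test_polarity_inversion_is_complementary(self, rng):
        scores = rng.integers(1, 4, 20)
        labels = np.where(rng.random(20) < 0.5, "cancerous", "non_cancerous")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "cancerous", "non_cancerous"
        hi = pq.auc_from_scores(scores, labels, "higher_positive")
        lo = pq.auc_from_scores(scores, labels, "lower_positive")
        assert hi + lo == pytest.approx(1.0)
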