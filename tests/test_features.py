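import numpy as np
import pytest
from scipy import ndimage as ndi

from egohand.config import FeatureConfig
from egohand.detection import BoundingBox
from egohand.features import (RegionSet, assemble_feature, bhattacharyya,
                              colour_feature, dense_flow, fit_shape_pca,
                              motion_feature, raw_hog, shape_feature)
from .conftest import make_frame


def _textured_frame(seed=0, shape=(60, 80), shift=0):
    rng = np.random.default_rng(seed)
    base = ndi.gaussian_filter(rng.random(shape), 2.0)
    img = np.clip(base * 255, 0, 255).astype(np.uint8)
    img = np.roll(img, shift, axis=1)
    return make_frame(np.stack([img] * 3, -1))


def _regions(shape, box):
    hand = np.zeros(shape, bool)
    hand[box.y + 2:box.y + box.h - 2, box.x + 2:box.x + box.w - 2] = True
    return RegionSet.from_segment(shape, hand, box)


class TestDenseFlow:
    def test_identical_frames_give_no_motion(self):
        f = _textured_frame(0)
        flow = dense_flow(f, f)
        assert np.median(np.hypot(flow[..., 0], flow[..., 1])) < 0.1

    def test_three_pixel_shift_recovered(self):
        a = _textured_frame(1)
        b = _textured_frame(1, shift=3)
        flow = dense_flow(a, b)
        assert 2.5 <= np.median(flow[..., 1]) <= 3.5
        assert -0.5 <= np.median(flow[..., 0]) <= 0.5

    def test_uncorrelated_noise_is_finite(self):
        rng = np.random.default_rng(2)
        a = make_frame(rng.integers(0, 255, (40, 50, 3)).astype(np.uint8))
        b = make_frame(rng.integers(0, 255, (40, 50, 3)).astype(np.uint8))
        assert np.isfinite(dense_flow(a, b)).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            dense_flow(_textured_frame(0, (40, 50)),
                       _textured_frame(0, (40, 60)))


class TestMotionFeature:
    def test_length_is_60(self):
        shape = (60, 80)
        flow = np.zeros((*shape, 2))
        out = motion_feature(flow, _regions(shape, BoundingBox(10, 10, 30, 30)))
        assert out.shape == (60,)

    def test_identical_flow_in_hand_and_box_zeroes_first_half(self):
        shape = (60, 80)
        flow = np.full((*shape, 2), 2.0)
        out = motion_feature(flow, _regions(shape, BoundingBox(10, 10, 30, 30)))
        assert np.allclose(out[:30], 0.0)

    def test_moving_box_static_background_signature(self):
        # hand+box move 5 px right, background still: the second
        # difference vector gains mass in the zero bin, loses at 5 px
        shape = (60, 80)
        box = BoundingBox(10, 10, 30, 30)
        regions = _regions(shape, box)
        flow = np.zeros((*shape, 2))
        flow[regions.box, 1] = 5.0
        cfg = FeatureConfig()
        out = motion_feature(flow, regions, cfg)
        assert np.allclose(out[:30], 0.0)   # hand == box
        mag_diff = out[30:45]               # background - box magnitudes
        zero_bin = 0
        five_bin = int(5.0 / (cfg.mag_cap / cfg.n_bins))
        assert mag_diff[zero_bin] > 0.5
        assert mag_diff[five_bin] < -0.5

    def test_difference_blocks_sum_to_zero(self):
        rng = np.random.default_rng(3)
        shape = (60, 80)
        flow = rng.normal(0, 2, (*shape, 2))
        out = motion_feature(flow, _regions(shape, BoundingBox(5, 5, 40, 40)))
        for block in (out[0:15], out[15:30], out[30:45], out[45:60]):
            assert block.sum() == pytest.approx(0.0, abs=1e-9)


class TestShapePCA:
    def test_transform_dimension(self):
        rng = np.random.default_rng(0)
        pca = fit_shape_pca(rng.random((200, 300)))
        assert pca.transform(rng.random((5, 300))).shape == (5, 60)

    def test_low_rank_data_has_no_variance_beyond_rank(self):
        rng = np.random.default_rng(1)
        basis = rng.random((5, 300))
        data = rng.random((150, 5)) @ basis
        pca = fit_shape_pca(data)
        assert np.all(pca.explained_variance_[5:] < 1e-10)

    def test_training_mean_projects_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.random((100, 200))
        pca = fit_shape_pca(X)
        proj = pca.transform(X.mean(axis=0, keepdims=True))
        assert np.allclose(proj, 0.0, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="training vectors"):
            fit_shape_pca(np.random.default_rng(0).random((60, 100)))


class TestShapeFeature:
    def test_length_and_determinism(self):
        rng = np.random.default_rng(4)
        frame = make_frame(rng.integers(0, 255, (60, 80, 3)).astype(np.uint8))
        box = BoundingBox(10, 10, 30, 30)
        hogs = np.array([raw_hog(frame, BoundingBox(x, 10, 30, 30))
                         for x in range(10, 45)] * 2)
        pca = fit_shape_pca(hogs + rng.normal(0, 1e-6, hogs.shape))
        a = shape_feature(frame, box, pca)
        b = shape_feature(frame, box, pca)
        assert a.shape == (60,)
        assert np.array_equal(a, b)

    def test_unfitted_pca_rejected(self):
        from sklearn.decomposition import PCA
        frame = make_frame(np.zeros((60, 80, 3), np.uint8))
        with pytest.raises(ValueError, match="not fitted"):
            shape_feature(frame, BoundingBox(0, 0, 10, 10), PCA(60))

    def test_uniform_crop_has_zero_raw_hog(self):
        frame = make_frame(np.full((60, 80, 3), 100, np.uint8))
        assert np.allclose(raw_hog(frame, BoundingBox(10, 10, 30, 30)), 0.0)


class TestColour:
    def test_bhattacharyya_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert bhattacharyya(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_bhattacharyya_disjoint(self):
        assert bhattacharyya([1, 0, 0], [0, 0.5, 0.5]) == pytest.approx(1.0)

    def test_bhattacharyya_closed_form(self):
        # sqrt(1 - sqrt(0.5)) = 0.541196...
        d = bhattacharyya([0.5, 0.5, 0.0], [1.0, 0.0, 0.0])
        assert d == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)

    def test_colour_feature_bounds_and_uniform_frame(self):
        frame = make_frame(np.full((60, 80, 3), 90, np.uint8))
        out = colour_feature(frame, _regions((60, 80),
                                             BoundingBox(10, 10, 30, 30)))
        assert out.shape == (2,)
        assert np.all((out >= 0) & (out <= 1))
        assert np.allclose(out, 0.0, atol=1e-9)  # identical histograms


class TestAssemble:
    def test_combined_length(self):
        f = assemble_feature(np.zeros(60), np.zeros(60), np.zeros(2))
        assert f.combined.shape == (122,)

    def test_wrong_lengths_rejected(self):
        with pytest.raises(ValueError):
            assemble_feature(np.zeros(59), np.zeros(60), np.zeros(2))
        with pytest.raises(ValueError):
            assemble_feature(np.zeros(60), np.zeros(60), np.zeros(3))

    def test_order_is_motion_shape_colour(self):
        f = assemble_feature(np.full(60, 1.0), np.full(60, 2.0),
                             np.full(2, 3.0))
        assert (f.combined[:60] == 1.0).all()
        assert (f.combined[60:120] == 2.0).all()
        assert (f.combined[120:] == 3.0).all()
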