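"""The 122-value hand-object interaction feature.

Three cue families, concatenated:

* motion (60): a dense optical-flow field is summarised in three regions —
  the segmented hand, its re-centred bounding box, and the background
  (frame minus box) — as L1-normalised 15-bin histograms of flow magnitude
  and direction.  The feature holds two difference vectors,
  (hand - box) ++ (background - box), magnitudes before directions in
  each.  An object held in the hand moves with it, so during interaction
  the box's motion resembles the hand's and differs from the background's.
* shape (60): HOG on the box crop resized to 10% of the frame height by
  15% of the frame width, PCA-reduced to 60 to match the motion feature's
  dimension.  Grip shape correlates with manipulation.
* colour (2): Bhattacharyya distances between HSV histograms,
  d_B(box, hand) and d_B(box, background) — objects near the hand recolour
  the box relative to both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import hog
from skimage.registration import optical_flow_ilk
from skimage.transform import resize
from sklearn.decomposition import PCA

from .config import FeatureConfig
from .detection import BoundingBox
from .video_io import Frame

MOTION_DIM = 60
SHAPE_DIM = 60
COLOUR_DIM = 2
FEATURE_DIM = MOTION_DIM + SHAPE_DIM + COLOUR_DIM

#: column blocks of the combined feature
BLOCKS = {"motion": slice(0, 60), "shape": slice(60, 120),
          "colour": slice(120, 122)}


@dataclass(frozen=True)
class RegionSet:
    """Pixel partition for one frame: hand ⊆ box, background = frame − box."""

    hand: np.ndarray        # boolean, full frame
    box: np.ndarray         # boolean, full frame
    background: np.ndarray  # boolean, full frame

    @classmethod
    def from_segment(cls, frame_shape: tuple[int, int], hand_mask: np.ndarray,
                     box: BoundingBox) -> "RegionSet":
        H, W = frame_shape
        box_mask = np.zeros((H, W), dtype=bool)
        box_mask[box.y:box.y + box.h, box.x:box.x + box.w] = True
        hand = hand_mask & box_mask
        return cls(hand=hand, box=box_mask, background=~box_mask)


@dataclass(frozen=True)
class InteractionFeature:
    """Motion ++ shape ++ colour, 60 + 60 + 2 = 122 values."""

    motion: np.ndarray
    shape: np.ndarray
    colour: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.motion, self.shape, self.colour])


def dense_flow(prev: Frame, curr: Frame,
               config: FeatureConfig | None = None) -> np.ndarray:
    """Dense per-pixel flow (dy, dx stacked last) between consecutive
    frames, via iterative Lucas-Kanade with a fixed window radius."""
    cfg = config or FeatureConfig()
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    g0 = prev.gray().astype(np.float32)
    g1 = curr.gray().astype(np.float32)
    vy, vx = optical_flow_ilk(g0, g1, radius=cfg.flow_radius,
                              num_warp=cfg.flow_num_warp)
    return np.stack([vy, vx], axis=-1)


def _flow_histograms(flow: np.ndarray, region: np.ndarray,
                     cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """L1-normalised magnitude and direction histograms over one region;
    empty regions give all-zero histograms."""
    n = cfg.n_bins
    if not region.any():
        return np.zeros(n), np.zeros(n)
    fy = flow[..., 0][region]
    fx = flow[..., 1][region]
    mag = np.hypot(fx, fy)
    mag_clipped = np.minimum(mag, cfg.mag_cap)  # overflow goes to the top bin
    hm, _ = np.histogram(mag_clipped, bins=n, range=(0.0, cfg.mag_cap))
    ang = np.degrees(np.arctan2(fy, fx)) % 360.0
    w = mag if cfg.weight_direction_by_magnitude else None
    hd, _ = np.histogram(ang, bins=n, range=(0.0, 360.0), weights=w)
    hm = hm.astype(np.float64)
    hd = hd.astype(np.float64)
    if hm.sum() > 0:
        hm /= hm.sum()
    if hd.sum() > 0:
        hd /= hd.sum()
    return hm, hd


def motion_feature(flow: np.ndarray, regions: RegionSet,
                   config: FeatureConfig | None = None) -> np.ndarray:
    """(hand − box) ++ (background − box) difference histograms, 60 values."""
    cfg = config or FeatureConfig()
    hm_h, hd_h = _flow_histograms(flow, regions.hand, cfg)
    hm_b, hd_b = _flow_histograms(flow, regions.box, cfg)
    hm_g, hd_g = _flow_histograms(flow, regions.background, cfg)
    return np.concatenate([hm_h - hm_b, hd_h - hd_b,
                           hm_g - hm_b, hd_g - hd_b])


def raw_hog(frame: Frame, box: BoundingBox,
            config: FeatureConfig | None = None) -> np.ndarray:
    """HOG descriptor of the box crop after resizing to the fixed fraction
    of the frame size (identical dimensions for every frame)."""
    cfg = config or FeatureConfig()
    H, W = frame.shape
    box.validate(W, H)
    crop = frame.gray()[box.y:box.y + box.h, box.x:box.x + box.w]
    th = max(int(round(cfg.crop_h_frac * H)), 2 * cfg.hog_cell_px * cfg.hog_block_cells)
    tw = max(int(round(cfg.crop_w_frac * W)), 2 * cfg.hog_cell_px * cfg.hog_block_cells)
    resized = resize(crop, (th, tw), anti_aliasing=True, preserve_range=True)
    return hog(resized, orientations=cfg.hog_orientations,
               pixels_per_cell=(cfg.hog_cell_px, cfg.hog_cell_px),
               cells_per_block=(cfg.hog_block_cells, cfg.hog_block_cells),
               feature_vector=True)


def fit_shape_pca(training_hog: np.ndarray,
                  config: FeatureConfig | None = None) -> PCA:
    """Fit the HOG dimensionality reduction on training-fold vectors only."""
    cfg = config or FeatureConfig()
    X = np.asarray(training_hog, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("training HOG matrix must be 2-D")
    if X.shape[0] <= cfg.pca_components:
        raise ValueError(
            f"need more than {cfg.pca_components} training vectors, "
            f"got {X.shape[0]}")
    pca = PCA(n_components=cfg.pca_components, svd_solver="randomized",
              random_state=0)
    pca.fit(X)
    return pca


def shape_feature(frame: Frame, box: BoundingBox, pca: PCA,
                  config: FeatureConfig | None = None) -> np.ndarray:
    """PCA-reduced HOG of the re-centred box crop, 60 values."""
    if not hasattr(pca, "components_"):
        raise ValueError("PCA model is not fitted")
    vec = raw_hog(frame, box, config)
    return pca.transform(vec.reshape(1, -1))[0]


def bhattacharyya(p: np.ndarray, q: np.ndarray) -> float:
    """d_B(p, q) = sqrt(1 − Σ sqrt(p_i q_i)) for L1-normalised histograms."""
    bc = float(np.sum(np.sqrt(np.asarray(p) * np.asarray(q))))
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def _hsv_histogram(hsv: np.ndarray, region: np.ndarray,
                   cfg: FeatureConfig) -> np.ndarray:
    nb = cfg.hsv_bins
    if not region.any():
        return np.zeros(3 * nb)
    parts = []
    for c in range(3):
        h, _ = np.histogram(hsv[..., c][region], bins=nb, range=(0.0, 1.0))
        parts.append(h.astype(np.float64))
    out = np.concatenate(parts)
    s = out.sum()
    return out / s if s > 0 else out


def colour_feature(frame: Frame, regions: RegionSet,
                   config: FeatureConfig | None = None) -> np.ndarray:
    """[d_B(box, hand), d_B(box, background)] on HSV histograms."""
    cfg = config or FeatureConfig()
    hsv = rgb2hsv(frame.pixels)
    h_hand = _hsv_histogram(hsv, regions.hand, cfg)
    h_box = _hsv_histogram(hsv, regions.box, cfg)
    h_bg = _hsv_histogram(hsv, regions.background, cfg)
    return np.array([bhattacharyya(h_box, h_hand),
                     bhattacharyya(h_box, h_bg)])


def assemble_feature(motion: np.ndarray, shape: np.ndarray,
                     colour: np.ndarray) -> InteractionFeature:
    """Concatenate the three families in the fixed order motion, shape,
    colour; lengths are checked."""
    motion = np.asarray(motion, dtype=np.float64)
    shape = np.asarray(shape, dtype=np.float64)
    colour = np.asarray(colour, dtype=np.float64)
    if motion.shape != (MOTION_DIM,):
        raise ValueError(f"motion feature must have {MOTION_DIM} values")
    if shape.shape != (SHAPE_DIM,):
        raise ValueError(f"shape feature must have {SHAPE_DIM} values")
    if colour.shape != (COLOUR_DIM,):
        raise ValueError(f"colour feature must have {COLOUR_DIM} values")
    return InteractionFeature(motion=motion, shape=shape, colour=colour)
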