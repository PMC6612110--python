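"""Skin-colour back-projection and hand segmentation.

The segmenter combines two cues inside a detected bounding box:

* a chroma histogram back-projection under a mixture-of-Gaussians skin
  model (CbCr plane), thresholded at 0.75 of the per-frame maximum, and
* an edge map from a pluggable edge operator, thresholded at 0.05 of its
  maximum and morphologically closed (dilation then erosion).

Candidate contours of the edge-refined skin mask are filtered by area
(2-75% of the box area) and perimeter (contours within 90-110% of the box
perimeter are box-hugging artefacts and removed); the survivor with the
highest overlap against the dilated edge image wins.  The box is then
re-centred on the midpoint of the contour centroid and its topmost pixel,
which biases coverage toward the hand rather than the arm below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2ycbcr
from skimage.feature import canny
from skimage.filters import sobel
from skimage.measure import find_contours, label, regionprops

from .config import SegConfig
from .detection import BoundingBox
from .video_io import Frame

# CbCr range of the Rec.601 YCbCr transform used for the chroma histogram
_CBCR_LO, _CBCR_HI = 16.0, 240.0


@dataclass
class SkinModel:
    """A normalised 2-D chroma (Cb, Cr) histogram used for back-projection.

    Built by evaluating a mixture-of-Gaussians skin-colour density on the
    bin centres, so the histogram is smooth and deterministic.
    """

    hist: np.ndarray                       # (n_bins, n_bins), sums to 1
    bin_edges: np.ndarray = field(default=None)  # shared Cb/Cr edges

    def __post_init__(self):
        self.hist = np.asarray(self.hist, dtype=np.float64)
        if self.bin_edges is None:
            self.bin_edges = np.linspace(_CBCR_LO, _CBCR_HI,
                                         self.hist.shape[0] + 1)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if np.any(self.hist < 0):
            raise ValueError("skin histogram has negative mass")
        s = self.hist.sum()
        if s <= 0:
            raise ValueError("skin histogram is empty")
        self.hist = self.hist / s

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"bin_edges": self.bin_edges.tolist(),
             "values": self.hist.tolist()}))

    @classmethod
    def load(cls, path: str | Path) -> "SkinModel":
        d = json.loads(Path(path).read_text())
        return cls(hist=np.array(d["values"]), bin_edges=np.array(d["bin_edges"]))


#: Gaussian mixture in the CbCr plane: (weight, mean, covariance diagonal).
#: The dominant component sits on the classic skin-chroma cluster
#: (Cb ~ 110, Cr ~ 150); a broad low-weight component captures the spread
#: across skin tones and illumination.
DEFAULT_SKIN_MIXTURE = [
    (0.75, (110.0, 152.0), (90.0, 70.0)),
    (0.25, (115.0, 145.0), (220.0, 160.0)),
]


def default_skin_model(n_bins: int = 32,
                       mixture=None) -> SkinModel:
    """Skin chroma histogram from a mixture-of-Gaussians density."""
    mixture = mixture or DEFAULT_SKIN_MIXTURE
    edges = np.linspace(_CBCR_LO, _CBCR_HI, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    cb, cr = np.meshgrid(centres, centres, indexing="ij")
    dens = np.zeros_like(cb)
    for w, (mu_cb, mu_cr), (var_cb, var_cr) in mixture:
        dens += w * np.exp(-0.5 * ((cb - mu_cb) ** 2 / var_cb
                                   + (cr - mu_cr) ** 2 / var_cr))
    return SkinModel(hist=dens, bin_edges=edges)


def skin_probability(frame: Frame, model: SkinModel, thresh: float = 0.75,
                     min_support: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Back-project the frame under the skin model.

    Returns ``(prob, mask)`` where ``prob`` holds the histogram value of
    each pixel's chroma bin and ``mask = prob >= thresh * prob.max()``.
    Chroma bins carrying less than ``min_support`` of the histogram's peak
    count as zero support (the mixture's tails are unbounded, so without a
    floor a skin-free frame would mask its own least-unlikely colour);
    an all-zero probability map yields an empty mask.
    """
    ycbcr = rgb2ycbcr(frame.pixels)
    cb, cr = ycbcr[..., 1], ycbcr[..., 2]
    edges = model.bin_edges
    n = model.hist.shape[0]
    ib = np.clip(np.searchsorted(edges, cb, side="right") - 1, 0, n - 1)
    ir = np.clip(np.searchsorted(edges, cr, side="right") - 1, 0, n - 1)
    prob = model.hist[ib, ir].copy()
    prob[prob < min_support * model.hist.max()] = 0.0
    mx = prob.max()
    mask = prob >= thresh * mx if mx > 0 else np.zeros_like(prob, dtype=bool)
    return prob, mask


def gradient_edge_strength(gray: np.ndarray, sigma: float = 0.0) -> np.ndarray:
    """Sobel gradient magnitude, optionally after Gaussian presmoothing."""
    if sigma > 0:
        gray = ndi.gaussian_filter(gray, sigma)
    return sobel(gray)


def canny_edge_strength(gray: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Default baseline edge operator: Canny at scale ``sigma``.

    Non-maximum suppression plus hysteresis keeps region boundaries while
    rejecting surface texture, which a plain gradient threshold cannot do
    when the frame's strongest edge varies between scenes."""
    return canny(gray, sigma=sigma).astype(float)


EdgeOperator = Callable[[np.ndarray], np.ndarray]


def hand_edge_map(frame: Frame, edge_operator: EdgeOperator | None = None,
                  config: SegConfig | None = None) -> np.ndarray:
    """Binary edge image: operator response thresholded at ``edge_thresh``
    of its maximum, then closed (dilation followed by erosion) to bridge
    small contour gaps."""
    cfg = config or SegConfig()
    if edge_operator is None:
        def edge_operator(g):
            return canny_edge_strength(g, cfg.edge_sigma)
    strength = np.asarray(edge_operator(frame.gray()), dtype=np.float64)
    mx = strength.max()
    if mx <= 1e-10:  # numerically flat frame: no edges
        return np.zeros(strength.shape, dtype=bool)
    binary = strength >= cfg.edge_thresh * mx
    se = np.ones((cfg.morph_size, cfg.morph_size), dtype=bool)
    closed = ndi.binary_erosion(ndi.binary_dilation(binary, se), se)
    return closed


@dataclass
class HandSegment:
    """The selected hand contour and its re-centred bounding box."""

    mask: np.ndarray            # full-frame boolean, True inside the hand
    contour: np.ndarray         # (K, 2) boundary points, (row, col) order
    recentred_box: BoundingBox
    source_box: BoundingBox


def _topmost_pixel(region_mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(region_mask)
    top = rows.min()
    return float(top), float(cols[rows == top].min())


def segment_hand(frame: Frame, box: BoundingBox, skin: SkinModel,
                 edge_operator: EdgeOperator | None = None,
                 config: SegConfig | None = None) -> HandSegment | None:
    """Segment the hand inside ``box``; ``None`` signals failure.

    Candidate contours come from connected components of the skin mask
    after subtracting dilated edge pixels (which splits regions merged
    across object boundaries).  Components are filtered by filled area
    (``area_min_frac``-``area_max_frac`` of the box area) and perimeter
    (within ``perim_lo``-``perim_hi`` of the box perimeter they are
    discarded as box-hugging); the winner maximises the fraction of its
    filled area covered by the dilated edge image, ties broken by larger
    area.  The returned box keeps its size but is re-centred on the
    midpoint of the winning contour's centroid and topmost pixel.
    """
    cfg = config or SegConfig()
    H, W = frame.shape
    box.validate(W, H)

    prob, skin_mask = skin_probability(frame, skin, thresh=cfg.skin_thresh)
    edges = hand_edge_map(frame, edge_operator, cfg)
    se = np.ones((cfg.morph_size, cfg.morph_size), dtype=bool)
    dilated_edges = ndi.binary_dilation(edges, se)

    refined = skin_mask & ~dilated_edges
    window = np.zeros((H, W), dtype=bool)
    window[box.y:box.y + box.h, box.x:box.x + box.w] = True
    refined &= window

    labels = label(refined, connectivity=2)
    if labels.max() == 0:
        return None

    box_area = float(box.w * box.h)
    box_perim = 2.0 * (box.w + box.h)
    best = None
    for rp in regionprops(labels):
        area = float(rp.area_filled)
        if area < cfg.area_min_frac * box_area or area > cfg.area_max_frac * box_area:
            continue
        if cfg.perim_lo * box_perim <= rp.perimeter <= cfg.perim_hi * box_perim:
            continue
        filled = np.zeros((H, W), dtype=bool)
        rr0, cc0, rr1, cc1 = rp.bbox
        filled[rr0:rr1, cc0:cc1] = rp.image_filled
        overlap = np.count_nonzero(filled & dilated_edges) / area
        key = (overlap, area)
        if best is None or key > best[0]:
            best = (key, rp, filled)
    if best is None:
        return None

    _, rp, filled = best
    # the edge-refined mask is only used to pick the winner; the final
    # delineation recovers the winner's full skin support by morphological
    # reconstruction (binary propagation) inside the search window
    filled = ndi.binary_propagation(filled, mask=(skin_mask | filled) & window)

    rows, cols = np.nonzero(filled)
    cy, cx = float(rows.mean()), float(cols.mean())
    top_r, top_c = _topmost_pixel(filled)
    new_cy = 0.5 * (cy + top_r)
    new_cx = 0.5 * (cx + top_c)
    nx = int(round(new_cx - box.w / 2.0))
    ny = int(round(new_cy - box.h / 2.0))
    nx = int(np.clip(nx, 0, W - box.w))
    ny = int(np.clip(ny, 0, H - box.h))
    new_box = BoundingBox(x=nx, y=ny, w=box.w, h=box.h)

    inside = np.zeros((H, W), dtype=bool)
    inside[ny:ny + box.h, nx:nx + box.w] = True
    mask = filled & inside
    if not mask.any():
        return None

    padded = np.pad(filled, 1)
    cs = find_contours(padded.astype(float), 0.5)
    contour = max(cs, key=len) - 1.0 if cs else np.empty((0, 2))
    return HandSegment(mask=mask, contour=contour,
                       recentred_box=new_box, source_box=box)
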