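"""Hand bounding-box candidates.

The detector contract is pluggable: any per-frame source of boxes can feed
the pipeline (an external CNN's output loaded from CSV, or the built-in
baseline skin-blob detector).  Verification and handedness assignment
happen downstream from the arm-angle feature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import DetectorConfig

HANDEDNESS = ("left", "right", "other", "unknown")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, origin top-left, half-open on the right/bottom."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1 or self.x < 0 or self.y < 0:
            raise ValueError(f"degenerate box {self}")

    def validate(self, frame_w: int, frame_h: int) -> None:
        if self.x + self.w > frame_w or self.y + self.h > frame_h:
            raise ValueError(f"box {self} exceeds frame {frame_w}x{frame_h}")

    @property
    def centre(self) -> tuple[float, float]:
        """(cx, cy) in pixel coordinates."""
        return self.x + self.w / 2.0, self.y + self.h / 2.0

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0, min(self.x + self.w, other.x + other.w) - max(self.x, other.x))
        iy = max(0, min(self.y + self.h, other.y + other.h) - max(self.y, other.y))
        inter = ix * iy
        union = self.w * self.h + other.w * other.h - inter
        return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class DetectionRecord:
    """A candidate hand box; handedness is set only after verification."""

    frame: int
    box: BoundingBox
    score: float
    verified: bool = False
    handedness: str = "unknown"

    def __post_init__(self):
        if self.handedness not in HANDEDNESS:
            raise ValueError(f"unknown handedness {self.handedness!r}")
        if self.handedness != "unknown" and not self.verified:
            raise ValueError("handedness requires a verified detection")

    def with_verification(self, verified: bool, handedness: str = "unknown"):
        return replace(self, verified=verified,
                       handedness=handedness if verified else "unknown")


def detect_hands_baseline(frame, skin_model,
                          config: DetectorConfig | None = None):
    """Baseline detector: connected components of the thresholded
    skin-probability map.

    Components with pixel area >= ``min_area_frac`` of the frame are
    returned as tight boxes (clipped to the frame; egocentric hands
    frequently touch the border), scored by the mean skin probability
    inside the box, best first; ties broken by larger area.  At most
    ``max_detections`` boxes are returned.
    """
    from .segmentation import skin_probability  # local: avoids cycle at import

    cfg = config or DetectorConfig()
    prob, mask = skin_probability(frame, skin_model, thresh=cfg.skin_threshold)
    H, W = mask.shape
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return []
    min_area = cfg.min_area_frac * H * W
    candidates = []
    for sl, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        area = int(np.count_nonzero(labels[sl] == lab))
        if area < min_area:
            continue
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        box = BoundingBox(x=x0, y=y0, w=x1 - x0, h=y1 - y0)
        score = float(prob[y0:y1, x0:x1].mean())
        candidates.append((box, score, area))
    candidates.sort(key=lambda t: (-t[1], -t[2], t[0].x, t[0].y))
    return [(box, score) for box, score, _ in candidates[:cfg.max_detections]]


def hand_box_from_blob(skin_mask: np.ndarray, blob_box: BoundingBox,
                       scale: float = 3.0) -> BoundingBox:
    """Localise the hand inside a skin component that includes the arm.

    The palm is the widest part of the hand+arm silhouette, so the peak of
    the euclidean distance transform inside the component marks the palm
    centre and its value the palm half-width.  Returns a square box of
    side ``scale`` x that radius centred there (clipped to the frame) —
    the analogue of a hand-trained detector's box for the baseline
    skin-blob detector, whose tight boxes span hand *and* forearm.
    """
    H, W = skin_mask.shape
    y1 = min(blob_box.y + blob_box.h, H)
    x1 = min(blob_box.x + blob_box.w, W)
    crop = skin_mask[blob_box.y:y1, blob_box.x:x1]
    if not crop.any():
        return blob_box
    dt = ndi.distance_transform_edt(np.pad(crop, 1))[1:-1, 1:-1]
    iy, ix = np.unravel_index(np.argmax(dt), dt.shape)
    r = float(dt[iy, ix])
    cy, cx = blob_box.y + iy, blob_box.x + ix
    side = max(int(round(scale * r)), 8)
    x0 = int(np.clip(cx - side // 2, 0, max(W - side, 0)))
    y0 = int(np.clip(cy - side // 2, 0, max(H - side, 0)))
    return BoundingBox(x=x0, y=y0, w=min(side, W - x0), h=min(side, H - y0))


def pad_box(box: BoundingBox, frac: float, frame_w: int,
            frame_h: int) -> BoundingBox:
    """Grow a box by ``frac`` of its width/height on each side, clipped to
    the frame.  The pipeline applies this to the baseline detector's tight
    component boxes so downstream stages see the slack a trained detector
    would leave around the hand."""
    px = int(round(frac * box.w))
    py = int(round(frac * box.h))
    x0 = max(box.x - px, 0)
    y0 = max(box.y - py, 0)
    x1 = min(box.x + box.w + px, frame_w)
    y1 = min(box.y + box.h + py, frame_h)
    return BoundingBox(x=x0, y=y0, w=x1 - x0, h=y1 - y0)


def load_external_detections(path: str | Path, frame_w: int,
                             frame_h: int) -> list[DetectionRecord]:
    """Load per-frame boxes produced by an external detector.

    CSV header ``frame,x,y,w,h,score``; boxes outside the frame bounds are
    rejected with the offending line number.  Records come back unverified
    with unknown handedness: verification and handedness assignment are the
    arm-angle stage's job.
    """
    df = pd.read_csv(path)
    expected = ["frame", "x", "y", "w", "h", "score"]
    if list(df.columns[:6]) != expected:
        raise ValueError(f"detections CSV must have header "
                         f"{','.join(expected)}, got {','.join(df.columns)}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            box = BoundingBox(x=int(row.x), y=int(row.y),
                              w=int(row.w), h=int(row.h))
            box.validate(frame_w, frame_h)
        except ValueError as exc:
            raise ValueError(f"{path}, line {pos}: {exc}") from exc
        records.append(DetectionRecord(frame=int(row.frame), box=box,
                                       score=float(row.score)))
    return records


def write_detections(records, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.frame, r.box.x, r.box.y, r.box.w, r.box.h, r.score)
         for r in records],
        columns=["frame", "x", "y", "w", "h", "score"])
    df.to_csv(path, index=False)
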