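"""Pipeline configuration.

Every tunable of the pipeline lives here as a dataclass field with its
default, so a run can be archived as a single YAML/JSON snapshot and
replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class DetectorConfig:
    """Baseline skin-blob detector settings."""

    #: minimum connected-component area as a fraction of the frame area
    min_area_frac: float = 0.001
    #: maximum number of boxes returned per frame, best-scoring first
    max_detections: int = 4
    #: skin-probability threshold relative to the per-frame maximum
    skin_threshold: float = 0.75


@dataclass
class ArmConfig:
    """Rotating three-rectangle arm-angle feature."""

    #: rectangle width as a fraction of the shorter bounding-box side
    rect_width_frac: float = 0.5
    #: rotation step in degrees (360/step responses)
    step_deg: int = 1
    #: bin width in degrees for the summed feature vector
    bin_deg: int = 5
    #: trees in the box-verification random forest
    n_trees: int = 150


@dataclass
class SegConfig:
    """Hand segmentation thresholds (relative thresholds are empirical and
    camera dependent; these defaults suit the bundled skin model)."""

    skin_thresh: float = 0.75     # of per-frame max back-projection
    edge_thresh: float = 0.05     # of per-frame max edge strength
    edge_sigma: float = 2.0       # gaussian scale of the baseline Canny
                                  # edge operator
    box_pad_frac: float = 0.2     # box padding per side (fraction of w/h)
                                  # applied by the pipeline before
                                  # verification/segmentation
    area_min_frac: float = 0.02   # contour area >= 2% of box area
    area_max_frac: float = 0.75   # contour area <= 75% of box area
    perim_lo: float = 0.9         # drop contours with perimeter in
    perim_hi: float = 1.1         # [0.9, 1.1] x box perimeter
    morph_size: int = 3           # square element for dilation/erosion


@dataclass
class FeatureConfig:
    """Interaction feature extraction (motion + shape + colour)."""

    n_bins: int = 15              # bins per flow magnitude/direction histogram
    mag_cap: float = 20.0         # px; flow magnitudes above go to the top bin
    weight_direction_by_magnitude: bool = False
    hsv_bins: int = 15            # bins per HSV channel
    crop_h_frac: float = 0.10     # HOG crop resized to this fraction of frame H
    crop_w_frac: float = 0.15     # ... and of frame W
    hog_orientations: int = 9
    hog_cell_px: int = 4          # square cell side on the resized crop
    hog_block_cells: int = 2      # block side in cells
    pca_components: int = 60
    flow_radius: int = 7          # iterative Lucas-Kanade window radius
    flow_num_warp: int = 3


@dataclass
class ClassifierConfig:
    """Interaction random forest."""

    n_trees: int = 150
    max_features: str = "sqrt"


@dataclass
class TimelineConfig:
    """Timeline post-processing and metric extraction."""

    bridge_frames: int = 90       # prolong interactions over <=90 absent frames
    window_frames: int = 120      # moving-average window (4 s at 30 fps)
    threshold: float = 0.5        # on the min-max normalised moving average


@dataclass
class PipelineConfig:
    """Top-level configuration: every stage plus the global seed."""

    detector: DetectorConfig = field(default_factory=DetectorConfig)
    arm: ArmConfig = field(default_factory=ArmConfig)
    seg: SegConfig = field(default_factory=SegConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    timeline: TimelineConfig = field(default_factory=TimelineConfig)
    seed: int = 0
    target_height: int = 480
    default_fps: float = 30.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for name, sub in [
            ("detector", DetectorConfig), ("arm", ArmConfig),
            ("seg", SegConfig), ("features", FeatureConfig),
            ("classifier", ClassifierConfig), ("timeline", TimelineConfig),
        ]:
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
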