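"""Arm-angle estimation from a rotating three-rectangle Haar-like feature.

For each 1-degree step, a centre rectangle extends from the bounding-box
centroid along the ray at that angle to the image border, flanked by two
adjacent parallel rectangles of the same width.  Because an arm is a
near-uniform strip against a busier background, the coefficient of
variation (CV = population std / mean of pixel intensity) is lowest in the
centre rectangle when the ray aligns with the arm, so the response

    response(theta) = ((CV_side1 - CV_centre) + (CV_side2 - CV_centre)) / 2

peaks along the arm.  The 360 responses summed over 5-degree bins give a
72-value feature used for two decisions:

* box verification — a random-forest classifier on the 72-value vector
  says whether the box really contains a hand;
* handedness — the quadrant with the largest summed response decides the
  hand: bottom-left (270-360 deg) = user's left, bottom-right (180-270 deg)
  = user's right, top half (0-180 deg) = another person's hand.

Angle convention (forced by the quadrant semantics above): 0 deg points
left (image West) and angles increase clockwise on screen, so 90 deg is
up, 180 deg right, 270 deg down; the image y axis points down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import ArmConfig
from .detection import BoundingBox

_EPS_MEAN = 1e-6   # CV defined as 0 below this mean intensity
_MIN_PIXELS = 4    # ... or below this pixel count


@dataclass(frozen=True)
class ArmAngleFeature:
    """Raw 360-step response profile, its 5-degree binned sum and the
    source box centre."""

    raw_profile: np.ndarray   # (360,)
    binned: np.ndarray        # (72,)
    centroid: tuple[float, float]


def angle_direction(theta_deg: float) -> tuple[float, float]:
    """Unit direction (dx, dy) of the ray at ``theta_deg``: (-1, 0) at 0
    (West), (0, -1) at 90 (up, y down on screen)."""
    t = np.deg2rad(theta_deg)
    return -float(np.cos(t)), -float(np.sin(t))


def compute_arm_feature(gray: np.ndarray, box: BoundingBox,
                        config: ArmConfig | None = None) -> ArmAngleFeature:
    """Evaluate the rotating three-rectangle feature around ``box``.

    ``gray`` is the full frame on [0, 1].  Rectangles have width
    ``rect_width_frac`` x the shorter box side and are truncated at the
    image border; membership is by pixel-centre inclusion.
    """
    cfg = config or ArmConfig()
    H, W = gray.shape
    box.validate(W, H)
    cx, cy = box.centre
    if not (0 <= cx < W and 0 <= cy < H):
        raise ValueError(f"box centroid {(cx, cy)} outside frame")

    w_rect = cfg.rect_width_frac * min(box.w, box.h)
    half = w_rect / 2.0

    ys, xs = np.mgrid[0:H, 0:W]
    dx = (xs + 0.5 - cx).ravel()
    dy = (ys + 0.5 - cy).ravel()
    v = gray.ravel().astype(np.float64)
    v2 = v * v

    n_steps = 360 // cfg.step_deg
    thetas = np.deg2rad(np.arange(n_steps) * cfg.step_deg)
    raw = np.zeros(n_steps)
    for i, t in enumerate(thetas):
        ux, uy = -np.cos(t), -np.sin(t)
        # projection along the ray and signed perpendicular offset
        proj = dx * ux + dy * uy
        perp = dx * uy - dy * ux
        fwd = proj >= 0.0
        apos = np.abs(perp)
        centre = fwd & (apos <= half)
        side1 = fwd & (perp > half) & (perp <= 3 * half)
        side2 = fwd & (perp < -half) & (perp >= -3 * half)
        cvs, valid = [], []
        for m in (centre, side1, side2):
            cnt = int(np.count_nonzero(m))
            if cnt < _MIN_PIXELS:
                cvs.append(0.0)
                valid.append(False)
                continue
            vm = v[m]
            mean = float(vm.mean())
            if mean < _EPS_MEAN:
                cvs.append(0.0)
                valid.append(False)
                continue
            var = float(v2[m].mean()) - mean * mean
            cvs.append(np.sqrt(max(var, 0.0)) / mean)
            valid.append(True)
        # the response is only defined where the centre rectangle is
        # measurable; near the image border truncated rectangles would
        # otherwise produce spurious side-minus-zero responses
        if not valid[0]:
            raw[i] = 0.0
            continue
        sides_cv = [cv for cv, ok in zip(cvs[1:], valid[1:]) if ok]
        if not sides_cv:
            raw[i] = 0.0
            continue
        raw[i] = float(np.mean([cv - cvs[0] for cv in sides_cv]))

    per_bin = cfg.bin_deg // cfg.step_deg
    binned = raw.reshape(-1, per_bin).sum(axis=1)
    return ArmAngleFeature(raw_profile=raw, binned=binned, centroid=(cx, cy))


@dataclass
class HandVerifierModel:
    """Random forest over the 72-value binned feature; True = hand."""

    forest: RandomForestClassifier
    n_trees: int
    seed: int

    def save(self, path: str | Path) -> None:
        joblib.dump(self.forest, path)
        Path(str(path) + ".json").write_text(json.dumps(
            {"n_trees": self.n_trees, "seed": self.seed}))

    @classmethod
    def load(cls, path: str | Path) -> "HandVerifierModel":
        forest = joblib.load(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(forest=forest, **meta)


def train_verifier(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                   config: ArmConfig | None = None) -> HandVerifierModel:
    """Fit the box-verification forest on 72-value features (labels: True
    for arm present)."""
    cfg = config or ArmConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or X.shape[1] != 72:
        raise ValueError("verifier features must be (n, 72)")
    if len(np.unique(y)) < 2:
        raise ValueError("verifier training needs both classes")
    forest = RandomForestClassifier(n_estimators=cfg.n_trees,
                                    random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return HandVerifierModel(forest=forest, n_trees=cfg.n_trees, seed=seed)


def verify_box(feature: ArmAngleFeature, model: HandVerifierModel) -> bool:
    """True iff the forest's positive-class vote fraction is >= 0.5."""
    if model is None or model.forest is None:
        raise ValueError("verifier model is untrained")
    proba = model.forest.predict_proba(feature.binned.reshape(1, -1))[0]
    classes = list(model.forest.classes_)
    p_true = proba[classes.index(True)] if True in classes else 0.0
    return bool(p_true >= 0.5)


def classify_handedness(feature: ArmAngleFeature) -> str:
    """Quadrant rule on the binned feature.

    With 5-degree bins: bins 0-35 cover 0-180 deg (top half, another
    person's hand), 36-53 cover 180-270 deg (bottom right, user's right),
    54-71 cover 270-360 deg (bottom left, user's left).  Quadrants vote
    with the positive part of the response: positive bins are arm-like
    evidence, while negative bins (centre rectangle busier than its
    flanks, e.g. over a held object) carry no information about where the
    arm is — with signed sums a quadrant could win by containing the
    least anti-arm content rather than the arm.  Ties break
    right > left > other.
    """
    b = np.maximum(feature.binned, 0.0)
    n = b.size
    s_top = float(b[: n // 2].sum())
    s_iii = float(b[n // 2: 3 * n // 4].sum())
    s_iv = float(b[3 * n // 4:].sum())
    # priority right > left > other on ties
    best = max((s_iii, 2), (s_iv, 1), (s_top, 0), key=lambda t: (t[0], t[1]))
    return {2: "right", 1: "left", 0: "other"}[best[1]]
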