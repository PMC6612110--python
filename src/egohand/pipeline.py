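"""End-to-end orchestration: video -> detections -> segments -> features
-> per-frame decisions -> per-hand timelines -> functional metrics.

Any stage failure on a frame (no detection, failed verification, failed
segmentation) degrades that frame to hand-absent; the timeline layer owns
missing-frame semantics (gap bridging), so a frame is never allowed to
abort a video.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arm_angle import (HandVerifierModel, classify_handedness,
                        compute_arm_feature, train_verifier, verify_box)
from .classifier import InteractionModel, SubjectData, predict, train
from .config import PipelineConfig
from .detection import (BoundingBox, detect_hands_baseline,
                        hand_box_from_blob, pad_box)
from .features import (RegionSet, colour_feature, dense_flow, fit_shape_pca,
                       motion_feature, raw_hog)
from .segmentation import (SkinModel, default_skin_model, segment_hand,
                           skin_probability)
from .synthetic import SceneSpec, SyntheticSubject, generate_scene
from .timeline import (HandUseMetrics, Timeline, build_timeline,
                       extract_metrics, smooth_threshold)
from .video_io import Frame, write_metrics, write_timeline_csv

logger = logging.getLogger("egohand")

HANDS_SCORED = ("left", "right")


@dataclass
class ModelBundle:
    """Everything the pipeline needs at inference time."""

    skin: SkinModel
    verifier: HandVerifierModel
    interaction: InteractionModel

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.skin.save(d / "skin_model.json")
        self.verifier.save(d / "verifier.joblib")
        self.interaction.save(d / "interaction.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        return cls(skin=SkinModel.load(d / "skin_model.json"),
                   verifier=HandVerifierModel.load(d / "verifier.joblib"),
                   interaction=InteractionModel.load(d / "interaction.joblib"))


@dataclass
class FrameObservation:
    """One verified, segmented, classified detection."""

    frame: int
    handedness: str
    box: BoundingBox
    interacting: bool


@dataclass
class PipelineResult:
    timelines: dict[str, Timeline]
    smoothed: dict[str, np.ndarray]
    metrics: dict[str, HandUseMetrics]
    observations: list[FrameObservation] = field(default_factory=list)


def extract_frame_features(frames: list[Frame], models_skin: SkinModel,
                           verifier: HandVerifierModel | None,
                           config: PipelineConfig):
    """Run detection, verification, segmentation and raw feature
    extraction on every frame.

    Returns a list of dicts (frame, handedness, box, motion, hog_raw,
    colour); frames where every stage fails contribute nothing.  The
    shape PCA is deliberately not applied here so that cross-validation
    can fit it per training fold.
    """
    rows = []
    prev = None
    for frame in frames:
        if prev is None:
            # flow is undefined without a predecessor; the first frame is
            # left to the timeline layer's missing-frame handling
            prev = frame
            continue
        flow = dense_flow(prev, frame, config.features)
        dets = detect_hands_baseline(frame, models_skin, config.detector)
        seen_hands: set[str] = set()
        H, W = frame.shape
        if dets:
            _, skin_mask = skin_probability(frame, models_skin,
                                            config.detector.skin_threshold)
        for tight_box, score in dets:
            # the blob spans hand + forearm; localise the hand first
            hand_box = hand_box_from_blob(skin_mask, tight_box)
            try:
                feat = compute_arm_feature(frame.gray(), hand_box, config.arm)
            except ValueError:
                continue
            if verifier is not None and not verify_box(feat, verifier):
                continue
            hand = classify_handedness(feat)
            if hand in seen_hands:
                continue  # keep the best-scoring box per hand per frame
            box = pad_box(hand_box, config.seg.box_pad_frac, W, H)
            seg = segment_hand(frame, box, models_skin, config=config.seg)
            if seg is None:
                continue
            seen_hands.add(hand)
            # the padded box is only the segmentation search window; the
            # feature regions use a hand-sized box at the re-centred
            # position, as a hand-trained detector would supply
            cx, cy = seg.recentred_box.centre
            fx = int(np.clip(round(cx - hand_box.w / 2), 0, W - hand_box.w))
            fy = int(np.clip(round(cy - hand_box.h / 2), 0, H - hand_box.h))
            feat_box = BoundingBox(x=fx, y=fy, w=hand_box.w, h=hand_box.h)
            regions = RegionSet.from_segment(frame.shape, seg.mask, feat_box)
            rows.append({
                "frame": frame.index,
                "handedness": hand,
                "box": feat_box,
                "motion": motion_feature(flow, regions, config.features),
                "hog_raw": raw_hog(frame, feat_box, config.features),
                "colour": colour_feature(frame, regions, config.features),
            })
        prev = frame
    return rows


def build_subject_data(subject: SyntheticSubject, skin: SkinModel,
                       verifier: HandVerifierModel | None,
                       config: PipelineConfig) -> SubjectData:
    """Run the front half of the pipeline on a synthetic subject and pair
    each surviving frame with its ground-truth interaction label."""
    motion, hog, colour, labels, hands, idx = [], [], [], [], [], []
    gt_hand, gt_label = [], []
    offset = 0
    fps = config.default_fps
    for spec, frames, truth in subject.scenes:
        fps = spec.fps
        rows = extract_frame_features(frames, skin, verifier, config)
        for r in rows:
            motion.append(r["motion"])
            hog.append(r["hog_raw"])
            colour.append(r["colour"])
            labels.append(bool(truth.labels[r["frame"]]))
            hands.append(r["handedness"])
            idx.append(offset + r["frame"])
        gt_hand.extend([truth.handedness] * len(frames))
        gt_label.extend(truth.labels.tolist())
        offset += len(frames)
    return SubjectData(subject=subject.subject,
                       motion=np.array(motion), hog_raw=np.array(hog),
                       colour=np.array(colour),
                       labels=np.array(labels, dtype=bool),
                       hands=np.array(hands),
                       frame_index=np.array(idx, dtype=int),
                       gt_hand=np.array(gt_hand),
                       gt_label=np.array(gt_label, dtype=bool),
                       fps=fps)


def train_verifier_from_scenes(seed: int, config: PipelineConfig,
                               n_scenes: int = 40,
                               frame_h: int = 120, frame_w: int = 160
                               ) -> HandVerifierModel:
    """Fit the box verifier on synthetic arm-present vs arm-absent scenes.

    Positives: the arm-angle feature at the true hand box of scenes with a
    hand.  Negatives: the same feature at a matching box placed in a scene
    without any hand (background texture only).
    """
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for i in range(n_scenes):
        side = ("bottom-left", "bottom-right", "top")[i % 3]
        spec = SceneSpec(n_frames=1, entry_side=side, coupling="absent",
                         frame_h=frame_h, frame_w=frame_w,
                         seed=int(rng.integers(0, 2**31 - 1)))
        frames, truth = generate_scene(spec)
        box = truth.hand_box[0]
        feats.append(compute_arm_feature(frames[0].gray(), box,
                                         config.arm).binned)
        labels.append(True)
        # matching negative: same box on a hand-free background
        neg = np.clip(
            np.array(spec.background_rgb, dtype=np.float64)[None, None, :]
            + rng.normal(0, spec.background_noise, (frame_h, frame_w, 3)),
            0, 255).astype(np.uint8)
        neg_frame = Frame(pixels=neg, index=0, fps=spec.fps)
        feats.append(compute_arm_feature(neg_frame.gray(), box,
                                         config.arm).binned)
        labels.append(False)
    return train_verifier(np.array(feats), np.array(labels), seed=seed,
                          config=config.arm)


def train_models(subjects: list[SyntheticSubject], seed: int = 0,
                 config: PipelineConfig | None = None) -> ModelBundle:
    """Fit the full model bundle (skin histogram, box verifier, shape PCA
    and interaction forest) from a synthetic training cohort."""
    cfg = config or PipelineConfig(seed=seed)
    skin = default_skin_model()
    verifier = train_verifier_from_scenes(seed, cfg)
    data = [build_subject_data(s, skin, verifier, cfg) for s in subjects]
    hog_all = np.vstack([d.hog_raw for d in data])
    pca = fit_shape_pca(hog_all, cfg.features)
    X = np.vstack([np.hstack([d.motion, pca.transform(d.hog_raw), d.colour])
                   for d in data])
    y = np.concatenate([d.labels for d in data])
    interaction = train(X, y, seed=seed, config=cfg.classifier, pca=pca)
    return ModelBundle(skin=skin, verifier=verifier, interaction=interaction)


def process_frames(frames: list[Frame], models: ModelBundle,
                   config: PipelineConfig | None = None) -> PipelineResult:
    """Classify every frame and reduce to per-hand timelines and metrics."""
    cfg = config or PipelineConfig()
    rows = extract_frame_features(frames, models.skin, models.verifier, cfg)
    observations = []
    per_hand: dict[str, dict[int, str]] = {h: {} for h in
                                           ("left", "right", "other")}
    pca = models.interaction.pca
    for r in rows:
        shape = pca.transform(r["hog_raw"].reshape(1, -1))[0]
        vec = np.concatenate([r["motion"], shape, r["colour"]])
        decision = bool(predict(models.interaction, vec.reshape(1, -1))[0])
        state = "interaction" if decision else "no_interaction"
        per_hand[r["handedness"]][r["frame"]] = state
        observations.append(FrameObservation(
            frame=r["frame"], handedness=r["handedness"], box=r["box"],
            interacting=decision))

    n = len(frames)
    fps = frames[0].fps if frames else cfg.default_fps
    timelines, smoothed, metrics = {}, {}, {}
    for hand in ("left", "right", "other"):
        tl = build_timeline(per_hand[hand], n, fps, cfg.timeline)
        timelines[hand] = tl
        if hand in HANDS_SCORED:
            sm = smooth_threshold(tl, cfg.timeline)
            smoothed[hand] = sm
            metrics[hand] = extract_metrics(sm, fps)
    return PipelineResult(timelines=timelines, smoothed=smoothed,
                          metrics=metrics, observations=observations)


def run_pipeline(frames: list[Frame], models: ModelBundle,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Full run with optional artifact archiving (metrics JSON, timeline
    CSV, config snapshot)."""
    cfg = config or PipelineConfig()
    result = process_frames(frames, models, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics({h: m.as_dict() for h, m in result.metrics.items()},
                      out / "metrics.json")
        write_timeline_csv({h: t.states for h, t in result.timelines.items()},
                           out / "timeline.csv")
        cfg.save(out / "config.yaml")
        smoothed = {h: s.tolist() for h, s in result.smoothed.items()}
        (out / "smoothed.json").write_text(json.dumps(smoothed))
    return result
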