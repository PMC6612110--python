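"""Random-forest interaction classifier and its evaluation harness.

One pooled 150-tree forest decides interaction vs no interaction per frame
from the 122-value feature; timelines are split by handedness afterwards.
Evaluation is leave-one-subject-out (LOSO): each subject is scored on a
forest (and shape PCA) fitted with that subject held out entirely, so no
test-subject frame ever leaks into PCA or forest fitting.  Ablations
restrict the feature columns to one family (motion / shape / colour) under
the identical protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .config import ClassifierConfig, FeatureConfig
from .features import BLOCKS, FEATURE_DIM, fit_shape_pca

FAMILIES = ("motion", "shape", "colour")


@dataclass
class SubjectData:
    """Per-frame raw material for one subject.

    Shape PCA is fitted per cross-validation fold, so the raw HOG vectors
    are kept rather than their 60-value projections.  The optional
    timeline fields (``frame_index`` over the subject's whole recording,
    plus full-length ground-truth hand/label sequences) enable the
    filtered (timeline-level) evaluation; without them scoring is raw
    per-frame.
    """

    subject: str
    motion: np.ndarray      # (n, 60)
    hog_raw: np.ndarray     # (n, D_raw)
    colour: np.ndarray      # (n, 2)
    labels: np.ndarray      # (n,) bool, True = interaction
    hands: np.ndarray       # (n,) str in {left, right, other}
    frame_index: np.ndarray | None = None   # (n,) global frame ordinals
    gt_hand: np.ndarray | None = None       # (n_frames,) true hand per frame
    gt_label: np.ndarray | None = None      # (n_frames,) true interaction
    fps: float = 30.0

    def __post_init__(self):
        n = len(self.labels)
        for name in ("motion", "hog_raw", "colour", "hands"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != labels length")
        if self.frame_index is not None and len(self.frame_index) != n:
            raise ValueError("frame_index length != labels length")

    @property
    def has_timeline(self) -> bool:
        return (self.frame_index is not None and self.gt_hand is not None
                and self.gt_label is not None)

    @property
    def n_frames(self) -> int | None:
        return None if self.gt_hand is None else len(self.gt_hand)


def _assemble(subjects: list[SubjectData], pca: PCA) -> np.ndarray:
    parts = []
    for s in subjects:
        shape = pca.transform(s.hog_raw)
        parts.append(np.hstack([s.motion, shape, s.colour]))
    return np.vstack(parts)


@dataclass
class InteractionModel:
    """Fitted forest + the PCA used for shape features + family mask."""

    forest: RandomForestClassifier
    pca: PCA | None
    families: tuple[str, ...] = FAMILIES
    seed: int = 0
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    @property
    def n_features(self) -> int:
        dims = {"motion": 60, "shape": 60, "colour": 2}
        return sum(dims[f] for f in self.families)

    def save(self, path: str | Path) -> None:
        joblib.dump({"forest": self.forest, "pca": self.pca}, path)
        Path(str(path) + ".json").write_text(json.dumps(
            {"families": list(self.families), "seed": self.seed,
             "n_trees": self.config.n_trees,
             "max_features": self.config.max_features}))

    @classmethod
    def load(cls, path: str | Path) -> "InteractionModel":
        blob = joblib.load(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        cfg = ClassifierConfig(n_trees=meta["n_trees"],
                               max_features=meta["max_features"])
        return cls(forest=blob["forest"], pca=blob["pca"],
                   families=tuple(meta["families"]), seed=meta["seed"],
                   config=cfg)


def select_families(X: np.ndarray, families) -> np.ndarray:
    """Restrict a (n, 122) feature matrix to the given families' columns."""
    cols = np.concatenate([np.arange(FEATURE_DIM)[BLOCKS[f]] for f in families])
    return X[:, cols]


def train(features: np.ndarray, labels: np.ndarray, seed: int = 0,
          config: ClassifierConfig | None = None, pca: PCA | None = None,
          families=FAMILIES) -> InteractionModel:
    """Fit the interaction forest on assembled feature rows.

    ``features`` columns must already match ``families`` (pass 122-column
    matrices with the default families).  Deterministic given ``seed``.
    """
    cfg = config or ClassifierConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features/labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    forest = RandomForestClassifier(n_estimators=cfg.n_trees,
                                    max_features=cfg.max_features,
                                    random_state=seed, n_jobs=1)
    forest.fit(X, y)
    model = InteractionModel(forest=forest, pca=pca,
                             families=tuple(families), seed=seed, config=cfg)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} columns for "
                         f"families {families}, got {X.shape[1]}")
    return model


def predict(model: InteractionModel, features: np.ndarray) -> np.ndarray:
    """Per-frame interaction decision: majority tree vote at 0.5."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(f"feature dimension {X.shape[1]} does not match "
                         f"model's {model.n_features}")
    proba = model.forest.predict_proba(X)
    classes = list(model.forest.classes_)
    p_true = proba[:, classes.index(True)] if True in classes \
        else np.zeros(X.shape[0])
    return p_true >= 0.5


def f1_score_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 = 2TP / (2TP + FP + FN); defined as 0 when the denominator is 0."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int(np.count_nonzero(y_true & y_pred))
    fp = int(np.count_nonzero(~y_true & y_pred))
    fn = int(np.count_nonzero(y_true & ~y_pred))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


@dataclass
class EvaluationResult:
    """Per-subject, per-hand F1 and accuracy with means and SDs."""

    per_subject: pd.DataFrame   # columns subject, F1_L, F1_R, acc_L, acc_R
    families: tuple[str, ...]

    def _stats(self, col: str) -> tuple[float, float]:
        vals = self.per_subject[col].dropna().to_numpy()
        if vals.size == 0:
            return float("nan"), float("nan")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return float(vals.mean()), sd

    @property
    def mean_f1(self) -> float:
        vals = self.per_subject[["F1_L", "F1_R"]].to_numpy(dtype=float)
        return float(np.nanmean(vals))

    @property
    def mean_accuracy(self) -> float:
        vals = self.per_subject[["acc_L", "acc_R"]].to_numpy(dtype=float)
        return float(np.nanmean(vals))

    def summary(self) -> pd.DataFrame:
        rows = {}
        for col in ("F1_L", "F1_R", "acc_L", "acc_R"):
            m, s = self._stats(col)
            rows[col] = {"mean": m, "sd": s}
        return pd.DataFrame(rows).T

    def to_csv(self, path: str | Path) -> None:
        self.per_subject.to_csv(path, index=False)


def _score_filtered(test: SubjectData, y_pred: np.ndarray) -> dict:
    """Score a held-out subject on filtered per-hand timelines.

    Filtered scoring: the per-frame decisions are assembled
    into a timeline per hand (with the 90-frame bridging of sudden hand
    loss), the 120-frame moving average + 0.5 threshold is applied, and
    the manually labelled timeline receives the identical filtering before
    F1 and accuracy are computed over all frames.
    """
    from .timeline import build_timeline, smooth_threshold

    n_frames = test.n_frames
    out = {}
    for hand, suffix in (("left", "L"), ("right", "R")):
        sel = test.hands == hand
        pred_states = {
            int(f): ("interaction" if p else "no_interaction")
            for f, p in zip(test.frame_index[sel], y_pred[sel])}
        pred_seq = smooth_threshold(
            build_timeline(pred_states, n_frames, test.fps))
        gt_sel = test.gt_hand == hand
        if not gt_sel.any():
            out[f"F1_{suffix}"] = np.nan
            out[f"acc_{suffix}"] = np.nan
            continue
        true_states = {
            int(f): ("interaction" if l else "no_interaction")
            for f, l in zip(np.nonzero(gt_sel)[0], test.gt_label[gt_sel])}
        true_seq = smooth_threshold(
            build_timeline(true_states, n_frames, test.fps))
        out[f"F1_{suffix}"] = f1_score_binary(true_seq == 1, pred_seq == 1)
        out[f"acc_{suffix}"] = float(np.mean(true_seq == pred_seq))
    return out


def evaluate_loso(dataset: list[SubjectData], seed: int = 0,
                  config: ClassifierConfig | None = None,
                  feature_config: FeatureConfig | None = None,
                  families=FAMILIES,
                  smooth_timelines: bool = False) -> EvaluationResult:
    """Leave-one-subject-out evaluation.

    Per fold the shape PCA and the forest are refitted on the training
    subjects only; the held-out subject is scored per hand (left/right).
    Raw per-frame decisions are scored by default.  With
    ``smooth_timelines`` on (and a dataset carrying timeline ground
    truth), scoring instead follows the filtered protocol — gap-bridged
    timelines, moving-average filter and threshold applied to both
    predicted and manual timelines — which is meaningful only when task
    durations are long relative to the 120-frame filter window.  A held-out hand with no frames is reported as NaN.
    """
    if len(dataset) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    rows = []
    use_shape = "shape" in families
    for i, test in enumerate(dataset):
        train_subjects = [s for j, s in enumerate(dataset) if j != i]
        assert all(s.subject != test.subject for s in train_subjects)
        pca = None
        if use_shape:
            hog_train = np.vstack([s.hog_raw for s in train_subjects])
            pca = fit_shape_pca(hog_train, feature_config)
            X_train = _assemble(train_subjects, pca)
            X_test = _assemble([test], pca)
        else:
            X_train = np.vstack([np.hstack([s.motion, s.colour])
                                 for s in train_subjects])
            X_test = np.hstack([test.motion, test.colour])
            # column layout for partial families handled below
        full_cols_train = _with_zero_shape(X_train) if not use_shape else X_train
        full_cols_test = _with_zero_shape(X_test) if not use_shape else X_test
        Xtr = select_families(full_cols_train, families)
        Xte = select_families(full_cols_test, families)
        y_train = np.concatenate([s.labels for s in train_subjects])
        model = train(Xtr, y_train, seed=seed, config=config, pca=pca,
                      families=families)
        y_pred = predict(model, Xte)
        row = {"subject": test.subject}
        if smooth_timelines and test.has_timeline:
            row.update(_score_filtered(test, y_pred))
        else:
            for hand, suffix in (("left", "L"), ("right", "R")):
                sel = test.hands == hand
                if not sel.any():
                    row[f"F1_{suffix}"] = np.nan
                    row[f"acc_{suffix}"] = np.nan
                    continue
                yt, yp = test.labels[sel], y_pred[sel]
                row[f"F1_{suffix}"] = f1_score_binary(yt, yp)
                row[f"acc_{suffix}"] = float(np.mean(yt == yp))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject", "F1_L", "F1_R",
                                     "acc_L", "acc_R"])
    return EvaluationResult(per_subject=df, families=tuple(families))


def _with_zero_shape(X: np.ndarray) -> np.ndarray:
    """Pad motion++colour columns back to the 122-column layout with a zero
    shape block, so family selection indexes stay uniform."""
    n = X.shape[0]
    return np.hstack([X[:, :60], np.zeros((n, 60)), X[:, 60:]])


def ablate(dataset: list[SubjectData], family: str, seed: int = 0,
           config: ClassifierConfig | None = None,
           feature_config: FeatureConfig | None = None,
           smooth_timelines: bool = False) -> EvaluationResult:
    """LOSO with the feature columns restricted to one family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    return evaluate_loso(dataset, seed=seed, config=config,
                         feature_config=feature_config, families=(family,),
                         smooth_timelines=smooth_timelines)
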