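"""Synthetic egocentric scenes with full ground truth.

The generator renders the minimal geometry that exercises every pipeline
stage: a skin-coloured elliptical hand with a uniform arm strip running
from the hand to a frame border (entry side fixes the true arm angle and
therefore the handedness), an optional object that either translates
rigidly with the hand (interaction) or follows its own path
(no interaction), and a seeded noise-textured background.  Ground truth
carries per-frame masks, tight boxes, the true arm angle, handedness and
interaction labels, plus the functional metrics derived from the labels.
Photo-realism is a non-goal; co-motion operationalises "the hand
manipulates the object".

Skin pixels are synthesised in YCbCr around the chroma cluster of the
bundled skin model, so segmentation fixtures are self-consistent with the
back-projection stage by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.color import ycbcr2rgb
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from scipy import ndimage as ndi

from .detection import BoundingBox
from .timeline import HandUseMetrics, extract_metrics
from .video_io import Frame, frames_from_array

ENTRY_SIDES = ("bottom-left", "bottom-right", "top")
COUPLINGS = ("moves_with_hand", "independent", "absent")

#: true-arm-angle sampling range (degrees) per entry side, inside the
#: corresponding quadrant with a safety margin
_ANGLE_RANGES = {"bottom-left": (285.0, 345.0),
                 "bottom-right": (195.0, 255.0),
                 "top": (45.0, 135.0)}
_SIDE_HANDEDNESS = {"bottom-left": "left", "bottom-right": "right",
                    "top": "other"}


@dataclass
class SceneSpec:
    """Full description of one synthetic scene; fixed seed implies
    bit-identical output."""

    n_frames: int = 60
    fps: float = 30.0
    frame_h: int = 120
    frame_w: int = 160
    entry_side: str = "bottom-left"
    coupling: str = "moves_with_hand"
    seed: int = 0
    #: per-frame hand-centre path (n_frames, 2) as (x, y); auto-generated
    #: from the seed when None
    trajectory: np.ndarray | None = None
    hand_moves: bool = True
    #: hand ellipse semi-axis along y, as a fraction of frame height
    hand_ry_frac: float = 0.095
    hand_aspect: float = 1.3          # rx = aspect * ry
    arm_width_frac: float = 0.75      # arm width relative to 2*ry
    arm_angle_deg: float | None = None  # sampled from the entry side if None
    skin_y: float = 170.0             # luma of the skin tone (YCbCr)
    skin_cb: float = 110.0
    skin_cr: float = 152.0
    #: amplitude of the luma texture (shading/wrinkles) that translates
    #: rigidly with the hand, 8-bit units
    skin_noise: float = 10.0
    object_noise: float = 18.0        # object surface texture amplitude
    object_colour: tuple[int, int, int] = (40, 70, 210)
    #: (w, h) px; None samples a hand-comparable size per scene (ADL
    #: objects -- cups, phones, utensils -- span roughly the hand's scale)
    object_size: tuple[int, int] | None = None
    background_rgb: tuple[int, int, int] = (95, 115, 100)
    background_noise: float = 15.0    # per-pixel noise amplitude (8-bit)
    background_smooth: float = 0.6    # gaussian sigma on the noise texture

    def __post_init__(self):
        if self.entry_side not in ENTRY_SIDES:
            raise ValueError(f"unknown entry side {self.entry_side!r}")
        if self.coupling not in COUPLINGS:
            raise ValueError(f"unknown coupling {self.coupling!r}")


@dataclass
class GroundTruth:
    """Per-frame truth for one scene."""

    hand_mask: np.ndarray          # (N, H, W) bool — the hand ellipse
    skin_mask: np.ndarray          # (N, H, W) bool — ellipse + arm strip
    hand_box: list[BoundingBox]    # tight box of the ellipse
    skin_box: list[BoundingBox]    # tight box of all skin pixels
    handedness: str
    arm_angle_deg: float
    labels: np.ndarray             # (N,) bool, True = interaction
    fps: float
    metrics: HandUseMetrics = field(init=False)

    def __post_init__(self):
        self.metrics = extract_metrics(self.labels.astype(int), self.fps)


def _tight_box(mask: np.ndarray) -> BoundingBox:
    rows, cols = np.nonzero(mask)
    return BoundingBox(x=int(cols.min()), y=int(rows.min()),
                       w=int(cols.max() - cols.min() + 1),
                       h=int(rows.max() - rows.min() + 1))


def _auto_trajectory(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random walk that keeps the whole hand inside the frame."""
    ry = spec.hand_ry_frac * spec.frame_h
    rx = spec.hand_aspect * ry
    mx = rx + 2.0
    my = ry + 2.0
    lo = np.array([mx, my])
    hi = np.array([spec.frame_w - mx, spec.frame_h - my])
    # an egocentric hand works in the region adjacent to its arm's entry
    # border; it cannot plausibly hover in the far opposite corner with
    # the forearm crossing the whole view
    if spec.entry_side == "bottom-left":
        hi[0] = min(hi[0], 0.75 * spec.frame_w)
        lo[1] = max(lo[1], 0.30 * spec.frame_h)
    elif spec.entry_side == "bottom-right":
        lo[0] = max(lo[0], 0.25 * spec.frame_w)
        lo[1] = max(lo[1], 0.30 * spec.frame_h)
    else:  # top
        hi[1] = min(hi[1], 0.60 * spec.frame_h)
    # start in the frame region adjacent to the entry border
    if spec.entry_side == "bottom-left":
        start = np.array([spec.frame_w * 0.30, spec.frame_h * 0.65])
    elif spec.entry_side == "bottom-right":
        start = np.array([spec.frame_w * 0.70, spec.frame_h * 0.65])
    else:
        start = np.array([spec.frame_w * 0.50, spec.frame_h * 0.35])
    start = start + rng.uniform(-6, 6, size=2)
    start = np.clip(start, lo, hi)
    if not spec.hand_moves:
        return np.tile(start, (spec.n_frames, 1))
    pos = start.copy()
    vel = rng.uniform(-1.0, 1.0, size=2)
    vel *= 2.5 / max(np.linalg.norm(vel), 1e-9)
    path = []
    for _ in range(spec.n_frames):
        path.append(pos.copy())
        vel += rng.normal(0.0, 0.35, size=2)
        speed = np.linalg.norm(vel)
        if speed > 3.5:
            vel *= 3.5 / speed
        pos = pos + vel
        for k in range(2):  # reflect off the margins
            if pos[k] < lo[k]:
                pos[k] = 2 * lo[k] - pos[k]
                vel[k] = -vel[k]
            if pos[k] > hi[k]:
                pos[k] = 2 * hi[k] - pos[k]
                vel[k] = -vel[k]
        pos = np.clip(pos, lo, hi)
    return np.array(path)


def _arm_polygon(cx: float, cy: float, theta_deg: float, width: float,
                 H: int, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise the arm strip from (cx, cy) along the ray at
    ``theta_deg`` (0 deg = West, clockwise through top) to the border."""
    t = np.deg2rad(theta_deg)
    ux, uy = -np.cos(t), -np.sin(t)
    nx, ny = uy, -ux
    L = float(np.hypot(H, W)) + 4
    half = width / 2.0
    xs = [cx + nx * half, cx - nx * half,
          cx - nx * half + ux * L, cx + nx * half + ux * L]
    ys = [cy + ny * half, cy - ny * half,
          cy - ny * half + uy * L, cy + ny * half + uy * L]
    rr, cc = draw_polygon(np.array(ys), np.array(xs), shape=(H, W))
    return rr, cc


def generate_scene(spec: SceneSpec) -> tuple[list[Frame], GroundTruth]:
    """Render a scene and its ground truth; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.frame_h, spec.frame_w
    N = spec.n_frames

    traj = spec.trajectory if spec.trajectory is not None \
        else _auto_trajectory(spec, rng)
    traj = np.asarray(traj, dtype=np.float64)
    if traj.shape != (N, 2):
        raise ValueError(f"trajectory must be ({N}, 2)")
    if (np.any(traj[:, 0] < 0) or np.any(traj[:, 0] >= W)
            or np.any(traj[:, 1] < 0) or np.any(traj[:, 1] >= H)):
        raise ValueError("hand trajectory leaves the frame")

    if spec.arm_angle_deg is not None:
        theta = float(spec.arm_angle_deg)
    else:
        theta = float(rng.uniform(*_ANGLE_RANGES[spec.entry_side]))

    if spec.object_size is None:
        ry0 = spec.hand_ry_frac * H
        obj_size = (int(rng.integers(round(1.0 * ry0), round(2.2 * ry0))),
                    int(rng.integers(round(0.8 * ry0), round(1.8 * ry0))))
    else:
        obj_size = tuple(spec.object_size)

    ry = spec.hand_ry_frac * H
    rx = spec.hand_aspect * ry
    arm_w = spec.arm_width_frac * 2 * ry

    # static background texture (camera assumed still within a scene)
    base = np.array(spec.background_rgb, dtype=np.float64)
    noise = rng.normal(0.0, spec.background_noise, size=(H, W, 3))
    if spec.background_smooth > 0:
        noise = ndi.gaussian_filter(noise, (spec.background_smooth,
                                            spec.background_smooth, 0))
    background = np.clip(base[None, None, :] + noise, 0, 255)

    skin_rgb = np.clip(ycbcr2rgb(np.array(
        [[[spec.skin_y, spec.skin_cb, spec.skin_cr]]])), 0, 1)[0, 0] * 255.0

    # object path
    if spec.coupling == "independent":
        # a non-manipulated object must stay clear of the hand's box:
        # at frame level an un-manipulated object inside the box is
        # indistinguishable from a held one, so the ground-truth label
        # would not be decodable from the scene.  Seeded rejection
        # sampling keeps the closest approach above `min_sep`.
        min_sep = 35.0
        best_path, best_d = None, -1.0
        for _ in range(25):
            oy = rng.uniform(0.12 * H, 0.55 * H)
            ox0 = rng.uniform(0.05 * W, 0.95 * W)
            ovx = rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0])
            cand = np.array([[ox0 + ovx * i, oy] for i in range(N)])
            cand[:, 0] = np.abs(cand[:, 0] % (2 * W - 2))
            cand[:, 0] = np.where(cand[:, 0] >= W,
                                  2 * W - 2 - cand[:, 0], cand[:, 0])
            d = float(np.min(np.hypot(cand[:, 0] - traj[:, 0],
                                      cand[:, 1] - traj[:, 1])))
            if d > best_d:
                best_path, best_d = cand, d
            if d >= min_sep:
                break
        obj_path = best_path
    elif spec.coupling == "moves_with_hand":
        # held object: fixed offset beside the hand, just above it
        off = np.array([0.9 * rx * rng.choice([-1.0, 1.0]), -1.1 * ry])
        obj_path = traj + off[None, :]
    else:
        obj_path = None

    # surface textures are fixed fields sampled at coordinates relative to
    # their owner's centre, so they translate rigidly with the hand/object
    # (a flow estimator must be able to track a moving surface)
    skin_tex = ndi.gaussian_filter(
        rng.normal(0.0, spec.skin_noise, size=(H, W)), 0.8)
    obj_tex = rng.normal(0.0, spec.object_noise, size=(H, W))
    yy, xx = np.mgrid[0:H, 0:W]

    frames = np.empty((N, H, W, 3), dtype=np.uint8)
    hand_masks = np.zeros((N, H, W), dtype=bool)
    skin_masks = np.zeros((N, H, W), dtype=bool)
    hand_boxes, skin_boxes = [], []
    for i in range(N):
        img = background.copy()
        cx, cy = traj[i]
        hand = np.zeros((H, W), dtype=bool)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(H, W))
        hand[rr, cc] = True
        arm = np.zeros((H, W), dtype=bool)
        ar, ac = _arm_polygon(cx, cy, theta, arm_w, H, W)
        arm[ar, ac] = True
        skin = hand | arm
        tex = skin_tex[(yy[skin] - int(round(cy))) % H,
                       (xx[skin] - int(round(cx))) % W]
        img[skin] = np.clip(skin_rgb[None, :] + tex[:, None], 0, 255)

        if obj_path is not None:
            ox, oy = obj_path[i]
            ow, oh = obj_size
            x0 = int(np.clip(round(ox - ow / 2), 0, W - 1))
            y0 = int(np.clip(round(oy - oh / 2), 0, H - 1))
            x1, y1 = min(x0 + ow, W), min(y0 + oh, H)
            obj_region = np.zeros((H, W), dtype=bool)
            obj_region[y0:y1, x0:x1] = True
            obj_region &= ~skin   # the hand occludes the held object
            otex = obj_tex[(yy[obj_region] - int(round(oy))) % H,
                           (xx[obj_region] - int(round(ox))) % W]
            img[obj_region] = np.clip(
                np.array(spec.object_colour, dtype=np.float64)[None, :]
                + otex[:, None], 0, 255)

        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
        hand_masks[i] = hand
        skin_masks[i] = skin
        hand_boxes.append(_tight_box(hand))
        skin_boxes.append(_tight_box(skin))

    labels = np.full(N, spec.coupling == "moves_with_hand")
    truth = GroundTruth(hand_mask=hand_masks, skin_mask=skin_masks,
                        hand_box=hand_boxes, skin_box=skin_boxes,
                        handedness=_SIDE_HANDEDNESS[spec.entry_side],
                        arm_angle_deg=theta, labels=labels, fps=spec.fps)
    return frames_from_array(frames, fps=spec.fps), truth


@dataclass
class SyntheticSubject:
    """One simulated participant: an ordered list of scene segments."""

    subject: str
    scenes: list[tuple[SceneSpec, list[Frame], GroundTruth]]

    @property
    def n_frames(self) -> int:
        return sum(len(f) for _, f, _ in self.scenes)

    @property
    def positive_rate(self) -> float:
        lab = np.concatenate([t.labels for _, _, t in self.scenes])
        return float(lab.mean())


def generate_subjects(n_subjects: int, frames_per_subject: int = 600,
                      positive_frac: float = 0.48, seed: int = 0,
                      n_segments: int = 12,
                      frame_h: int = 120, frame_w: int = 160,
                      fps: float = 30.0,
                      per_subject_specs: Sequence[Sequence[SceneSpec]] | None = None,
                      ) -> list[SyntheticSubject]:
    """A LOSO-ready cohort of simulated participants.

    Each subject is a sequence of segments alternating between interactive
    tasks (object co-moving with the hand) and non-interactive ones
    (independent object, or empty hand at rest / waved), with the
    interactive share of frames set by ``positive_frac`` (default matches
    a balanced 48%/52% split).  Left and right hands alternate across
    segments so both are represented.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        if per_subject_specs is not None:
            specs = list(per_subject_specs[s])
        else:
            n_pos_frames = int(round(positive_frac * frames_per_subject))
            k_pos = max(1, n_segments // 2)
            k_neg = n_segments - k_pos
            pos_lens = _split(n_pos_frames, k_pos)
            neg_lens = _split(frames_per_subject - n_pos_frames, k_neg)
            specs = []
            sides = ["bottom-left", "bottom-right"]
            neg_couplings = ["independent", "absent"]
            pi = ni = 0
            neg_count = {"bottom-left": 0, "bottom-right": 0}
            for seg in range(n_segments):
                interactive = seg % 2 == 0 and pi < k_pos
                if not interactive and ni >= k_neg:
                    interactive = True
                side = sides[(seg // 2 + s) % 2]
                if interactive:
                    coupling, n_fr = "moves_with_hand", pos_lens[pi]
                    pi += 1
                else:
                    # alternate the non-interaction task type per hand
                    # (and rotate by subject) so neither hand nor subject
                    # is confounded with a single negative type
                    coupling = neg_couplings[(neg_count[side] + s) % 2]
                    neg_count[side] += 1
                    n_fr = neg_lens[ni]
                    ni += 1
                specs.append(SceneSpec(
                    n_frames=n_fr, fps=fps, frame_h=frame_h, frame_w=frame_w,
                    entry_side=side, coupling=coupling,
                    hand_moves=(coupling != "absent") or (seg % 4 == 0),
                    seed=int(rng.integers(0, 2**31 - 1))))
        scenes = [(sp, *generate_scene(sp)) for sp in specs]
        subjects.append(SyntheticSubject(subject=f"S{s + 1}", scenes=scenes))
    return subjects


def _split(total: int, k: int) -> list[int]:
    base = total // k
    out = [base] * k
    for i in range(total - base * k):
        out[i] += 1
    return out


def dataset_manifest(subjects: list[SyntheticSubject]) -> dict:
    """Per-scene content hashes; identical seeds give identical manifests."""
    manifest = {}
    for sub in subjects:
        entries = []
        for spec, frames, truth in sub.scenes:
            h = hashlib.sha256()
            for f in frames:
                h.update(f.pixels.tobytes())
            h.update(truth.labels.tobytes())
            entries.append({"n_frames": spec.n_frames,
                            "coupling": spec.coupling,
                            "entry_side": spec.entry_side,
                            "sha256": h.hexdigest()})
        manifest[sub.subject] = entries
    return manifest


def generate_timeline(target: HandUseMetrics | dict, n_frames: int,
                      fps: float, seed: int = 0) -> np.ndarray:
    """Construct a binary sequence whose extracted metrics equal ``target``
    exactly (the metric formulas inverted analytically).

    Raises when the targets are mutually inconsistent or do not fit in
    ``n_frames`` (non-integer run counts/lengths, or runs that cannot be
    separated by at least one gap frame).
    """
    if isinstance(target, dict):
        target = HandUseMetrics(**target)
    if target.mean_duration_s is None or target.interactions_per_hour is None:
        if target.pct_interaction != 0:
            raise ValueError("undefined duration/count requires pct == 0")
        return np.zeros(n_frames, dtype=np.int64)

    n_runs_f = target.interactions_per_hour * n_frames / fps / 3600.0
    run_len_f = target.mean_duration_s * fps
    n_runs, run_len = round(n_runs_f), round(run_len_f)
    if abs(n_runs_f - n_runs) > 1e-6 or abs(run_len_f - run_len) > 1e-6 \
            or n_runs < 1 or run_len < 1:
        raise ValueError("targets imply a non-integral number/length of runs")
    ones = n_runs * run_len
    if abs(target.pct_interaction - 100.0 * ones / n_frames) > 1e-9:
        raise ValueError("pct_interaction inconsistent with count x duration")
    zeros = n_frames - ones
    if zeros < n_runs - 1:
        raise ValueError("runs do not fit with separating gaps")

    rng = np.random.default_rng(seed)
    # distribute zero frames over the n_runs + 1 gaps (interior gaps >= 1)
    interior = n_runs - 1
    extra = zeros - interior
    alloc = rng.multinomial(extra, np.ones(n_runs + 1) / (n_runs + 1))
    gaps = alloc.copy()
    gaps[1:-1] += 1
    seq = []
    for g, r in zip(gaps[:-1], [run_len] * n_runs):
        seq.extend([0] * int(g))
        seq.extend([1] * r)
    seq.extend([0] * int(gaps[-1]))
    out = np.array(seq, dtype=np.int64)
    assert out.size == n_frames
    return out
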