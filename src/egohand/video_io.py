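"""Video decoding and tabular interchange I/O.

Frames are standardised to a 480-pixel analysis height (aspect ratio
preserved) regardless of the capture resolution; all downstream stages
operate at this resolution.  Tabular interchange (labels, detections,
timelines) is plain CSV with a mandatory header and 0-based frame indices;
metrics are JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize
from skimage.util import img_as_ubyte

HANDS = ("left", "right", "other")
STATES = ("interaction", "no_interaction", "hand_absent")


@dataclass(frozen=True)
class Frame:
    """One decoded image at analysis resolution.

    ``time_s`` is derived as ``index / fps``; ``pixels`` is H x W x 3 uint8.
    """

    pixels: np.ndarray
    index: int
    fps: float

    @property
    def time_s(self) -> float:
        return self.index / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Luma view on [0, 1] (Rec. 601 weights)."""
        p = self.pixels.astype(np.float64) / 255.0
        return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


@dataclass(frozen=True)
class LabelRecord:
    """A manual per-frame annotation for one hand."""

    frame: int
    hand: str
    state: str

    def __post_init__(self):
        if self.hand not in HANDS:
            raise ValueError(f"unknown hand {self.hand!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


def _standardize(img: np.ndarray, target_height: int) -> np.ndarray:
    """Resize to the analysis height, aspect preserved, width rounded to the
    nearest even integer.  Identity when already at the target height."""
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    h, w = img.shape[:2]
    if h == target_height:
        return np.ascontiguousarray(img)
    new_w = 2 * round(w * target_height / h / 2)
    out = resize(img, (target_height, max(new_w, 2)), anti_aliasing=True,
                 preserve_range=True)
    return img_as_ubyte(np.clip(out / 255.0, 0, 1))


def frames_from_array(stack: np.ndarray, fps: float = 30.0,
                      target_height: int | None = None) -> list[Frame]:
    """Wrap an (N, H, W, 3) uint8 array as a frame sequence."""
    out = []
    for i, img in enumerate(stack):
        if target_height is not None:
            img = _standardize(np.asarray(img), target_height)
        out.append(Frame(pixels=np.asarray(img, dtype=np.uint8), index=i, fps=fps))
    return out


def read_video(path: str | Path, target_height: int = 480,
               fps: float | None = None) -> list[Frame]:
    """Decode a video file (or image stack / .npy frame stack) to frames.

    Every frame is resized so its height equals ``target_height`` with the
    aspect ratio preserved (width rounded to the nearest even integer).
    ``fps`` is read from container metadata when available, with a fallback
    of 30 fps; an explicit ``fps`` argument overrides both.
    """
    path = Path(path)
    if target_height < 16:
        raise ValueError("target_height must be >= 16")
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")

    if path.suffix == ".npy":
        stack = np.load(path)
        frames = list(stack)
        meta_fps = None
    else:
        import imageio.v3 as iio
        try:
            data = iio.imread(path)
        except Exception as exc:  # pragma: no cover - codec dependent
            raise IOError(f"could not decode video file {path}: {exc}") from exc
        data = np.asarray(data)
        if data.ndim == 3 and data.shape[-1] in (3, 4):
            frames = [data]
        elif data.ndim == 2:
            frames = [data]
        else:
            frames = list(data)
        meta_fps = None
        try:
            meta = iio.immeta(path)
            meta_fps = meta.get("fps")
        except Exception:
            pass

    if len(frames) == 0:
        raise IOError(f"video file {path} contains zero frames")
    use_fps = fps if fps is not None else (meta_fps or 30.0)
    out = []
    for i, img in enumerate(frames):
        std = _standardize(np.asarray(img), target_height)
        out.append(Frame(pixels=std, index=i, fps=float(use_fps)))
    return out


def read_labels(path: str | Path) -> list[LabelRecord]:
    """Read manual interaction labels from CSV (header ``frame,hand,state``).

    Raises on unknown tokens or duplicate (frame, hand) pairs, naming the
    offending line.
    """
    df = pd.read_csv(path, dtype=str)
    expected = ["frame", "hand", "state"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"label CSV must have header {','.join(expected)}, "
                         f"got {','.join(df.columns)}")
    records: list[LabelRecord] = []
    seen: set[tuple[int, str]] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = LabelRecord(frame=int(row.frame), hand=row.hand, state=row.state)
        except ValueError as exc:
            raise ValueError(f"{path}, line {pos}: {exc}") from exc
        key = (rec.frame, rec.hand)
        if key in seen:
            raise ValueError(f"{path}, line {pos}: duplicate record for "
                             f"frame {rec.frame}, hand {rec.hand}")
        seen.add(key)
        records.append(rec)
    return records


def write_labels(records: Iterable[LabelRecord], path: str | Path) -> None:
    df = pd.DataFrame([(r.frame, r.hand, r.state) for r in records],
                      columns=["frame", "hand", "state"])
    df.to_csv(path, index=False)


def write_metrics(metrics: dict, path: str | Path) -> None:
    """Write per-hand functional metrics as JSON.

    ``metrics`` maps hand -> dict with keys ``pct_interaction``,
    ``mean_duration_s``, ``interactions_per_hour`` (values may be None for
    metrics undefined on a video with no interactions).
    """
    out = {}
    for hand, m in metrics.items():
        entry = {}
        for key in ("pct_interaction", "mean_duration_s", "interactions_per_hour"):
            v = m.get(key) if isinstance(m, dict) else getattr(m, key)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"non-finite metric {key} for hand {hand}")
            entry[key] = v
        out[hand] = entry
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))


def read_metrics(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_timeline_csv(states: dict[str, Sequence[str]], path: str | Path) -> None:
    """Write per-frame states per hand (columns left/right/other_state)."""
    n = len(next(iter(states.values())))
    df = pd.DataFrame({"frame": np.arange(n)})
    for hand in HANDS:
        if hand in states:
            df[f"{hand}_state"] = list(states[hand])
    df.to_csv(path, index=False)


def read_timeline_csv(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path)
    out = {}
    for hand in HANDS:
        col = f"{hand}_state"
        if col in df.columns:
            vals = [str(v) for v in df[col]]
            bad = set(vals) - set(STATES)
            if bad:
                raise ValueError(f"unknown states {bad} in {path}")
            out[hand] = vals
    return out
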