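# egohand

Measuring functional hand use from egocentric video.

For people with impaired upper-extremity function — e.g. after cervical
spinal cord injury — how much the hands are actually *used* at home is a
more meaningful outcome than clinic-based capacity tests, but today it is
only accessible through self-report or direct observation. `egohand`
implements an automated alternative: from first-person video recorded by
a head-mounted camera, it produces a binary hand–object-interaction
timeline for each of the user's hands and reduces it to three functional
measures

* **percentage of interaction time** — 100 · t_interaction / t_total,
* **mean interaction duration** (seconds),
* **interactions per hour**,

which satisfy `pct = n · mean / total · 100` exactly.

The pipeline: per-frame hand boxes (pluggable detector, with a
self-contained skin-blob baseline) → box verification and left/right/other
assignment from a rotating three-rectangle Haar-like feature (the
72-value arm-angle vector; quadrant with the largest summed response
decides the hand) → skin + edge hand segmentation with contour filters
and box re-centring → a 122-value feature per frame (60 optical-flow
difference-histogram values, 60 PCA-reduced HOG values, 2 Bhattacharyya
colour distances) → a 150-tree random forest interaction classifier →
per-hand timelines with 90-frame gap bridging, a 120-frame moving-average
filter, min–max normalisation and a 0.5 threshold → the three metrics.
Agreement with manual annotation across subjects is assessed by a
one-tailed Pearson or Spearman correlation, chosen by a Shapiro–Wilk
normality check.

Every stage is testable without any external data: the `synthetic` module
renders egocentric-like scenes (skin-textured hand + arm entering from a
border, objects that move with the hand or independently, textured
background) with full ground truth — masks, boxes, handedness, labels and
the true metrics. See `docs/methods.md` for the model, its assumptions
and what the synthetic scenes do and do not emulate.

## Worked example

```python
import numpy as np
import egohand as eh

# a 30-second synthetic video: a left hand uses an object for 15 s,
# then rests empty for 15 s
cfg = eh.PipelineConfig(seed=5)
task = eh.SceneSpec(seed=55, n_frames=450, coupling="moves_with_hand")
rest = eh.SceneSpec(seed=56, n_frames=450, coupling="absent",
                    hand_moves=False)
frames_a, _ = eh.generate_scene(task)
frames_b, _ = eh.generate_scene(rest)
stack = np.stack([f.pixels for f in frames_a + frames_b])
frames = eh.frames_from_array(stack, fps=30.0)

# train the model bundle (skin model, box verifier, interaction forest)
# on a synthetic cohort, then run the full pipeline
subjects = eh.generate_subjects(4, frames_per_subject=600, seed=5)
bundle = eh.train_models(subjects, seed=5, config=cfg)
result = eh.run_pipeline(frames, bundle, cfg)

m = result.metrics["left"]
print(f"left hand: {m.pct_interaction:.1f}% of time, "
      f"mean bout {m.mean_duration_s:.2f} s, "
      f"{m.interactions_per_hour:.0f} interactions/h")
```

prints (training takes a few minutes on one CPU)

```
left hand: 50.0% of time, mean bout 15.00 s, 120 interactions/h
```

— the pipeline recovers the video's structure exactly: the hand
interacts for half the recording, in one 15-second bout, which
extrapolates to 120 interactions per hour. The right-hand timeline of
the same run stays empty
(`result.metrics["right"].pct_interaction == 0.0`).

The same flow is available from the shell:

```sh
egohand --seed 5 train --models models/
egohand --seed 5 simulate --n-subjects 2 --out scenes/
egohand run scenes/S1/scene_00.npy --models models/ --out out/
egohand --seed 5 evaluate-loso --n-subjects 5
```

`run` writes `metrics.json`, a per-frame `timeline.csv`
(frame, left/right/other state) and the exact config snapshot used.

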