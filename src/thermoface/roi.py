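"""Facial regions of interest and stimulation-locked feature extraction.

Five regions are analysed: forehead, nose, mouth, left cheek and right
cheek.  Their rectangles are placed relative to the binocular midpoint and
scaled by the inter-ocular distance ``d``, so the layout adapts to face size
and position without manual landmarking.  Per-frame ROI means give one
temperature time series per region; windowing those series on the stimulus
schedule and subtracting a per-segment baseline yields the temperature-change
feature vectors used by the statistical stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import FeatureMatrix, ThermalSequence, ThermofaceError
from .schedule import (
    EmotionType,
    ScheduleEvent,
    StimulusSchedule,
    WindowPolicy,
    event_frame_range,
)

ROI_NAMES = ("forehead", "nose", "mouth", "left_cheek", "right_cheek")

#: Rectangle layout in units of the inter-ocular distance d, relative to the
#: binocular midpoint: (center_dx, center_dy, width, height).  Chosen so the
#: five regions are disjoint and sit inside a typical face oval; stored in
#: the ROI JSON so deployments can override.
_LAYOUT: dict[str, tuple[float, float, float, float]] = {
    "forehead": (0.0, -0.65, 1.6, 0.6),
    "nose": (0.0, 0.5, 0.5, 0.6),
    "mouth": (0.0, 1.1, 0.9, 0.4),
    "left_cheek": (-0.85, 0.5, 0.6, 0.6),
    "right_cheek": (0.85, 0.5, 0.6, 0.6),
}


class RoiError(ThermofaceError):
    pass


@dataclass
class RoiSet:
    """Named axis-aligned rectangles ``(x0, y0, x1, y1)``, half-open, 0-based."""

    rects: dict[str, tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        if set(self.rects) != set(ROI_NAMES):
            raise RoiError(f"ROI set must contain exactly {ROI_NAMES}")
        for name, (x0, y0, x1, y1) in self.rects.items():
            if x1 <= x0 or y1 <= y0:
                raise RoiError(f"ROI {name!r} is empty")

    def validate_bounds(self, frame_shape: tuple[int, int]) -> None:
        rows, cols = frame_shape
        for name, (x0, y0, x1, y1) in self.rects.items():
            if x0 < 0 or y0 < 0 or x1 > cols or y1 > rows:
                raise RoiError(f"ROI {name!r} exceeds frame bounds {frame_shape}")

    def pixel_counts(self) -> dict[str, int]:
        return {
            name: (x1 - x0) * (y1 - y0) for name, (x0, y0, x1, y1) in self.rects.items()
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({k: list(v) for k, v in self.rects.items()}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RoiSet":
        d = json.loads(Path(path).read_text())
        return cls({k: tuple(int(x) for x in v) for k, v in d.items()})


def roi_layout(
    eye_left: Sequence[float],
    eye_right: Sequence[float],
    layout: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> RoiSet:
    """Place the five ROI rectangles from the two eye centers (x, y)."""
    layout = dict(layout or _LAYOUT)
    ex = (eye_left[0] + eye_right[0]) / 2.0
    ey = (eye_left[1] + eye_right[1]) / 2.0
    d = float(np.hypot(eye_right[0] - eye_left[0], eye_right[1] - eye_left[1]))
    if d <= 0:
        raise RoiError("eye centers must be distinct")
    rects = {}
    for name, (cdx, cdy, w, h) in layout.items():
        cx, cy = ex + cdx * d, ey + cdy * d
        wpx, hpx = int(round(w * d)), int(round(h * d))
        x0 = int(round(cx - w * d / 2.0))
        y0 = int(round(cy - h * d / 2.0))
        rects[name] = (x0, y0, x0 + wpx, y0 + hpx)
    return RoiSet(rects)


def default_roi_set(
    frame_shape: tuple[int, int],
    eyes: tuple[Sequence[float], Sequence[float]],
) -> RoiSet:
    """Eye-anchored default ROI set, validated against the frame bounds."""
    rois = roi_layout(eyes[0], eyes[1])
    rois.validate_bounds(frame_shape)
    return rois


def extract_roi_series(
    sequence: ThermalSequence, rois: RoiSet
) -> dict[str, np.ndarray]:
    """Per-frame arithmetic-mean temperature of each ROI.

    Assumes the sequence is registered to the fixed image the ROI set was
    defined on.  A pixel belongs to a ROI iff its index lies inside the
    half-open rectangle.
    """
    rois.validate_bounds(sequence.frame_shape)
    out = {}
    for name, (x0, y0, x1, y1) in rois.rects.items():
        out[name] = sequence.frames[:, y0:y1, x0:x1].mean(axis=(1, 2)).astype(float)
    return out


# --------------------------------------------------------------------------
# Feature building


def _selected_events(
    schedule: StimulusSchedule, emotion: EmotionType, policy: WindowPolicy
) -> list[ScheduleEvent]:
    events = schedule.events_for(emotion)
    if policy.max_segments is not None:
        events = events[: policy.max_segments]
    return events


def _baseline_frames(
    schedule: StimulusSchedule, ev: ScheduleEvent, n_frames: int = 6
) -> tuple[int, int]:
    """Baseline window for one event: the final frames of the nearest
    preceding rest break, or the start of the sequence if there is none."""
    prior_rests = [
        e
        for e in schedule.events_for(EmotionType.REST)
        if e.end_s <= ev.start_s + 1e-9 and e is not ev
    ]
    if prior_rests:
        _, stop = event_frame_range(schedule, prior_rests[-1])
        return stop - n_frames, stop
    return 0, n_frames


def build_features(
    series: np.ndarray,
    schedule: StimulusSchedule,
    emotion: EmotionType,
    policy: WindowPolicy | None = None,
    baseline: str = "pre_segment",
) -> np.ndarray:
    """Stimulation-locked temperature-change feature vector for one ROI.

    Concatenates the policy window of every contributing event in temporal
    order.  Baseline rules:

    - ``"pre_segment"`` (default): subtract the mean of the final 3 s (6
      frames at 2 fps) of the rest break immediately preceding the event;
      the first event of the film falls back to the first 6 frames of the
      sequence.  Removes slow drift per segment.
    - ``"global"``: subtract the mean of the first 6 frames of the sequence.
    - ``"none"``: raw temperatures.
    """
    series = np.asarray(series, dtype=float)
    n_expected = int(round(schedule.total_duration_s * schedule.fps))
    if len(series) != n_expected:
        raise RoiError(
            f"series length {len(series)} does not match schedule ({n_expected} frames)"
        )
    policy = policy or WindowPolicy()
    feats: list[np.ndarray] = []
    for ev in _selected_events(schedule, emotion, policy):
        ev_start, ev_stop = event_frame_range(schedule, ev)
        start = ev_start + policy.offset_frames
        stop = start + policy.length_frames
        if stop > ev_stop:
            raise RoiError("window policy does not fit inside event")
        window = series[start:stop]
        if baseline == "pre_segment":
            b0, b1 = _baseline_frames(schedule, ev)
            window = window - series[b0:b1].mean()
        elif baseline == "global":
            window = window - series[:6].mean()
        elif baseline != "none":
            raise RoiError(f"unknown baseline rule {baseline!r}")
        feats.append(window)
    return np.concatenate(feats) if feats else np.empty(0)


@dataclass
class SubjectSeries:
    """Per-subject ROI temperature series with its group label."""

    subject_id: str
    group: str
    series: dict[str, np.ndarray]
    fps: float = 2.0


def cohort_feature_matrix(
    cohort: Sequence[SubjectSeries],
    schedule: StimulusSchedule,
    emotions: Sequence[EmotionType] | None = None,
    policy: WindowPolicy | None = None,
    baseline: str = "pre_segment",
) -> dict[tuple[str, EmotionType], FeatureMatrix]:
    """One ``n_subjects x n_features`` block per ROI x emotion.

    Group labels are row-aligned; subject order is preserved.
    """
    from .schedule import ALL_BLOCKS

    emotions = list(emotions or ALL_BLOCKS)
    blocks: dict[tuple[str, EmotionType], FeatureMatrix] = {}
    for roi in ROI_NAMES:
        for emo in emotions:
            rows = [
                build_features(s.series[roi], schedule, emo, policy, baseline)
                for s in cohort
            ]
            blocks[(roi, emo)] = FeatureMatrix(
                values=np.vstack(rows),
                labels=np.array([s.group for s in cohort]),
                roi=roi,
                emotion=emo.value,
            )
    return blocks
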