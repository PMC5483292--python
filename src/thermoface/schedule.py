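"""Emotion-stimulation timeline: segments, rest breaks, and frame windows.

The default protocol is a 225 s film: nine 15 s picture segments (five
pictures, 3 s each) interleaved with nine 10 s rest breaks.  Each picture
segment evokes one of three dimensional-emotion categories — HVLA (high
valence / low arousal), LVLA (low valence / low arousal) and LVHA (low
valence / high arousal) — and each category appears in exactly three
segments.  Thermal acquisition runs at 2 frames per second, so a full run
yields 450 frames per subject.

Feature extraction is stimulation-locked: for each emotion a fixed
per-segment response window (default: the first 16 frames, i.e. 8 s, of each
of its three segments) is concatenated, giving 48 frames per emotion.  The
same windowing applied to the first three rest breaks provides the
"no stimulus" block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import yaml

from .core import DEFAULT_FPS, ThermofaceError


class EmotionType(str, Enum):
    """Dimensional emotion categories plus rest."""

    HVLA = "HVLA"
    LVLA = "LVLA"
    LVHA = "LVHA"
    REST = "REST"


#: The three picture-evoked emotions, in default presentation order.
IMAGE_EMOTIONS = (EmotionType.HVLA, EmotionType.LVLA, EmotionType.LVHA)

#: All four feature blocks (REST = the "no stimulus" column).
ALL_BLOCKS = (EmotionType.HVLA, EmotionType.LVLA, EmotionType.LVHA, EmotionType.REST)


class ScheduleError(ThermofaceError):
    """Invalid schedule or window policy."""


@dataclass(frozen=True)
class ScheduleEvent:
    emotion: EmotionType
    start_s: float
    duration_s: float
    image_count: int = 0

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.duration_s <= 0:
            raise ScheduleError("event times must be non-negative / positive")
        if self.emotion is EmotionType.REST and self.image_count != 0:
            raise ScheduleError("rest breaks display no images")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class WindowPolicy:
    """Per-segment response sub-window, in frames.

    ``offset_frames`` frames are skipped from the segment start, then
    ``length_frames`` frames are taken.  At most ``max_segments`` matching
    events contribute (earliest first); ``None`` means all of them.  The
    default (0, 16, 3) yields 3 x 16 = 48 features per emotion on the
    default schedule.
    """

    offset_frames: int = 0
    length_frames: int = 16
    max_segments: int | None = 3

    def __post_init__(self) -> None:
        if self.offset_frames < 0 or self.length_frames <= 0:
            raise ScheduleError("invalid window policy")


@dataclass
class StimulusSchedule:
    events: list[ScheduleEvent]
    fps: float = DEFAULT_FPS
    image_duration_s: float = 3.0

    def __post_init__(self) -> None:
        t = 0.0
        for ev in self.events:
            if not math.isclose(ev.start_s, t, abs_tol=1e-9):
                raise ScheduleError("events must be contiguous and non-overlapping")
            if ev.image_count:
                if not math.isclose(
                    ev.image_count * self.image_duration_s, ev.duration_s, abs_tol=1e-9
                ):
                    raise ScheduleError(
                        "image_count x image_duration must equal segment duration"
                    )
            t = ev.end_s

    @property
    def total_duration_s(self) -> float:
        return sum(ev.duration_s for ev in self.events)

    def events_for(self, emotion: EmotionType) -> list[ScheduleEvent]:
        return [ev for ev in self.events if ev.emotion is emotion]

    def segment_count(self, emotion: EmotionType) -> int:
        return len(self.events_for(emotion))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fps": self.fps,
            "image_duration_s": self.image_duration_s,
            "events": [
                {
                    "emotion": ev.emotion.value,
                    "start_s": ev.start_s,
                    "duration_s": ev.duration_s,
                    "image_count": ev.image_count,
                }
                for ev in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        events = [
            ScheduleEvent(
                emotion=EmotionType(e["emotion"]),
                start_s=float(e["start_s"]),
                duration_s=float(e["duration_s"]),
                image_count=int(e.get("image_count", 0)),
            )
            for e in d["events"]
        ]
        return cls(
            events=events,
            fps=float(d.get("fps", DEFAULT_FPS)),
            image_duration_s=float(d.get("image_duration_s", 3.0)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "StimulusSchedule":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def build_default_schedule(
    fps: float = DEFAULT_FPS,
    segment_s: float = 15.0,
    break_s: float = 10.0,
    images_per_segment: int = 5,
    image_duration_s: float = 3.0,
    cycles: int = 3,
    emotion_order: Iterable[EmotionType] = IMAGE_EMOTIONS,
) -> StimulusSchedule:
    """The default 225 s protocol.

    ``cycles`` repetitions of the emotion cycle, each 15 s segment followed
    by a 10 s rest break: 9 segments + 9 breaks, three segments per emotion.
    """
    order = list(emotion_order)
    events: list[ScheduleEvent] = []
    t = 0.0
    for _ in range(cycles):
        for emo in order:
            events.append(ScheduleEvent(emo, t, segment_s, images_per_segment))
            t += segment_s
            events.append(ScheduleEvent(EmotionType.REST, t, break_s, 0))
            t += break_s
    return StimulusSchedule(events=events, fps=fps, image_duration_s=image_duration_s)


def total_frames(schedule: StimulusSchedule) -> int:
    """Number of frames a full acquisition of the schedule produces."""
    return int(round(schedule.total_duration_s * schedule.fps))


def event_frame_range(schedule: StimulusSchedule, ev: ScheduleEvent) -> tuple[int, int]:
    """Half-open frame range covered by one event (floor mapping)."""
    start = math.floor(ev.start_s * schedule.fps)
    stop = math.floor(ev.end_s * schedule.fps)
    return start, stop


def frame_windows(
    schedule: StimulusSchedule,
    emotion: EmotionType,
    policy: WindowPolicy | None = None,
) -> list[tuple[int, int]]:
    """Stimulation-locked frame windows for one emotion.

    Returns 0-based half-open ``(start, stop)`` ranges, one per contributing
    event, each ``policy.length_frames`` long and lying inside its event.
    """
    policy = policy or WindowPolicy()
    events = schedule.events_for(emotion)
    if policy.max_segments is not None:
        events = events[: policy.max_segments]
    windows: list[tuple[int, int]] = []
    for ev in events:
        ev_start, ev_stop = event_frame_range(schedule, ev)
        start = ev_start + policy.offset_frames
        stop = start + policy.length_frames
        if stop > ev_stop:
            raise ScheduleError(
                f"window policy ({policy.offset_frames}+{policy.length_frames} frames) "
                f"does not fit in a {ev.duration_s} s event at {ev.start_s} s"
            )
        windows.append((start, stop))
    return windows


def features_per_emotion(
    schedule: StimulusSchedule, emotion: EmotionType, policy: WindowPolicy | None = None
) -> int:
    return sum(stop - start for start, stop in frame_windows(schedule, emotion, policy))
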