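"""Synthetic thermal-face cohort generator with known ground truth.

Real patient thermal sequences are not publicly available, so every
downstream stage is exercised on a phantom: a face-shaped temperature field
(warm elliptical face on a cooler ambient background, rectangular ROI
plateaus, two cool "spectacle"-like eye disks) whose ROI temperatures follow
first-order exponential kinetics toward a per-ROI, per-emotion, per-group
response amplitude during matching stimulus segments and decay back toward
baseline during rest breaks.  Per-frame rigid-plus-mild-scale head jitter,
additive Gaussian sensor noise and a slow linear drift complete the model.

The generator returns the exact per-frame transforms and per-subject
response amplitudes it used, so registration recovery, feature extraction
and group statistics can all be checked against ground truth.

Two sampling paths share the same trajectory model:

- :func:`generate_subject` rasterises full frames (registration testing);
- :func:`generate_cohort_series` emits ROI-mean series directly (large
  cohort simulations for statistical calibration), with sensor noise scaled
  by the ROI pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .core import AffineParams, ThermalSequence, ThermofaceError
from .roi import ROI_NAMES, RoiSet, roi_layout, SubjectSeries
from .schedule import (
    EmotionType,
    IMAGE_EMOTIONS,
    StimulusSchedule,
    total_frames,
)

GROUPS = ("moderate", "marked")


class PhantomError(ThermofaceError):
    pass


def _default_amplitudes() -> dict[str, dict[str, dict[str, float]]]:
    """Group-mean response amplitudes, °C relative to ROI baseline.

    No effect sizes in °C are published for this paradigm; these defaults
    are plausible emotion-evoked skin-temperature responses chosen to mirror
    the qualitative group-difference pattern of interest: forehead responses
    differ between groups for every emotion (most for LVHA), nose responses
    (cooling) differ for every emotion, the right cheek differs under HVLA
    only, and the mouth/left cheek show no group difference.
    """
    mod = {
        "forehead": {"HVLA": 0.25, "LVLA": 0.25, "LVHA": 0.25},
        "nose": {"HVLA": -0.20, "LVLA": -0.20, "LVHA": -0.20},
        "mouth": {"HVLA": 0.15, "LVLA": 0.15, "LVHA": 0.15},
        "left_cheek": {"HVLA": 0.15, "LVLA": 0.15, "LVHA": 0.15},
        "right_cheek": {"HVLA": 0.15, "LVLA": 0.15, "LVHA": 0.15},
    }
    mrk = {
        "forehead": {"HVLA": 0.45, "LVLA": 0.45, "LVHA": 0.60},
        "nose": {"HVLA": -0.38, "LVLA": -0.42, "LVHA": -0.35},
        "mouth": {"HVLA": 0.15, "LVLA": 0.15, "LVHA": 0.15},
        "left_cheek": {"HVLA": 0.15, "LVLA": 0.15, "LVHA": 0.15},
        "right_cheek": {"HVLA": 0.32, "LVLA": 0.15, "LVHA": 0.15},
    }
    return {"moderate": mod, "marked": mrk}


@dataclass
class PhantomConfig:
    """Geometry, kinetics and nuisance parameters of the synthetic face."""

    shape: tuple[int, int] = (240, 320)  # rows, cols
    face_center: tuple[float, float] = (160.0, 115.0)  # (x, y)
    face_axes: tuple[float, float] = (80.0, 100.0)  # semi-axes (x, y), px
    eye_left: tuple[float, float] = (130.0, 100.0)
    eye_right: tuple[float, float] = (190.0, 100.0)
    # the left eye is drawn slightly larger: a mild, realistic asymmetry
    # that lets the fixed-image builder detect mirrored acquisitions
    eye_radius_left: float = 9.0
    eye_radius_right: float = 8.0
    eye_temp: float = 29.8
    ambient: float = 27.0
    face_base: float = 33.5
    roi_baselines: dict[str, float] = field(
        default_factory=lambda: {
            "forehead": 34.3,
            "nose": 33.0,
            "mouth": 33.8,
            "left_cheek": 33.6,
            "right_cheek": 33.6,
        }
    )
    amplitudes: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=_default_amplitudes
    )
    between_subject_sd: float = 0.08  # °C, per ROI x emotion amplitude
    tau_s: float = 5.0  # response time constant
    jitter_translation_sd: float = 2.0  # px
    jitter_rotation_sd: float = 1.0  # degrees
    jitter_scale_sd: float = 0.005  # fractional
    noise_sd: float = 0.05  # °C per pixel per frame
    physio_sd: float = 0.05  # °C, ROI-level vasomotor fluctuation (stationary sd)
    physio_rho: float = 0.9  # AR(1) lag-1 correlation of the fluctuation
    drift_per_min: float = 0.1  # °C / min, linear
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or min(
            self.jitter_translation_sd, self.jitter_rotation_sd, self.jitter_scale_sd
        ) < 0:
            raise PhantomError("noise and jitter scales must be non-negative")
        for g, per_roi in self.amplitudes.items():
            for roi, per_emo in per_roi.items():
                for emo, a in per_emo.items():
                    if not np.isfinite(a):
                        raise PhantomError(f"amplitude {g}/{roi}/{emo} not finite")

    # -- convenience constructors ----------------------------------------
    @classmethod
    def null(cls, **kw) -> "PhantomConfig":
        """Zero group-mean amplitudes everywhere (type-I calibration)."""
        amps = {
            g: {r: {e.value: 0.0 for e in IMAGE_EMOTIONS} for r in ROI_NAMES}
            for g in GROUPS
        }
        return cls(amplitudes=amps, **kw)

    @classmethod
    def single_effect(
        cls,
        roi: str = "forehead",
        emotion: str = "LVHA",
        moderate: float = 0.20,
        marked: float = 0.55,
        **kw,
    ) -> "PhantomConfig":
        """Group gap planted in exactly one ROI x emotion cell, zero elsewhere."""
        amps = {
            g: {r: {e.value: 0.0 for e in IMAGE_EMOTIONS} for r in ROI_NAMES}
            for g in GROUPS
        }
        amps["moderate"][roi][emotion] = moderate
        amps["marked"][roi][emotion] = marked
        return cls(amplitudes=amps, **kw)

    def scaled(self, factor: float) -> "PhantomConfig":
        """Geometrically scaled copy (all pixel quantities x factor)."""
        return replace(
            self,
            shape=(int(round(self.shape[0] * factor)), int(round(self.shape[1] * factor))),
            face_center=tuple(v * factor for v in self.face_center),
            face_axes=tuple(v * factor for v in self.face_axes),
            eye_left=tuple(v * factor for v in self.eye_left),
            eye_right=tuple(v * factor for v in self.eye_right),
            eye_radius_left=self.eye_radius_left * factor,
            eye_radius_right=self.eye_radius_right * factor,
            jitter_translation_sd=self.jitter_translation_sd * factor,
        )

    def roi_set(self) -> RoiSet:
        """The ROI rectangles anchored at the true (planted) eye centers."""
        rois = roi_layout(self.eye_left, self.eye_right)
        rois.validate_bounds(self.shape)
        return rois


@dataclass
class GroundTruth:
    """What the generator actually used for one subject."""

    group: str
    transforms: list[AffineParams]
    amplitudes: dict[tuple[str, str], float]  # (roi, emotion) -> °C
    config: PhantomConfig | None = None


# --------------------------------------------------------------------------
# Template and trajectories


def face_template(config: PhantomConfig) -> np.ndarray:
    """Static face image: ambient background, face ellipse, ROI plateaus, eyes."""
    rows, cols = config.shape
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    cx, cy = config.face_center
    ax, ay = config.face_axes
    img = np.full((rows, cols), config.ambient, dtype=float)
    face = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    img[face] = config.face_base
    rois = config.roi_set()
    for name, (x0, y0, x1, y1) in rois.rects.items():
        img[y0:y1, x0:x1] = config.roi_baselines[name]
    for (ex, ey), r in (
        (config.eye_left, config.eye_radius_left),
        (config.eye_right, config.eye_radius_right),
    ):
        disk = (x - ex) ** 2 + (y - ey) ** 2 <= r**2
        img[disk] = config.eye_temp
    return img


def draw_subject_amplitudes(
    config: PhantomConfig, group: str, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    """Per-subject amplitudes: group mean + N(0, between_subject_sd)."""
    if group not in GROUPS:
        raise PhantomError(f"unknown group {group!r}; expected one of {GROUPS}")
    out = {}
    for roi in ROI_NAMES:
        for emo in IMAGE_EMOTIONS:
            mean = config.amplitudes[group][roi][emo.value]
            out[(roi, emo.value)] = mean + rng.normal(0.0, config.between_subject_sd)
    return out


def roi_trajectories(
    config: PhantomConfig,
    schedule: StimulusSchedule,
    amplitudes: dict[tuple[str, str], float],
) -> dict[str, np.ndarray]:
    """Noise-free, drift-free ROI temperature at every frame time.

    First-order kinetics ``dT/dt = (target - T)/tau`` with a piecewise-
    constant target: ``baseline + amplitude`` during a segment of the ROI's
    matching emotion, ``baseline`` otherwise.  The piecewise solution is
    evaluated exactly (in closed form) at each frame time, so these values
    serve as an analytic oracle for feature extraction.
    """
    n = total_frames(schedule)
    fps = schedule.fps
    tau = config.tau_s
    out = {}
    for roi in ROI_NAMES:
        base = config.roi_baselines[roi]
        vals = np.empty(n)
        state = 0.0  # response relative to baseline at current event start
        k = 0  # next frame index to fill
        for ev in schedule.events:
            target = (
                amplitudes.get((roi, ev.emotion.value), 0.0)
                if ev.emotion is not EmotionType.REST
                else 0.0
            )
            while k < n and k / fps < ev.end_s - 1e-9:
                t_rel = k / fps - ev.start_s
                if t_rel >= -1e-9:
                    vals[k] = base + target + (state - target) * np.exp(-t_rel / tau)
                    k += 1
                else:  # frame precedes this event (should not happen)
                    k += 1
            dur = ev.duration_s
            state = target + (state - target) * np.exp(-dur / tau)
        while k < n:  # frames beyond last event boundary (rounding guard)
            vals[k] = base + state
            k += 1
        out[roi] = vals
    return out


def _drift(config: PhantomConfig, n: int, fps: float) -> np.ndarray:
    t_min = np.arange(n) / fps / 60.0
    return config.drift_per_min * t_min


def _physio_fluctuations(
    config: PhantomConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Slow within-subject vasomotor fluctuation per ROI: stationary AR(1).

    Real facial skin temperature wanders by a few hundredths of a °C on a
    seconds timescale independently of the stimulus; without this term the
    only within-subject variation would be (tiny) averaged sensor noise and
    every scaled copy of a subject's response would be equally detectable.
    """
    out = {}
    for roi in ROI_NAMES:
        x = np.empty(n)
        if config.physio_sd <= 0 or n == 0:
            out[roi] = np.zeros(n)
            continue
        rho = config.physio_rho
        x[0] = rng.normal(0.0, config.physio_sd)
        innov_sd = config.physio_sd * np.sqrt(max(0.0, 1.0 - rho**2))
        eps = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
        for k in range(1, n):
            x[k] = rho * x[k - 1] + eps[k - 1]
        out[roi] = x
    return out


def _draw_jitter(config: PhantomConfig, rng: np.random.Generator) -> AffineParams:
    return AffineParams(
        tx=rng.normal(0.0, config.jitter_translation_sd),
        ty=rng.normal(0.0, config.jitter_translation_sd),
        theta=rng.normal(0.0, config.jitter_rotation_sd),
        sx=max(1e-3, 1.0 + rng.normal(0.0, config.jitter_scale_sd)),
        sy=max(1e-3, 1.0 + rng.normal(0.0, config.jitter_scale_sd)),
        shear=0.0,
    )


def generate_subject(
    config: PhantomConfig,
    schedule: StimulusSchedule,
    group: str,
    seed: int | None = None,
) -> tuple[ThermalSequence, GroundTruth]:
    """Rasterise one subject's full thermal sequence.

    Deterministic given ``seed``.  Each frame is the static template with the
    current ROI response added, warped by that frame's jitter transform
    (background fill = ambient), plus linear drift and i.i.d. Gaussian
    sensor noise.
    """
    from .registration import apply_affine  # local import: avoid cycle

    if group not in GROUPS:
        raise PhantomError(f"unknown group {group!r}; expected one of {GROUPS}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    amps = draw_subject_amplitudes(config, group, rng)
    traj = roi_trajectories(config, schedule, amps)
    template = face_template(config)
    rois = config.roi_set()
    n = total_frames(schedule)
    drift = _drift(config, n, schedule.fps)
    physio = _physio_fluctuations(config, n, rng)
    frames = np.empty((n,) + config.shape, dtype=float)
    transforms: list[AffineParams] = []
    for k in range(n):
        frame = template.copy()
        for name, (x0, y0, x1, y1) in rois.rects.items():
            frame[y0:y1, x0:x1] += (
                traj[name][k] + physio[name][k] - config.roi_baselines[name]
            )
        params = _draw_jitter(config, rng)
        if not params.is_identity:
            frame = apply_affine(frame, params, fill=config.ambient)
        frame += drift[k]
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, size=frame.shape)
        frames[k] = frame
        transforms.append(params)
    seq = ThermalSequence(frames=frames, fps=schedule.fps, subject_id=f"{group}-{seed}")
    return seq, GroundTruth(group=group, transforms=transforms, amplitudes=amps, config=config)


def generate_subject_series(
    config: PhantomConfig,
    schedule: StimulusSchedule,
    group: str,
    seed: int | None = None,
    subject_id: str = "",
) -> tuple[SubjectSeries, GroundTruth]:
    """ROI-mean series for one subject without rasterising frames.

    Statistically matches :func:`generate_subject` followed by perfect
    registration and ROI averaging: the trajectory and drift terms are
    identical and the per-frame ROI-mean sensor noise has standard deviation
    ``noise_sd / sqrt(n_pixels_in_roi)``.
    """
    if group not in GROUPS:
        raise PhantomError(f"unknown group {group!r}; expected one of {GROUPS}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    amps = draw_subject_amplitudes(config, group, rng)
    traj = roi_trajectories(config, schedule, amps)
    n = total_frames(schedule)
    drift = _drift(config, n, schedule.fps)
    physio = _physio_fluctuations(config, n, rng)
    npix = config.roi_set().pixel_counts()
    series = {}
    for roi in ROI_NAMES:
        sd = config.noise_sd / np.sqrt(npix[roi])
        series[roi] = traj[roi] + physio[roi] + drift + rng.normal(0.0, sd, size=n)
    subj = SubjectSeries(
        subject_id=subject_id or f"{group}-{seed}",
        group=group,
        series=series,
        fps=schedule.fps,
    )
    return subj, GroundTruth(group=group, transforms=[], amplitudes=amps, config=config)


def _subject_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def _cohort_plan(n_moderate: int, n_marked: int) -> list[tuple[str, str]]:
    if n_moderate < 1 or n_marked < 1:
        raise PhantomError("each group needs at least one subject")
    plan = [("moderate", f"mod{i + 1:02d}") for i in range(n_moderate)]
    plan += [("marked", f"mrk{i + 1:02d}") for i in range(n_marked)]
    return plan


def generate_cohort(
    config: PhantomConfig,
    schedule: StimulusSchedule,
    n_moderate: int = 18,
    n_marked: int = 17,
    seed: int = 0,
) -> list[tuple[ThermalSequence, GroundTruth]]:
    """Full-frame cohort (default sizes 18 moderately / 17 markedly ill)."""
    plan = _cohort_plan(n_moderate, n_marked)
    seeds = _subject_seeds(seed, len(plan))
    out = []
    for (group, sid), s in zip(plan, seeds):
        seq, truth = generate_subject(config, schedule, group, int(s))
        seq.subject_id = sid
        out.append((seq, truth))
    return out


def generate_cohort_series(
    config: PhantomConfig,
    schedule: StimulusSchedule,
    n_moderate: int = 18,
    n_marked: int = 17,
    seed: int = 0,
) -> tuple[list[SubjectSeries], list[GroundTruth]]:
    """ROI-series cohort for fast statistical simulation."""
    plan = _cohort_plan(n_moderate, n_marked)
    seeds = _subject_seeds(seed, len(plan))
    subjects, truths = [], []
    for (group, sid), s in zip(plan, seeds):
        subj, truth = generate_subject_series(config, schedule, group, int(s), sid)
        subjects.append(subj)
        truths.append(truth)
    return subjects, truths
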