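"""Core data containers shared by every pipeline stage.

Temperatures are degrees Celsius throughout; images are ``(rows, cols)``
float arrays with row = y, col = x, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default frame geometry (rows, cols) of the thermal camera.
FRAME_SHAPE = (240, 320)

#: Default acquisition rate, frames per second.
DEFAULT_FPS = 2.0


class ThermofaceError(Exception):
    """Base error for this package."""


@dataclass(frozen=True)
class AffineParams:
    """Six-parameter planar affine transform, applied about the image center.

    The forward map of a point ``p`` (x, y) is ``M @ (p - c) + c + t`` where
    ``c`` is the image center, ``t = (tx, ty)`` and
    ``M = R(theta) @ diag(sx, sy) @ [[1, shear], [0, 1]]``.

    Parameters
    ----------
    tx, ty : float
        Translation in pixels.
    theta : float
        Rotation in degrees, counter-clockwise in (x, y) coordinates.
    sx, sy : float
        Scale factors (> 0).
    shear : float
        Shear coefficient (unitless).
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    shear: float = 0.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.tx == 0.0
            and self.ty == 0.0
            and self.theta == 0.0
            and self.sx == 1.0
            and self.sy == 1.0
            and self.shear == 0.0
        )

    def linear_matrix(self) -> np.ndarray:
        """The 2x2 linear part ``M`` in (x, y) coordinates."""
        a = np.deg2rad(self.theta)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        scale = np.diag([self.sx, self.sy])
        sh = np.array([[1.0, self.shear], [0.0, 1.0]])
        return rot @ scale @ sh

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.tx, self.ty, self.theta, self.sx, self.sy, self.shear)

    @staticmethod
    def identity() -> "AffineParams":
        return AffineParams()


def compose_displacement(
    a: AffineParams, b: AffineParams, shape: tuple[int, int]
) -> tuple[float, float]:
    """Residual of the composition ``a ∘ b`` relative to the identity.

    Returns ``(translation_px, rotation_deg)``: the displacement of the image
    center under ``a`` applied after ``b`` and the net rotation angle of the
    combined linear part.  Both are 0 when ``a`` inverts ``b`` exactly, which
    makes this the natural error metric for planted-transform recovery.
    """
    c = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
    ma, mb = a.linear_matrix(), b.linear_matrix()
    ta = np.array([a.tx, a.ty])
    tb = np.array([b.tx, b.ty])
    # p -> mb(p - c) + c + tb -> ma(that - c) + c + ta
    m = ma @ mb
    t = ma @ tb + ta
    center_out = m @ (c - c) + c + t
    trans_err = float(np.hypot(*(center_out - c)))
    rot_err = float(abs(np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))))
    return trans_err, rot_err


@dataclass
class ThermalSequence:
    """An ordered stack of thermal frames for one subject.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Per-pixel skin/ambient temperature in degrees Celsius.
    fps : float
        Acquisition rate.
    subject_id : str
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (n, rows, cols) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class FeatureMatrix:
    """Subjects x features block for one ROI x emotion cell.

    ``values`` is ``(n_subjects, p)`` in °C (temperature changes), ``labels``
    a same-length sequence of group labels, conventionally ``"moderate"`` and
    ``"marked"``.
    """

    values: np.ndarray
    labels: np.ndarray
    roi: str = ""
    emotion: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
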