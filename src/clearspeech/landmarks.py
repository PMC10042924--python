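"""Facial landmark data model, similarity normalization, and visual speech cues.

Frames follow the 68-point iBUG annotation convention with **1-based**
indexing in all documentation and public helpers (``landmark(34)`` is the
nose tip).  Two coordinate spaces are used:

``pixel``
    Image coordinates, y increasing downward.
``normalized``
    Face-centric coordinates: nose tip at the origin, the line joining the
    nose tip and the mid-point between the two eyes pointing along +y with
    unit length.  All cue measurements are taken in this space, which makes
    them invariant to head translation, rotation and camera distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PIXEL",
    "NORMALIZED",
    "N_LANDMARKS",
    "NOSE_TIP",
    "CHIN",
    "LEFT_EYE",
    "RIGHT_EYE",
    "LIP_SLICE",
    "OUTER_LIP_SLICE",
    "INNER_LIP_SLICE",
    "LandmarkFrame",
    "NormalizationParams",
    "VisualCues",
    "InvalidGeometryError",
    "normalize_frame",
    "denormalize_frame",
    "compute_visual_cues",
]

logger = logging.getLogger(__name__)

PIXEL = "pixel"
NORMALIZED = "normalized"

N_LANDMARKS = 68

# 1-based landmark indices (iBUG convention).
NOSE_TIP = 34
CHIN = 9
LEFT_EYE = tuple(range(37, 43))
RIGHT_EYE = tuple(range(43, 49))
# Mouth landmarks, 1-based 49..68: outer ring 49..60, inner ring 61..68.
LIP_SLICE = slice(48, 68)
OUTER_LIP_SLICE = slice(48, 60)
INNER_LIP_SLICE = slice(60, 68)

# Cue landmarks (1-based).
_UPPER_LIP_MID = 52
_LOWER_LIP_MID = 58
_LEFT_MOUTH_CORNER = 49
_RIGHT_MOUTH_CORNER = 55


class InvalidGeometryError(ValueError):
    """Raised for degenerate face geometry or invalid transform parameters."""


@dataclass
class LandmarkFrame:
    """One video frame's 68 ordered 2-D landmark positions.

    Parameters
    ----------
    points
        Array of shape (68, 2).  Row ``k`` holds landmark ``k + 1`` in the
        1-based convention.
    space
        Either ``"pixel"`` or ``"normalized"``.
    """

    points: np.ndarray
    space: str = PIXEL

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected (68, 2) points, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if self.space not in (PIXEL, NORMALIZED):
            raise ValueError(f"unknown space {self.space!r}")
        self.points = pts

    def landmark(self, k: int) -> np.ndarray:
        """Return landmark ``k`` (1-based, 1..68)."""
        if not 1 <= k <= N_LANDMARKS:
            raise IndexError(f"landmark index {k} out of range 1..68")
        return self.points[k - 1]

    def copy(self) -> "LandmarkFrame":
        return LandmarkFrame(self.points.copy(), self.space)

    @property
    def nose_tip(self) -> np.ndarray:
        return self.landmark(NOSE_TIP)

    @property
    def eye_midpoint(self) -> np.ndarray:
        """Midpoint of the two eye centroids (mean of 6 landmarks each)."""
        left = self.points[[k - 1 for k in LEFT_EYE]].mean(axis=0)
        right = self.points[[k - 1 for k in RIGHT_EYE]].mean(axis=0)
        return 0.5 * (left + right)


@dataclass(frozen=True)
class NormalizationParams:
    """Similarity transform removed by :func:`normalize_frame`.

    ``denormalize_frame`` maps a normalized point q back to pixel space via
    ``p = scale * R(-rotation) @ q + translation``.
    """

    translation: np.ndarray
    rotation: float
    scale: float

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(2)
        object.__setattr__(self, "translation", t)
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise InvalidGeometryError(f"scale must be positive, got {self.scale}")

    @staticmethod
    def identity() -> "NormalizationParams":
        return NormalizationParams(np.zeros(2), 0.0, 1.0)


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def normalize_frame(frame: LandmarkFrame) -> tuple[LandmarkFrame, NormalizationParams]:
    """Similarity-normalize a landmark frame.

    Centers the landmarks on the nose tip, rotates so the line L from the
    nose tip to the eye midpoint points along +y, and scales so |L| = 1.

    Returns the normalized frame and the parameters that invert the
    transform.  Raises :class:`InvalidGeometryError` when the eye midpoint
    coincides with the nose tip.
    """
    nose = frame.nose_tip.copy()
    d = frame.eye_midpoint - nose
    s = float(np.hypot(*d))
    if s < 1e-9:
        raise InvalidGeometryError("eye midpoint coincides with the nose tip")
    # Rotation taking d/s onto (0, 1).
    theta = math.pi / 2.0 - math.atan2(d[1], d[0])
    rot = _rotation_matrix(theta)
    q = (frame.points - nose) @ rot.T / s
    params = NormalizationParams(nose, theta, s)
    return LandmarkFrame(q, NORMALIZED), params


def denormalize_frame(frame: LandmarkFrame, params: NormalizationParams) -> LandmarkFrame:
    """Invert :func:`normalize_frame`: map a normalized frame to pixel space."""
    if not params.scale > 0:
        raise InvalidGeometryError("non-positive scale in normalization params")
    rot_inv = _rotation_matrix(-params.rotation)
    p = frame.points @ rot_inv.T * params.scale + params.translation
    return LandmarkFrame(p, PIXEL)


@dataclass(frozen=True)
class VisualCues:
    """The five visual speech measures plus the ellipse axes.

    All lengths are in normalized face units (the nose-to-eye line has
    length 1).  ``area`` is the lip-ellipse area (pi/4 * V * H).
    ``eccentricity`` is sqrt(1 - b/a): 0 when the lips are fully rounded
    (V = H), 1 when the lips are closed (V = 0).
    """

    v_stretch: float
    h_stretch: float
    jaw_lowering: float
    eccentricity: float
    area: float
    minor_axis: float = field(init=False)
    major_axis: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("v_stretch", "h_stretch", "jaw_lowering", "area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.eccentricity <= 1.0:
            raise ValueError("eccentricity must lie in [0, 1]")
        object.__setattr__(self, "minor_axis", min(self.v_stretch, self.h_stretch))
        object.__setattr__(self, "major_axis", max(self.v_stretch, self.h_stretch))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.v_stretch, self.h_stretch, self.jaw_lowering, self.eccentricity, self.area]
        )


CUE_NAMES = ("v_stretch", "h_stretch", "jaw_lowering", "eccentricity", "area")


def compute_visual_cues(frame: LandmarkFrame) -> VisualCues:
    """Measure the five visual cues on a normalized landmark frame.

    V_stretch = |l52 - l58|, H_stretch = |l55 - l49|,
    Jaw_lowering = |l9 - l34|, e = sqrt(1 - b/a), Area = pi/4 * V * H,
    with Euclidean distances.  When both stretches are zero the
    eccentricity is defined as 1 (closed-lips limit).
    """
    if frame.space != NORMALIZED:
        raise ValueError("visual cues are defined on normalized frames")
    pts = frame.points
    v = float(np.linalg.norm(pts[_UPPER_LIP_MID - 1] - pts[_LOWER_LIP_MID - 1]))
    h = float(np.linalg.norm(pts[_RIGHT_MOUTH_CORNER - 1] - pts[_LEFT_MOUTH_CORNER - 1]))
    jaw = float(np.linalg.norm(pts[CHIN - 1] - pts[NOSE_TIP - 1]))
    b, a = min(v, h), max(v, h)
    if a <= 0.0:
        logger.info("both lip stretches are zero; eccentricity set to 1 by convention")
        e = 1.0
    else:
        e = math.sqrt(max(0.0, 1.0 - b / a))
    area = 0.25 * math.pi * v * h
    return VisualCues(v, h, jaw, e, area)
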