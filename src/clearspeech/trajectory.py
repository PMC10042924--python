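"""Landmark trajectories, degree-3 polynomial curve fitting and resampling.

A word clip is modelled as 136 polynomial curves (68 landmarks x {x, y})
over normalized time t in [0, 1].  Fitting and equidistant resampling serve
three purposes: temporal smoothing of detector jitter, aligning plain and
clear clips of different duration frame-by-frame, and realizing the
displacement-factor duration scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import polynomial as npoly

from .landmarks import N_LANDMARKS, LandmarkFrame

__all__ = [
    "LandmarkTrajectory",
    "CurveSet",
    "InsufficientFramesError",
    "fit_curves",
    "sample_curves",
    "temporal_smooth",
    "output_frame_count",
    "round_half_away",
]

PLAIN = "plain"
CLEAR = "clear"
MODIFIED = "modified"

MAX_DEGREE = 3


class InsufficientFramesError(ValueError):
    """Raised when a trajectory has too few frames to fit curves."""


@dataclass
class LandmarkTrajectory:
    """A word clip's landmark frame sequence plus its annotations.

    ``vowel_span`` holds 0-based (start, mid, end) frame indices of the
    vowel portion; the mid frame anchors the ratio transfer and the warp.
    """

    frames: list[LandmarkFrame]
    fps: float = 29.0
    talker_id: str = ""
    word: str = ""
    style: str = PLAIN
    vowel_span: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise InsufficientFramesError("a trajectory needs at least 2 frames")
        spaces = {f.space for f in self.frames}
        if len(spaces) != 1:
            raise ValueError("all frames must share one coordinate space")
        if self.vowel_span is not None:
            start, mid, end = (int(i) for i in self.vowel_span)
            n = len(self.frames)
            if not (0 <= start <= mid <= end < n):
                raise ValueError(f"invalid vowel_span {self.vowel_span} for {n} frames")
            self.vowel_span = (start, mid, end)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def space(self) -> str:
        return self.frames[0].space

    def points(self) -> np.ndarray:
        """Stack all frames into an (n_frames, 68, 2) array."""
        return np.stack([f.points for f in self.frames])

    @property
    def mid_vowel_index(self) -> int:
        if self.vowel_span is not None:
            return self.vowel_span[1]
        return (self.n_frames - 1) // 2

    @property
    def mid_vowel_frame(self) -> LandmarkFrame:
        return self.frames[self.mid_vowel_index]

    def with_frames(self, frames: list[LandmarkFrame], **changes) -> "LandmarkTrajectory":
        """Copy of this trajectory with new frames (vowel span rescaled)."""
        span = self.vowel_span
        if span is not None and len(frames) != self.n_frames:
            ratio = (len(frames) - 1) / max(1, self.n_frames - 1)
            span = tuple(min(len(frames) - 1, int(round(i * ratio))) for i in span)
        return replace(self, frames=frames, vowel_span=span, **changes)


@dataclass
class CurveSet:
    """136 polynomial coefficient vectors over normalized time t in [0, 1].

    ``coefficients`` has shape (degree + 1, 136); column order is landmark-
    major, coordinate-minor (x then y), i.e. ``points.reshape(n, 136)``.
    """

    coefficients: np.ndarray
    n_source: int
    space: str

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 * N_LANDMARKS:
            raise ValueError(f"expected (deg+1, 136) coefficients, got {c.shape}")
        if c.shape[0] > MAX_DEGREE + 1:
            raise ValueError("polynomial degree exceeds 3")
        self.coefficients = c

    @property
    def degree(self) -> int:
        return self.coefficients.shape[0] - 1

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all curves at times ``t`` -> (len(t), 68, 2)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        vals = npoly.polyval(t, self.coefficients)  # (136, len(t))
        return vals.T.reshape(len(t), N_LANDMARKS, 2)


def fit_curves(traj: LandmarkTrajectory) -> CurveSet:
    """Least-squares fit one degree-3 polynomial per landmark coordinate.

    The degree is reduced to ``n_frames - 1`` for very short clips so the
    system stays determined.
    """
    n = traj.n_frames
    if n < 2:
        raise InsufficientFramesError("need at least 2 frames to fit curves")
    deg = min(MAX_DEGREE, n - 1)
    t = np.linspace(0.0, 1.0, n)
    y = traj.points().reshape(n, 2 * N_LANDMARKS)
    coeffs = npoly.polyfit(t, y, deg)
    return CurveSet(coeffs, n, traj.space)


def sample_curves(curves: CurveSet, n_points: int) -> list[LandmarkFrame]:
    """Sample the curve set at ``n_points`` equidistant times in [0, 1]."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = np.linspace(0.0, 1.0, n_points)
    pts = curves.evaluate(t)
    return [LandmarkFrame(p, curves.space) for p in pts]


def temporal_smooth(traj: LandmarkTrajectory) -> LandmarkTrajectory:
    """Replace each coordinate by its fitted-curve value at the same times.

    Equivalent to ``sample_curves(fit_curves(traj), traj.n_frames)``; a
    projection, so applying it twice equals applying it once.
    """
    frames = sample_curves(fit_curves(traj), traj.n_frames)
    return traj.with_frames(frames)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def output_frame_count(n_plain: int, n_clear: int, df: float) -> int:
    """Frame count of a modified clip under displacement factor ``df``.

    The plain/clear duration difference is scaled by ``df`` and added to the
    plain frame count: e.g. plain 9, clear 12, df 2 -> 3 * 2 + 9 = 15.
    """
    if n_plain < 2 or n_clear < 2:
        raise ValueError("frame counts must be >= 2")
    if not df > 0:
        raise ValueError("displacement factor must be positive")
    return max(2, n_plain + round_half_away(df * (n_clear - n_plain)))
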