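"""The landmark manipulator: plain-to-clear change fields and their application.

From a normalized plain/clear trajectory pair of the same word, the change
field stores, per landmark coordinate and as degree-3 curves over normalized
time t in [0, 1]:

* the plain animation ratio  alpha_t = plain_t / p_mid, and
* the relative change        c_t = (clear_t - plain_t) / p_mid,

both anchored at the training plain **mid-vowel** coordinate p_mid.  The
plain clip is first resampled to the clear clip's frame count so the
displacements are one-to-one.  Applying the field to a novel talker's
plain clip animates that talker's mid-vowel landmark frame m_in:

    dest_t = m_in * (alpha_t + df * c_t)

so df = 0 reproduces the plain-style animation, df = 1 the clear-style one,
and df = 2 doubles the displacement (a stored 25% change becomes an applied
50% change).  Coordinates whose anchor is nearly zero (|p_mid| < 1e-3, e.g.
near the nose-tip origin) use an additive channel instead to avoid ratio
blow-up.  The duration difference (delta_frames) is scaled by the same df.

Change fields may be averaged with equal weight across many talkers' pairs
("average" target) to capture talker-universal clear-speech features, or
used directly from a single pair ("same-talker" target).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import convolve1d

from .landmarks import (
    INNER_LIP_SLICE,
    N_LANDMARKS,
    NORMALIZED,
    NOSE_TIP,
    OUTER_LIP_SLICE,
    LandmarkFrame,
)
from .trajectory import (
    LandmarkTrajectory,
    fit_curves,
    round_half_away,
    sample_curves,
)

__all__ = [
    "SAME_TALKER",
    "AVERAGE",
    "ANCHOR_EPS",
    "ChangeField",
    "ModificationConfig",
    "FoldWarning",
    "compute_change_field",
    "average_change_fields",
    "make_destination_frames",
    "spatial_smooth_folds",
    "has_fold",
]

SAME_TALKER = "same_talker"
AVERAGE = "average"

#: anchors below this magnitude (normalized units) use the additive channel
ANCHOR_EPS = 1e-3

_N_COORDS = 2 * N_LANDMARKS
_N_COEF = 4  # degree 3


class FoldWarning(UserWarning):
    """Emitted when fold correction cannot fully resolve a fold."""


@dataclass
class ChangeField:
    """Plain-to-clear change field for one word (see module docstring).

    All four coefficient blocks have shape (4, 136) (degree-3 curves over
    t in [0, 1], column order = ``points.reshape(-1, 136)``).  ``fallback``
    marks coordinates served by the additive channels.
    """

    word: str
    target_mode: str
    n_pairs: int
    delta_frames: float
    ratio_anim: np.ndarray
    relative_change: np.ndarray
    additive_anim: np.ndarray
    additive_change: np.ndarray
    fallback: np.ndarray
    reference_mid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ratio_anim", "relative_change", "additive_anim", "additive_change"):
            block = np.asarray(getattr(self, name), dtype=float)
            if block.shape != (_N_COEF, _N_COORDS):
                raise ValueError(f"{name} must have shape (4, 136), got {block.shape}")
            if not np.all(np.isfinite(block)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, block)
        self.fallback = np.asarray(self.fallback, dtype=bool).reshape(_N_COORDS)
        self.reference_mid = np.asarray(self.reference_mid, dtype=float).reshape(_N_COORDS)
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.target_mode == SAME_TALKER and self.n_pairs != 1:
            raise ValueError("same-talker fields come from exactly one pair")
        if not np.isfinite(self.delta_frames):
            raise ValueError("delta_frames must be finite")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "word": self.word,
            "target_mode": self.target_mode,
            "n_pairs": self.n_pairs,
            "delta_frames": self.delta_frames,
            "ratio_anim": self.ratio_anim.tolist(),
            "relative_change": self.relative_change.tolist(),
            "additive_anim": self.additive_anim.tolist(),
            "additive_change": self.additive_change.tolist(),
            "fallback": self.fallback.astype(int).tolist(),
            "reference_mid": self.reference_mid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChangeField":
        return cls(
            word=d["word"],
            target_mode=d["target_mode"],
            n_pairs=int(d["n_pairs"]),
            delta_frames=float(d["delta_frames"]),
            ratio_anim=np.asarray(d["ratio_anim"], dtype=float),
            relative_change=np.asarray(d["relative_change"], dtype=float),
            additive_anim=np.asarray(d["additive_anim"], dtype=float),
            additive_change=np.asarray(d["additive_change"], dtype=float),
            fallback=np.asarray(d["fallback"], dtype=bool),
            reference_mid=np.asarray(d["reference_mid"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ChangeField":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ModificationConfig:
    """How a field is applied: target mode, displacement factor, fold smoothing."""

    target_mode: str = SAME_TALKER
    df: float = 1.0
    fold_sigma: float = 1.0
    fold_kernel_width: int = 5
    fold_max_iter: int = 10

    def __post_init__(self) -> None:
        if not self.df > 0:
            raise ValueError("displacement factor must be positive")


def _pad_coeffs(c: np.ndarray) -> np.ndarray:
    out = np.zeros((_N_COEF, _N_COORDS))
    out[: c.shape[0]] = c
    return out


def _fit_channel(t: np.ndarray, values: np.ndarray) -> np.ndarray:
    deg = min(3, len(t) - 1)
    return _pad_coeffs(npoly.polyfit(t, values, deg))


def compute_change_field(
    plain: LandmarkTrajectory, clear: LandmarkTrajectory
) -> ChangeField:
    """Quantify how landmarks change from a plain to a clear production.

    Both trajectories must be normalized and share the same word.  The plain
    clip is resampled (via its fitted curves) to the clear clip's frame
    count; per aligned frame the relative change is anchored at the plain
    mid-vowel coordinates.
    """
    if plain.word != clear.word:
        raise ValueError(f"word mismatch: {plain.word!r} vs {clear.word!r}")
    if plain.space != NORMALIZED or clear.space != NORMALIZED:
        raise ValueError("change fields are computed on normalized trajectories")
    if plain.vowel_span is None:
        raise ValueError("plain trajectory needs a vowel_span annotation")

    n_clear = clear.n_frames
    plain_rs = sample_curves(fit_curves(plain), n_clear)
    p = np.stack([f.points for f in plain_rs]).reshape(n_clear, _N_COORDS)
    c = clear.points().reshape(n_clear, _N_COORDS)
    p_mid = plain.mid_vowel_frame.points.reshape(_N_COORDS)

    fallback = np.abs(p_mid) < ANCHOR_EPS
    safe_mid = np.where(fallback, 1.0, p_mid)

    t = np.linspace(0.0, 1.0, n_clear)
    ratio_anim = _fit_channel(t, p / safe_mid)
    relative_change = _fit_channel(t, (c - p) / safe_mid)
    additive_anim = _fit_channel(t, p - p_mid)
    additive_change = _fit_channel(t, c - p)
    # ratio channels are meaningless on fallback coordinates
    ratio_anim[:, fallback] = 0.0
    relative_change[:, fallback] = 0.0

    return ChangeField(
        word=plain.word,
        target_mode=SAME_TALKER,
        n_pairs=1,
        delta_frames=float(n_clear - plain.n_frames),
        ratio_anim=ratio_anim,
        relative_change=relative_change,
        additive_anim=additive_anim,
        additive_change=additive_change,
        fallback=fallback,
        reference_mid=p_mid,
    )


def average_change_fields(fields: list[ChangeField]) -> ChangeField:
    """Equal-weight pointwise mean of change fields for one word.

    Averaging the polynomial coefficients over the shared normalized-time
    axis equals averaging the curves pointwise.  A coordinate falls back to
    the additive channel if it does so in any contributing field.
    """
    if not fields:
        raise ValueError("cannot average an empty list of change fields")
    words = {f.word for f in fields}
    if len(words) != 1:
        raise ValueError(f"cannot average fields of different words: {sorted(words)}")

    fallback = np.any([f.fallback for f in fields], axis=0)
    avg = {
        name: np.mean([getattr(f, name) for f in fields], axis=0)
        for name in ("ratio_anim", "relative_change", "additive_anim", "additive_change")
    }
    avg["ratio_anim"][:, fallback] = 0.0
    avg["relative_change"][:, fallback] = 0.0
    return ChangeField(
        word=fields[0].word,
        target_mode=AVERAGE,
        n_pairs=sum(f.n_pairs for f in fields),
        delta_frames=float(np.mean([f.delta_frames for f in fields])),
        fallback=fallback,
        reference_mid=np.mean([f.reference_mid for f in fields], axis=0),
        **avg,
    )


def make_destination_frames(
    input_plain: LandmarkTrajectory,
    field: ChangeField,
    config: ModificationConfig | None = None,
    *,
    df: float | None = None,
) -> list[LandmarkFrame]:
    """Apply a change field to a novel plain clip's mid-vowel landmark frame.

    The output has ``n_in + round(df * delta_frames)`` frames; destination
    coordinates are ``m_in * (alpha_t + df * c_t)`` (additive channel on
    fallback coordinates), where m_in is the input mid-vowel coordinate.
    ``df = 0`` is the identity limit (plain-style animation, unchanged
    duration); negative df is an error.
    """
    if df is None:
        df = config.df if config is not None else 1.0
    if df < 0:
        raise ValueError("displacement factor must be non-negative")
    if field.word and input_plain.word and field.word != input_plain.word:
        raise ValueError(f"word mismatch: field {field.word!r} vs input {input_plain.word!r}")
    if input_plain.space != NORMALIZED:
        raise ValueError("input trajectory must be normalized")

    n_in = input_plain.n_frames
    n_out = max(2, n_in + round_half_away(df * field.delta_frames))
    t = np.linspace(0.0, 1.0, n_out)
    m_in = input_plain.mid_vowel_frame.points.reshape(_N_COORDS)

    alpha = npoly.polyval(t, field.ratio_anim)  # (136, n_out)
    c_rel = npoly.polyval(t, field.relative_change)
    dest = m_in[:, None] * (alpha + df * c_rel)

    fb = field.fallback
    if fb.any():
        add = npoly.polyval(t, field.additive_anim[:, fb]) + df * npoly.polyval(
            t, field.additive_change[:, fb]
        )
        dest[fb] = m_in[fb, None] + add

    return [LandmarkFrame(dest[:, i].reshape(N_LANDMARKS, 2), NORMALIZED) for i in range(n_out)]


# -- fold detection and spatial smoothing ------------------------------

# inner-lip vertical pairs, 1-based (upper, lower): l64/l66, l63/l67, l62/l68
_INNER_PAIRS = ((64, 66), (63, 67), (62, 68))


def has_fold(frame: LandmarkFrame, margin: float = 0.0) -> bool:
    """True if the frame shows a geometrically impossible lip configuration.

    Either (a) a lip landmark lies above the nose tip, or (b) an inner
    lower-lip landmark lies above its paired inner upper-lip landmark
    (y-up normalized space).
    """
    pts = frame.points
    nose_y = pts[NOSE_TIP - 1, 1]
    if np.any(pts[LIP_INDEX, 1] > nose_y + margin):
        return True
    for upper, lower in _INNER_PAIRS:
        if pts[lower - 1, 1] > pts[upper - 1, 1]:
            return True
    return False


LIP_INDEX = np.arange(OUTER_LIP_SLICE.start, INNER_LIP_SLICE.stop)


def _gaussian_kernel(sigma: float, width: int) -> np.ndarray:
    half = width // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def spatial_smooth_folds(
    frames: list[LandmarkFrame],
    *,
    sigma: float = 1.0,
    kernel_width: int = 5,
    max_iter: int = 10,
) -> list[LandmarkFrame]:
    """Correct landmark folds by Gaussian convolution over the lip rings.

    Fold-free frames are returned unchanged.  On folded frames a 1-D
    Gaussian (sigma in landmark-index units) is convolved circularly along
    the outer and inner lip rings, reducing the magnitude of the applied
    change, until the fold predicate is false or ``max_iter`` is reached
    (then a :class:`FoldWarning` is emitted and the best effort returned).
    """
    kernel = _gaussian_kernel(sigma, kernel_width)
    out: list[LandmarkFrame] = []
    for idx, frame in enumerate(frames):
        if not has_fold(frame):
            out.append(frame)
            continue
        pts = frame.points.copy()
        resolved = False
        for _ in range(max_iter):
            for ring in (OUTER_LIP_SLICE, INNER_LIP_SLICE):
                pts[ring] = convolve1d(pts[ring], kernel, axis=0, mode="wrap")
            if not has_fold(LandmarkFrame(pts, frame.space)):
                resolved = True
                break
        if not resolved:
            warnings.warn(
                f"fold in frame {idx} not fully resolved after {max_iter} iterations",
                FoldWarning,
                stacklevel=2,
            )
        out.append(LandmarkFrame(pts, frame.space))
    return out
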