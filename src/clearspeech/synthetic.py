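"""Parametric synthetic talkers: landmark trajectories and rendered faces.

Emulates the statistical structure of a /kVd/ word corpus — six words
("keyed", "kid", "cod", "cud", "cooed", "could") spanning three tense/lax
vowel pairs, many talkers, plain and clear styles — with exact ground-truth
landmarks, so every pipeline stage is testable without recordings or
landmark detectors.

A canonical symmetric 68-point face template in normalized space (nose tip
at origin, eye midpoint at (0, 1), y-up) is deformed by three articulatory
parameters: vertical lip stretch ``v`` (= |l52 - l58| by construction),
horizontal lip stretch ``h`` (= |l55 - l49|) and jaw lowering ``jaw``
(= |l9 - l34|), so cue values measured on synthetic frames equal the
injected targets.  A word clip follows a smooth cubic open-close profile
peaking exactly at the annotated mid-vowel frame (a cubic rather than a
raised cosine, so noiseless synthetic motion is exactly representable by
the degree-3 curves the pipeline fits).  Clear style multiplies
the vowel-peak cues by per-talker exaggeration gains (greater vertical
stretch and jaw lowering; horizontal stretch increases for front unrounded
vowels and tightens for rounded ones) and lengthens the clip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse, polygon

from .landmarks import N_LANDMARKS, NORMALIZED, LandmarkFrame, NormalizationParams, denormalize_frame
from .trajectory import CLEAR, PLAIN, LandmarkTrajectory
from . import io as cs_io

__all__ = [
    "WordSpec",
    "WORDS",
    "TENSE_WORDS",
    "LAX_WORDS",
    "SyntheticTalkerParams",
    "make_talker",
    "face_frame",
    "synth_trajectory",
    "render_face",
    "generate_corpus",
    "mean_template_frame",
]


@dataclass(frozen=True)
class WordSpec:
    """A /kVd/ word with its mid-vowel articulatory cue targets.

    Cue values are in normalized face units.  ``h_mode`` encodes how clear
    speech affects horizontal stretch: ``front`` (unrounded front vowels
    stretch wider), ``back`` (mild widening) or ``rounded`` (h tightens
    toward v, increasing lip rounding).
    """

    word: str
    tensity: str  # "tense" | "lax"
    v: float
    h: float
    jaw: float
    h_mode: str  # "front" | "back" | "rounded"

    @property
    def eccentricity(self) -> float:
        b, a = min(self.v, self.h), max(self.v, self.h)
        return float(np.sqrt(1.0 - b / a)) if a > 0 else 1.0


WORDS: dict[str, WordSpec] = {
    "keyed": WordSpec("keyed", "tense", v=0.34, h=1.00, jaw=1.68, h_mode="front"),
    "kid": WordSpec("kid", "lax", v=0.24, h=0.90, jaw=1.50, h_mode="front"),
    "cod": WordSpec("cod", "tense", v=0.60, h=0.86, jaw=1.88, h_mode="back"),
    "cud": WordSpec("cud", "lax", v=0.46, h=0.80, jaw=1.68, h_mode="back"),
    "cooed": WordSpec("cooed", "tense", v=0.42, h=0.50, jaw=1.64, h_mode="rounded"),
    "could": WordSpec("could", "lax", v=0.32, h=0.44, jaw=1.46, h_mode="rounded"),
}

TENSE_WORDS = tuple(w for w, s in WORDS.items() if s.tensity == "tense")
LAX_WORDS = tuple(w for w, s in WORDS.items() if s.tensity == "lax")

# rest (mouth nearly closed) articulatory pose shared by all words
REST_V = 0.06
REST_H = 0.50
REST_JAW = 1.40

JAW_REF = 1.5  # jaw value at which the mouth sits at its reference height


@dataclass
class SyntheticTalkerParams:
    """One synthetic talker: idiosyncrasy, clear-speech gains, clip design."""

    talker_id: str
    gender_tag: str = "F"
    face_scale: float = 55.0  # pixels per normalized unit when rendered
    v_gain: float = 1.25
    h_gain: float = 1.10
    jaw_gain: float = 1.10
    rounding_gain: float = 1.06
    n_plain_frames: int = 9
    n_clear_frames: int = 12
    jitter_sigma: float = 0.01
    seed: int = 0
    # per-cue multiplicative idiosyncrasy (v, h, jaw)
    cue_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for g in (self.v_gain, self.h_gain, self.jaw_gain, self.rounding_gain):
            if not g > 0:
                raise ValueError("gains must be positive")
        if min(self.n_plain_frames, self.n_clear_frames) < 4:
            raise ValueError("frame counts must be >= 4")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


def make_talker(index: int, seed: int = 0, *, idiosyncrasy_sd: float = 0.05,
                **overrides) -> SyntheticTalkerParams:
    """Deterministic talker ``index`` (0-based) with seeded idiosyncrasy.

    The first 10 talkers carry the F gender tag, the rest M, mirroring a
    10-female / 8-male panel at the default 18 talkers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, index]))
    cue_scale = tuple(np.clip(rng.normal(1.0, idiosyncrasy_sd, 3), 0.7, 1.3))
    gains = {
        "v_gain": float(max(1.01, rng.normal(1.25, idiosyncrasy_sd))),
        "h_gain": float(max(1.01, rng.normal(1.10, idiosyncrasy_sd))),
        "jaw_gain": float(max(1.01, rng.normal(1.10, idiosyncrasy_sd))),
    }
    gains.update(overrides)
    return SyntheticTalkerParams(
        talker_id=f"T{index + 1:02d}",
        gender_tag="F" if index < 10 else "M",
        seed=seed,
        cue_scale=cue_scale,
        **gains,
    )


# -- canonical face template -------------------------------------------

def _ring_trig(degrees) -> tuple[np.ndarray, np.ndarray]:
    """Cosine/sine of ring angles, exact at the cardinal angles.

    Snapping the ~1e-17 floating-point residue of cos(90 deg) etc. to zero
    makes the injected cue values exact (e.g. V_stretch is exactly 0 for a
    fully closed mouth, so the eccentricity limit e = 1 is hit exactly).
    """
    th = np.deg2rad(np.asarray(degrees, dtype=float))
    c, s = np.cos(th), np.sin(th)
    c[np.abs(c) < 1e-12] = 0.0
    s[np.abs(s) < 1e-12] = 0.0
    return c, s


def face_frame(v: float = REST_V, h: float = REST_H, jaw: float = REST_JAW) -> LandmarkFrame:
    """Canonical 68-point face posed by the three articulatory parameters.

    By construction the frame is already normalized (nose tip l34 at the
    origin, eye midpoint at (0, 1)) and V_stretch = v, H_stretch = h,
    Jaw_lowering = jaw exactly.
    """
    pts = np.zeros((N_LANDMARKS, 2))

    # jaw 1..17: lower-half ellipse from left ear through the chin (l9)
    phi = np.linspace(np.pi, 2.0 * np.pi, 17)
    pts[0:17, 0] = 1.45 * np.cos(phi)
    pts[0:17, 1] = 0.8 + (0.8 + jaw) * np.sin(phi)

    # eyebrows 18..22 and 23..27
    bx = np.linspace(-0.95, -0.25, 5)
    arc = 0.08 * np.array([0.0, 0.7, 1.0, 0.7, 0.0])
    pts[17:22] = np.column_stack([bx, 1.45 + arc])
    pts[22:27] = np.column_stack([-bx[::-1], 1.45 + arc[::-1]])

    # nose bridge 28..31 and lower nose 32..36 (l34 = tip = origin)
    pts[27:31] = [(0.0, 0.85), (0.0, 0.60), (0.0, 0.35), (0.0, 0.12)]
    pts[31:36] = [(-0.22, -0.04), (-0.11, -0.01), (0.0, 0.0), (0.11, -0.01), (0.22, -0.04)]

    # eyes 37..42 (left) and 43..48 (right): symmetric hexagons, centroid
    # midpoint exactly (0, 1)
    hexa = np.array(
        [(-0.18, 0.0), (-0.09, 0.06), (0.09, 0.06), (0.18, 0.0), (0.09, -0.06), (-0.09, -0.06)]
    )
    pts[36:42] = hexa + (-0.5, 1.0)
    pts[42:48] = hexa + (0.5, 1.0)

    # mouth: outer ring 49..60 on an ellipse with full axes (h, v), lowered
    # with the jaw so lips follow mouth opening
    mouth_y = -0.95 - 0.5 * (jaw - JAW_REF)
    co, so = _ring_trig([180, 150, 120, 90, 60, 30, 0, 330, 300, 270, 240, 210])
    pts[48:60, 0] = 0.5 * h * co
    pts[48:60, 1] = mouth_y + 0.5 * v * so

    # inner ring 61..68
    ci, si = _ring_trig([180, 135, 90, 45, 0, 315, 270, 225])
    pts[60:68, 0] = 0.42 * h * ci
    pts[60:68, 1] = mouth_y + 0.38 * v * si

    return LandmarkFrame(pts, NORMALIZED)


def mean_template_frame() -> LandmarkFrame:
    """Mean of the six words' mid-vowel template poses (the reference shape)."""
    stack = np.mean([face_frame(s.v, s.h, s.jaw).points for s in WORDS.values()], axis=0)
    return LandmarkFrame(stack, NORMALIZED)


# -- trajectory synthesis ----------------------------------------------

def _bump_profile(n: int, mid: int) -> np.ndarray:
    """Cubic open-close profile: 0 at the clip edges, maximum 1 at ``mid``.

    ``q(t) = t (1 - t) (1 + g t)`` with ``g`` chosen so the interior maximum
    falls exactly on the annotated mid-vowel frame.  Because the face
    template is affine in the articulatory parameters, a cubic profile makes
    every landmark coordinate an exact degree-3 polynomial of time, so the
    noiseless synthetic corpus is closed under the pipeline's curve fitting.
    """
    t = np.arange(n, dtype=float) / (n - 1)
    tm = mid / (n - 1)
    g = (2.0 * tm - 1.0) / (2.0 * tm - 3.0 * tm * tm)
    q = t * (1.0 - t) * (1.0 + g * t)
    qm = tm * (1.0 - tm) * (1.0 + g * tm)
    return q / qm


def clear_peak_cues(talker: SyntheticTalkerParams, word: WordSpec) -> tuple[float, float, float]:
    """The talker's clear-style mid-vowel cue targets for a word."""
    v = word.v * talker.cue_scale[0] * talker.v_gain
    jaw = word.jaw * talker.cue_scale[2] * talker.jaw_gain
    h_plain = word.h * talker.cue_scale[1]
    if word.h_mode == "front":
        h = h_plain * talker.h_gain
    elif word.h_mode == "back":
        h = h_plain * (1.0 + 0.3 * (talker.h_gain - 1.0))
    else:  # rounded: tighten h toward v to increase rounding
        h = h_plain / talker.rounding_gain
    return v, h, jaw


def plain_peak_cues(talker: SyntheticTalkerParams, word: WordSpec) -> tuple[float, float, float]:
    return (
        word.v * talker.cue_scale[0],
        word.h * talker.cue_scale[1],
        word.jaw * talker.cue_scale[2],
    )


def synth_trajectory(
    talker: SyntheticTalkerParams,
    word: WordSpec | str,
    style: str,
    seed: int | None = None,
) -> LandmarkTrajectory:
    """Synthesize one word production (deterministic given ``seed``)."""
    if isinstance(word, str):
        word = WORDS[word]
    if style not in (PLAIN, CLEAR):
        raise ValueError(f"style must be plain or clear, got {style!r}")
    n = talker.n_plain_frames if style == PLAIN else talker.n_clear_frames
    mid = n // 2
    bump = _bump_profile(n, mid)

    peak = plain_peak_cues(talker, word) if style == PLAIN else clear_peak_cues(talker, word)
    rest = (REST_V, REST_H * talker.cue_scale[1], REST_JAW * talker.cue_scale[2])

    rng = np.random.default_rng(talker.seed if seed is None else seed)
    frames = []
    for b in bump:
        v = rest[0] + (peak[0] - rest[0]) * b
        h = rest[1] + (peak[1] - rest[1]) * b
        jaw = rest[2] + (peak[2] - rest[2]) * b
        pts = face_frame(v, h, jaw).points
        if talker.jitter_sigma > 0:
            pts = pts + rng.normal(0.0, talker.jitter_sigma, pts.shape)
        frames.append(LandmarkFrame(pts, NORMALIZED))

    start = max(1, n // 6)
    span = (start, mid, min(n - 1, n - 1 - start if n - 1 - start >= mid else mid))
    return LandmarkTrajectory(
        frames=frames,
        fps=29.0,
        talker_id=talker.talker_id,
        word=word.word,
        style=style,
        vowel_span=span,
    )


# -- face rendering ----------------------------------------------------

SKIN = np.array([224, 188, 158], dtype=np.uint8)
LIP = np.array([176, 70, 70], dtype=np.uint8)
MOUTH_CAVITY = np.array([38, 16, 16], dtype=np.uint8)
EYE_WHITE = np.array([245, 245, 245], dtype=np.uint8)
IRIS = np.array([60, 45, 30], dtype=np.uint8)
FEATURE = np.array([105, 75, 60], dtype=np.uint8)
BACKGROUND = np.array([210, 210, 215], dtype=np.uint8)


def placement_params(canvas: tuple[int, int], face_scale: float | None = None) -> NormalizationParams:
    """Similarity transform placing a normalized face on a pixel canvas.

    Rotation pi flips the y-up normalized face into y-down pixel space with
    the eyes above the nose.
    """
    h, w = canvas
    scale = face_scale if face_scale is not None else h / 4.8
    return NormalizationParams(np.array([w / 2.0, 0.45 * h]), np.pi, scale)


def render_face(
    frame: LandmarkFrame,
    canvas: tuple[int, int] = (256, 256),
    face_scale: float | None = None,
) -> tuple[np.ndarray, LandmarkFrame]:
    """Deterministically rasterize a synthetic face for a landmark frame.

    Returns the RGB image and the exact pixel-space landmarks, giving an
    analytic landmark-to-image correspondence for downstream tests.
    """
    h, w = canvas
    if h < 64 or w < 64:
        raise ValueError("canvas must be at least 64x64")
    params = placement_params(canvas, face_scale)
    pix = (
        denormalize_frame(frame, params)
        if frame.space == NORMALIZED
        else frame.copy()
    )
    pts = pix.points
    if pts[:, 0].min() < 1 or pts[:, 0].max() > w - 2 or pts[:, 1].min() < 1 or pts[:, 1].max() > h - 2:
        raise ValueError("landmarks do not fit the canvas; enlarge it or reduce face_scale")

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND

    jaw_pts = pts[0:17]
    brow_y = pts[17:27, 1].min()
    cx = float(jaw_pts[:, 0].mean())
    cy = float(0.5 * (brow_y + jaw_pts[:, 1].max()))
    semi_x = 0.5 * (jaw_pts[:, 0].max() - jaw_pts[:, 0].min()) * 1.06
    semi_y = 0.5 * (jaw_pts[:, 1].max() - brow_y) * 1.18
    rr, cc = ellipse(cy, cx, semi_y, semi_x, shape=(h, w))
    img[rr, cc] = SKIN

    # jaw-following chin contour
    for p in jaw_pts:
        rr, cc = disk((p[1], p[0]), 1.6, shape=(h, w))
        img[rr, cc] = FEATURE

    # eyebrows and nose
    for p in np.vstack([pts[17:27], pts[27:36]]):
        rr, cc = disk((p[1], p[0]), 1.4, shape=(h, w))
        img[rr, cc] = FEATURE

    # eyes: white hexagon fill + iris at the centroid
    for sl in (slice(36, 42), slice(42, 48)):
        eye = pts[sl]
        rr, cc = polygon(eye[:, 1], eye[:, 0], shape=(h, w))
        img[rr, cc] = EYE_WHITE
        c = eye.mean(axis=0)
        rr, cc = disk((c[1], c[0]), 2.2, shape=(h, w))
        img[rr, cc] = IRIS

    # lips: filled outer ring, dark cavity inside the inner ring
    outer = pts[48:60]
    rr, cc = polygon(outer[:, 1], outer[:, 0], shape=(h, w))
    img[rr, cc] = LIP
    inner = pts[60:68]
    rr, cc = polygon(inner[:, 1], inner[:, 0], shape=(h, w))
    img[rr, cc] = MOUTH_CAVITY

    return img, pix


# -- corpus generation -------------------------------------------------

def _token_seed(seed: int, talker_idx: int, word_idx: int, style_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([seed, talker_idx, word_idx, style_idx, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_corpus(
    out_dir: str | Path,
    n_talkers: int = 18,
    plain_reps: int = 15,
    clear_reps: int = 12,
    seed: int = 0,
    write_images: bool = False,
    talker_overrides: dict | None = None,
) -> pd.DataFrame:
    """Write a synthetic landmark corpus and its manifest to ``out_dir``.

    The default design mirrors an 18-talker panel contributing, per talker,
    6 words x 15 plain and 6 x 12 clear repetitions.  Returns the manifest
    (also written as ``manifest.csv``: talker, word, style, repetition,
    tensity, gender, path).
    """
    if n_talkers < 1:
        raise ValueError("need at least one talker")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    word_list = list(WORDS)
    for ti in range(n_talkers):
        talker = make_talker(ti, seed, **(talker_overrides or {}))
        for wi, word in enumerate(word_list):
            for si, (style, reps) in enumerate(((PLAIN, plain_reps), (CLEAR, clear_reps))):
                for rep in range(reps):
                    tok_seed = _token_seed(seed, ti, wi, si, rep)
                    traj = synth_trajectory(talker, word, style, seed=tok_seed)
                    rel = f"{talker.talker_id}_{word}_{style}_{rep:02d}.json"
                    cs_io.save_trajectory_json(traj, out / rel)
                    if write_images:
                        img_dir = out / f"{talker.talker_id}_{word}_{style}_{rep:02d}_frames"
                        from .render import write_frames  # local import avoids cycle

                        imgs = [render_face(f)[0] for f in traj.frames]
                        write_frames(imgs, img_dir)
                    rows.append(
                        {
                            "talker": talker.talker_id,
                            "word": word,
                            "style": style,
                            "repetition": rep,
                            "tensity": WORDS[word].tensity,
                            "gender": talker.gender_tag,
                            "path": rel,
                        }
                    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
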