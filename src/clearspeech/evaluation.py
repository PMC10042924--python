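"""Lip-reader style data preparation and a geometric word classifier.

The clip preparation mirrors standard lip-reading front ends: select a
fixed budget of 29 frames (1 s at 29 fps) at regular spacing, align each
frame to a reference mean face shape with a similarity transform, crop a
96 x 96 region centered on the mouth, and convert to gray level.

Word identification itself is served by a deterministic nearest-centroid
classifier over the five visual-cue trajectories (resampled to a fixed
time grid and z-scored with training statistics).  It sits behind a small
interface — anything with ``predict(trajectory) -> word`` plugs in — so a
learned lip reader can replace it without touching the evaluation logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import estimate_transform, warp

from .landmarks import NORMALIZED, LandmarkFrame, compute_visual_cues, normalize_frame
from .synthetic import WORDS, mean_template_frame, placement_params
from .landmarks import denormalize_frame
from .trajectory import LandmarkTrajectory

__all__ = [
    "TARGET_FRAMES",
    "CROP_SIZE",
    "select_frames",
    "reference_face_shape",
    "preprocess_clip",
    "cue_features",
    "CentroidClassifier",
    "evaluate_accuracy",
]

TARGET_FRAMES = 29
CROP_SIZE = 96
FEATURE_GRID = 20

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def select_frames(n_frames: int, target: int = TARGET_FRAMES) -> list[int]:
    """Indices of ``target`` frames taken at regular distance from a clip.

    A clip longer than the budget is thinned with ``floor(i * n / target)``
    (a 58-frame clip keeps every alternate frame); a shorter clip is padded
    by repeating its last frame.
    """
    if n_frames < 1:
        raise ValueError("clip must have at least one frame")
    if n_frames >= target:
        return [int(np.floor(i * n_frames / target)) for i in range(target)]
    return list(range(n_frames)) + [n_frames - 1] * (target - n_frames)


def reference_face_shape(canvas: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Pixel-space mean face shape used for alignment.

    Computed from the packaged synthetic face templates (the mean of the six
    words' mid-vowel poses) placed on the given canvas.
    """
    ref = mean_template_frame()
    return denormalize_frame(ref, placement_params(canvas)).points


def preprocess_clip(
    frames: list[np.ndarray],
    landmarks: list[LandmarkFrame],
    *,
    target: int = TARGET_FRAMES,
    crop_size: int = CROP_SIZE,
) -> np.ndarray:
    """Prepare a clip for word classification.

    Returns a (target, crop, crop) uint8 stack: frames selected at regular
    distance, each aligned to the reference mean face shape, cropped to a
    mouth-centered square, and converted to gray level.
    """
    if len(frames) != len(landmarks):
        raise ValueError("one landmark frame is required per image frame")
    if any(lm is None for lm in landmarks):
        raise ValueError("missing landmarks for a frame")
    idx = select_frames(len(frames), target)
    h, w = np.asarray(frames[0]).shape[:2]
    ref = reference_face_shape((h, w))

    out = np.empty((target, crop_size, crop_size), dtype=np.uint8)
    half = crop_size // 2
    for row, i in enumerate(idx):
        img = np.asarray(frames[i], dtype=float)
        lm = landmarks[i].points
        tf = estimate_transform("similarity", ref, lm)  # maps reference -> frame
        if not np.all(np.isfinite(tf.params)):
            raise ValueError("could not estimate the alignment transform")
        aligned = warp(img, tf, output_shape=(h, w), preserve_range=True)
        aligned_lm = tf.inverse(lm)
        gray = aligned @ _LUMA if aligned.ndim == 3 else aligned

        mouth = aligned_lm[48:68].mean(axis=0)
        cx = int(np.clip(round(mouth[0]), half, w - half))
        cy = int(np.clip(round(mouth[1]), half, h - half))
        crop = gray[cy - half : cy + half, cx - half : cx + half]
        out[row] = np.clip(np.rint(crop), 0, 255).astype(np.uint8)
    return out


def cue_features(traj: LandmarkTrajectory, n_grid: int = FEATURE_GRID) -> np.ndarray:
    """Concatenated cue trajectories on a fixed normalized-time grid.

    The five visual cues are measured per frame (frames are normalized
    first when given in pixel space) and each series is linearly resampled
    to ``n_grid`` points, yielding a (5 * n_grid,) vector.
    """
    series = []
    for f in traj.frames:
        nf = f if f.space == NORMALIZED else normalize_frame(f)[0]
        series.append(compute_visual_cues(nf).as_array())
    cues = np.asarray(series)  # (n, 5)
    t_src = np.linspace(0.0, 1.0, cues.shape[0])
    t_dst = np.linspace(0.0, 1.0, n_grid)
    return np.concatenate([np.interp(t_dst, t_src, cues[:, j]) for j in range(5)])


@dataclass
class CentroidClassifier:
    """Nearest-centroid word classifier over z-scored cue features.

    Prediction returns the class whose centroid is nearest in Euclidean
    distance; exact ties go to the lexicographically first word.
    """

    classes_: list[str] | None = None
    centroids_: np.ndarray | None = None
    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None
    n_grid: int = FEATURE_GRID

    def fit(
        self,
        trajectories: list[LandmarkTrajectory],
        labels: list[str],
        classes: list[str] | None = None,
    ) -> "CentroidClassifier":
        if len(trajectories) != len(labels):
            raise ValueError("one label per trajectory is required")
        feats = np.stack([cue_features(t, self.n_grid) for t in trajectories])
        self.classes_ = sorted(set(labels) if classes is None else classes)
        self.mean_ = feats.mean(axis=0)
        std = feats.std(axis=0)
        self.std_ = np.where(std < 1e-12, 1.0, std)
        z = (feats - self.mean_) / self.std_
        labels_arr = np.asarray(labels)
        centroids = []
        for cls in self.classes_:
            sel = labels_arr == cls
            if not sel.any():
                raise ValueError(f"no training examples for class {cls!r}")
            centroids.append(z[sel].mean(axis=0))
        self.centroids_ = np.stack(centroids)
        return self

    def _check_fitted(self) -> None:
        if self.centroids_ is None:
            raise RuntimeError("classifier is not fitted")

    def transform(self, traj: LandmarkTrajectory) -> np.ndarray:
        self._check_fitted()
        return (cue_features(traj, self.n_grid) - self.mean_) / self.std_

    def predict(self, traj: LandmarkTrajectory) -> str:
        z = self.transform(traj)
        d = np.linalg.norm(self.centroids_ - z, axis=1)
        # classes_ is sorted, so argmin's first-match rule is the
        # lexicographic tie-break
        return self.classes_[int(np.argmin(d))]

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        Path(path).write_text(
            json.dumps(
                {
                    "classes": self.classes_,
                    "centroids": self.centroids_.tolist(),
                    "mean": self.mean_.tolist(),
                    "std": self.std_.tolist(),
                    "n_grid": self.n_grid,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            classes_=list(d["classes"]),
            centroids_=np.asarray(d["centroids"], dtype=float),
            mean_=np.asarray(d["mean"], dtype=float),
            std_=np.asarray(d["std"], dtype=float),
            n_grid=int(d["n_grid"]),
        )


def evaluate_accuracy(
    classifier,
    items: list[tuple[LandmarkTrajectory, str, str]],
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Aggregate word-identification accuracy by condition and vowel tensity.

    ``items`` holds (trajectory, true word, condition) triples.  Returns a
    summary table with one row per (condition, tensity) cell plus an "all"
    tensity row per condition — accuracy, binomial standard error and n —
    and a confusion matrix (true x predicted) per condition.  Empty cells
    simply do not appear (missing, not zero).
    """
    records = []
    for traj, word, condition in items:
        pred = classifier.predict(traj)
        records.append(
            {
                "condition": condition,
                "word": word,
                "tensity": WORDS[word].tensity if word in WORDS else "unknown",
                "predicted": pred,
                "correct": int(pred == word),
            }
        )
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=["condition", "tensity", "n", "accuracy", "se"]), {}

    rows = []
    for (cond, tensity), grp in df.groupby(["condition", "tensity"], sort=True):
        rows.append(_cell(cond, tensity, grp))
    for cond, grp in df.groupby("condition", sort=True):
        rows.append(_cell(cond, "all", grp))
    summary = pd.DataFrame(rows)

    confusions = {
        cond: pd.crosstab(grp["word"], grp["predicted"]).rename_axis(
            index="true", columns="predicted"
        )
        for cond, grp in df.groupby("condition", sort=True)
    }
    return summary, confusions


def _cell(condition: str, tensity: str, grp: pd.DataFrame) -> dict:
    n = len(grp)
    p = grp["correct"].mean()
    return {
        "condition": condition,
        "tensity": tensity,
        "n": n,
        "accuracy": p,
        "se": float(np.sqrt(p * (1.0 - p) / n)),
    }
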