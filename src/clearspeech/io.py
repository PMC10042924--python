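"""Landmark file I/O.

JSON schema (one word clip per file)::

    {
      "talker": "T01", "word": "could", "style": "plain", "fps": 29.0,
      "space": "normalized",
      "vowel_span": [2, 4, 7],            # 0-based frame indices, or null
      "frames": [[[x, y], ... 68 pairs], ... n_frames]
    }

A long-format CSV alternative is also supported with columns
``frame, landmark, x, y`` where ``landmark`` is **1-based** (1..68) to match
the formula notation; clip annotations travel as keyword arguments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import N_LANDMARKS, LandmarkFrame
from .trajectory import LandmarkTrajectory

__all__ = [
    "save_trajectory_json",
    "load_trajectory_json",
    "save_trajectory_csv",
    "load_trajectory_csv",
]


def save_trajectory_json(traj: LandmarkTrajectory, path: str | Path) -> None:
    payload = {
        "talker": traj.talker_id,
        "word": traj.word,
        "style": traj.style,
        "fps": traj.fps,
        "space": traj.space,
        "vowel_span": list(traj.vowel_span) if traj.vowel_span is not None else None,
        "frames": [np.round(f.points, 12).tolist() for f in traj.frames],
    }
    Path(path).write_text(json.dumps(payload))


def load_trajectory_json(path: str | Path) -> LandmarkTrajectory:
    payload = json.loads(Path(path).read_text())
    space = payload.get("space", "pixel")
    frames = [LandmarkFrame(np.asarray(f, dtype=float), space) for f in payload["frames"]]
    span = payload.get("vowel_span")
    return LandmarkTrajectory(
        frames=frames,
        fps=float(payload.get("fps", 29.0)),
        talker_id=payload.get("talker", ""),
        word=payload.get("word", ""),
        style=payload.get("style", "plain"),
        vowel_span=tuple(span) if span is not None else None,
    )


def save_trajectory_csv(traj: LandmarkTrajectory, path: str | Path) -> None:
    """Write the long-format CSV (frame, landmark, x, y); landmark is 1-based."""
    n = traj.n_frames
    pts = traj.points().reshape(n * N_LANDMARKS, 2)
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), N_LANDMARKS),
            "landmark": np.tile(np.arange(1, N_LANDMARKS + 1), n),
            "x": pts[:, 0],
            "y": pts[:, 1],
        }
    )
    df.to_csv(path, index=False)


def load_trajectory_csv(
    path: str | Path,
    *,
    space: str = "pixel",
    fps: float = 29.0,
    talker_id: str = "",
    word: str = "",
    style: str = "plain",
    vowel_span: tuple[int, int, int] | None = None,
) -> LandmarkTrajectory:
    """Read the long-format CSV; ``landmark`` column is 1-based (converted here)."""
    df = pd.read_csv(path)
    frames = []
    for _, grp in df.sort_values(["frame", "landmark"]).groupby("frame", sort=True):
        if len(grp) != N_LANDMARKS:
            raise ValueError("each frame must have exactly 68 landmark rows")
        frames.append(LandmarkFrame(grp[["x", "y"]].to_numpy(dtype=float), space))
    return LandmarkTrajectory(
        frames=frames, fps=fps, talker_id=talker_id, word=word, style=style, vowel_span=vowel_span
    )
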