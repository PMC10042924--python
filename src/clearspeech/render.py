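"""Image generator: piecewise affine warping of the mid-vowel face image.

A Delaunay mesh is built once on the source mid-vowel landmarks plus eight
fixed border anchors (corners and edge midpoints, which pin the background).
Each destination landmark frame reuses the mesh topology; every destination
triangle is mapped by its own affine transform back to the source (inverse
mapping with bilinear sampling, so the output is hole-free), and pixels
outside the mesh are copied from the source.  Warping the single high-
resolution mid-vowel image to every destination frame preserves the input
resolution throughout the synthesized clip.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.spatial import Delaunay

from .landmarks import (
    NORMALIZED,
    LandmarkFrame,
    NormalizationParams,
    denormalize_frame,
)
from .trajectory import LandmarkTrajectory, temporal_smooth

__all__ = [
    "WarpSpec",
    "border_anchors",
    "build_warp_spec",
    "piecewise_affine_warp",
    "generate_video",
    "write_frames",
    "read_frames",
]

logger = logging.getLogger(__name__)

MIN_IMAGE_SIDE = 64


@dataclass
class WarpSpec:
    """Source/destination point sets (pixel space) sharing one triangulation."""

    src_points: np.ndarray  # (N, 2), x then y
    dst_points: np.ndarray  # (N, 2)
    triangles: np.ndarray  # (M, 3) indices into the point sets

    def __post_init__(self) -> None:
        self.src_points = np.asarray(self.src_points, dtype=float)
        self.dst_points = np.asarray(self.dst_points, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.src_points.shape != self.dst_points.shape:
            raise ValueError("source and destination point sets must match in shape")


def border_anchors(shape: tuple[int, int]) -> np.ndarray:
    """Four corners and four edge midpoints of an image of the given (H, W)."""
    h, w = shape[0] - 1.0, shape[1] - 1.0
    return np.array(
        [
            [0, 0], [w, 0], [0, h], [w, h],
            [w / 2, 0], [w / 2, h], [0, h / 2], [w, h / 2],
        ],
        dtype=float,
    )


def build_warp_spec(
    src_landmarks: np.ndarray, dst_landmarks: np.ndarray, image_shape: tuple[int, int]
) -> WarpSpec:
    """Anchor both point sets to the image border and triangulate the source."""
    anchors = border_anchors(image_shape)
    src = np.vstack([np.asarray(src_landmarks, dtype=float), anchors])
    dst = np.vstack([np.asarray(dst_landmarks, dtype=float), anchors])
    tri = Delaunay(src)
    return WarpSpec(src, dst, tri.simplices)


def _affine_from_triangles(dst: np.ndarray, src: np.ndarray) -> np.ndarray:
    """2x3 affine A with A @ [x_d, y_d, 1] = [x_s, y_s] for the three vertices."""
    m = np.hstack([dst, np.ones((3, 1))])  # (3, 3)
    return np.linalg.solve(m, src).T  # (2, 3)


def _bilinear(image: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h, w = image.shape[:2]
    x = np.clip(x, 0.0, w - 1.0)
    y = np.clip(y, 0.0, h - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2)
    fx = (x - x0)[..., None]
    fy = (y - y0)[..., None]
    img = image.astype(float)
    top = img[y0, x0] * (1 - fx) + img[y0, x0 + 1] * fx
    bot = img[y0 + 1, x0] * (1 - fx) + img[y0 + 1, x0 + 1] * fx
    return top * (1 - fy) + bot * fy


def piecewise_affine_warp(image: np.ndarray, spec: WarpSpec) -> np.ndarray:
    """Warp an RGB image triangle by triangle (inverse mapping, bilinear).

    Output dimensions equal the input's.  Pixels outside every destination
    triangle are copied from the source; degenerate destination triangles
    are skipped with a warning.  Triangles whose vertices did not move are
    copied verbatim, so the identity warp is bit-exact.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[..., None]
    h, w = image.shape[:2]
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise ValueError(f"image must be at least {MIN_IMAGE_SIDE}px per side")
    out = image.copy()

    for tri in spec.triangles:
        dst = spec.dst_points[tri]
        src = spec.src_points[tri]
        if np.max(np.abs(dst - src)) < 1e-9:
            continue  # identity triangle: out already holds the source pixels
        area2 = (dst[1, 0] - dst[0, 0]) * (dst[2, 1] - dst[0, 1]) - (
            dst[2, 0] - dst[0, 0]
        ) * (dst[1, 1] - dst[0, 1])
        if abs(area2) < 1e-12:
            warnings.warn("skipping degenerate destination triangle", stacklevel=2)
            continue

        x0 = max(0, int(np.floor(dst[:, 0].min())))
        x1 = min(w - 1, int(np.ceil(dst[:, 0].max())))
        y0 = max(0, int(np.floor(dst[:, 1].min())))
        y1 = min(h - 1, int(np.ceil(dst[:, 1].max())))
        if x1 < x0 or y1 < y0:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))

        # barycentric coordinates w.r.t. the destination triangle
        d = np.stack([xs - dst[0, 0], ys - dst[0, 1]], axis=-1)
        e1 = dst[1] - dst[0]
        e2 = dst[2] - dst[0]
        inv_det = 1.0 / area2
        l1 = (d[..., 0] * e2[1] - d[..., 1] * e2[0]) * inv_det
        l2 = (e1[0] * d[..., 1] - e1[1] * d[..., 0]) * inv_det
        mask = (l1 >= -1e-9) & (l2 >= -1e-9) & (l1 + l2 <= 1.0 + 1e-9)
        if not mask.any():
            continue

        aff = _affine_from_triangles(dst, src)
        sx = aff[0, 0] * xs + aff[0, 1] * ys + aff[0, 2]
        sy = aff[1, 0] * xs + aff[1, 1] * ys + aff[1, 2]
        sampled = _bilinear(image, sx[mask], sy[mask])
        out[ys[mask], xs[mask]] = np.clip(np.rint(sampled), 0, 255).astype(out.dtype)

    return out if out.shape[-1] > 1 else out[..., 0]


def generate_video(
    source: np.ndarray,
    source_mid_frame: LandmarkFrame,
    destination_frames: list[LandmarkFrame],
    params: NormalizationParams,
    fps: float = 29.0,
) -> list[np.ndarray]:
    """Synthesize one warped frame per destination landmark frame.

    The destination frames (normalized space) are first temporally smoothed
    with degree-3 curves, then brought to the scale and orientation of the
    mid-vowel source frame via ``params``, and finally each is rendered by
    piecewise-affine warping of the single source image.  The frame rate is
    unchanged; ``fps`` is metadata for downstream writers.
    """
    if len(destination_frames) < 2:
        raise ValueError("need at least 2 destination frames")
    if any(f.space != NORMALIZED for f in destination_frames):
        raise ValueError("destination frames must be in normalized space")
    source = np.asarray(source)
    h, w = source.shape[:2]

    traj = LandmarkTrajectory(frames=list(destination_frames), fps=fps, style="modified")
    smoothed = temporal_smooth(traj).frames

    spec0 = None
    outputs: list[np.ndarray] = []
    for frame in smoothed:
        pix = denormalize_frame(frame, params).points
        if (pix[:, 0].min() < 0 or pix[:, 0].max() > w - 1
                or pix[:, 1].min() < 0 or pix[:, 1].max() > h - 1):
            warnings.warn("destination landmarks outside image; clamped to border",
                          stacklevel=2)
            pix[:, 0] = np.clip(pix[:, 0], 0, w - 1)
            pix[:, 1] = np.clip(pix[:, 1], 0, h - 1)
        if spec0 is None:
            spec0 = build_warp_spec(source_mid_frame.points, pix, (h, w))
        spec = WarpSpec(spec0.src_points,
                        np.vstack([pix, border_anchors((h, w))]),
                        spec0.triangles)
        outputs.append(piecewise_affine_warp(source, spec))
    return outputs


def write_frames(frames: list[np.ndarray], out_dir: str | Path) -> list[Path]:
    """Write a frame sequence as zero-padded PNGs (frame_0000.png, ...)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:04d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_frames(in_dir: str | Path) -> list[np.ndarray]:
    return [iio.imread(p) for p in sorted(Path(in_dir).glob("frame_*.png"))]
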