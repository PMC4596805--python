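"""Software rendering of tractograms with transparency.

The pipeline projects streamline points through a camera, builds line
segments carrying a directionally-encoded color (RGB = |n_x|, |n_y|, |n_z|)
and an opacity, orders all segments back-to-front by their mean distance
from the eye (painter's algorithm), and alpha-composites them onto the
background with the standard "over" operator

    C <- alpha * C_segment + (1 - alpha) * C.

Rasterization is 1-px Bresenham lines without antialiasing, so renders are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from skimage.draw import line as _bresenham_line

from .errors import ConfigurationError, DomainError
from .opacity import OpacityConfig, assign_opacity
from .tract_io import Tractogram


@dataclass
class Camera:
    """Viewing geometry for the software renderer.

    eye : 3D point (mm)
    view_axis : unit vector normal to the image plane, pointing from the
        eye into the scene
    up : approximate up direction (orthogonalized internally)
    projection : 'orthographic' (default) or 'perspective'
    image_size : (width, height) in pixels
    scale : mm per pixel (orthographic) or vertical field of view in
        degrees (perspective)
    """

    eye: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -200.0]))
    view_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    projection: str = "orthographic"
    image_size: Tuple[int, int] = (256, 256)
    scale: float = 0.5

    def __post_init__(self):
        self.eye = np.asarray(self.eye, dtype=float)
        self.view_axis = np.asarray(self.view_axis, dtype=float)
        self.view_axis = self.view_axis / np.linalg.norm(self.view_axis)
        self.up = np.asarray(self.up, dtype=float)
        self.up = self.up / np.linalg.norm(self.up)
        if abs(float(self.view_axis @ self.up)) > 1.0 - 1e-9:
            raise ConfigurationError("camera up vector is parallel to the view axis")
        if self.projection not in ("orthographic", "perspective"):
            raise ConfigurationError(f"unknown projection {self.projection!r}")

    def basis(self):
        """Right-handed (right, up, forward) orthonormal camera frame."""
        f = self.view_axis
        r = np.cross(f, self.up)
        r = r / np.linalg.norm(r)
        u = np.cross(r, f)
        return r, u, f

    def project(self, points: np.ndarray):
        """Map world points to pixel coordinates and depths.

        Returns ``(xy, depth)``: ``xy`` is (N, 2) float pixel coordinates
        (x right, y down) and ``depth`` the distance along the view axis.
        """
        r, u, f = self.basis()
        d = np.asarray(points, dtype=float) - self.eye
        depth = d @ f
        x = d @ r
        y = d @ u
        w, h = self.image_size
        if self.projection == "orthographic":
            px = (w - 1) / 2 + x / self.scale
            py = (h - 1) / 2 - y / self.scale
        else:
            focal = (h / 2) / np.tan(np.deg2rad(self.scale) / 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                px = (w - 1) / 2 + focal * x / depth
                py = (h - 1) / 2 - focal * y / depth
        return np.column_stack([px, py]), depth


@dataclass
class Segment:
    """A projected streamline segment ready for compositing."""

    p0: np.ndarray  # (2,) pixel coordinates
    p1: np.ndarray
    color: np.ndarray  # (3,) RGB in [0, 1]
    alpha: float
    mean_depth: float


def dec_color(orientation) -> np.ndarray:
    """Directionally-encoded color: RGB = absolute axis components."""
    n = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise DomainError("dec_color requires a unit orientation")
    return np.abs(n)


def build_segments(tractogram: Tractogram, camera: Camera) -> list:
    """Project a tractogram into drawable segments.

    Segment opacity is the mean of its two endpoint opacities (taken from
    the tractogram's ``"alpha"`` channel, defaulting to 1); segment color
    encodes the normalized endpoint difference.
    """
    alphas = tractogram.scalars.get("alpha")
    segments = []
    for idx, s in enumerate(tractogram.streamlines):
        xy, depth = camera.project(s)
        a = (np.asarray(alphas[idx], dtype=float)
             if alphas is not None else np.ones(len(s)))
        diffs = np.diff(np.asarray(s, dtype=float), axis=0)
        norms = np.linalg.norm(diffs, axis=1)
        norms[norms == 0] = 1.0
        colors = np.abs(diffs / norms[:, None])
        seg_alpha = 0.5 * (a[:-1] + a[1:])
        seg_depth = 0.5 * (depth[:-1] + depth[1:])
        for i in range(len(s) - 1):
            segments.append(Segment(
                p0=xy[i], p1=xy[i + 1], color=colors[i],
                alpha=float(seg_alpha[i]), mean_depth=float(seg_depth[i]),
            ))
    return segments


def depth_sort_segments(segments: list) -> list:
    """Order segments far-to-near by mean depth; stable for ties."""
    depths = np.array([s.mean_depth for s in segments])
    if depths.size and not np.all(np.isfinite(depths)):
        raise ValueError("segment depths must be finite")
    order = np.argsort(-depths, kind="stable")
    return [segments[i] for i in order]


def composite(ordered_segments: list, background, image_size) -> np.ndarray:
    """Alpha-composite pre-sorted segments onto a background raster.

    Returns an (H, W, 3) float image in [0, 1].  An empty segment list
    returns the plain background.
    """
    w, h = image_size
    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.asarray(background, dtype=float)
    for seg in ordered_segments:
        if seg.alpha <= 0.0:
            continue
        r0, c0 = int(round(seg.p0[1])), int(round(seg.p0[0]))
        r1, c1 = int(round(seg.p1[1])), int(round(seg.p1[0]))
        rr, cc = _bresenham_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[keep], cc[keep]
        image[rr, cc] = seg.alpha * seg.color + (1.0 - seg.alpha) * image[rr, cc]
    return image


def render_scene(tractogram: Tractogram, camera: Camera,
                 config: Optional[OpacityConfig] = None,
                 background=(0.0, 0.0, 0.0)):
    """Full pipeline: opacity assignment, projection, sort, composite.

    With ``config=None`` every segment is fully opaque (conventional
    rendering).  When ``config.axis_mode='view'`` the opacity axis is the
    camera's viewing axis.  Returns ``(image, tractogram_with_alpha)``.
    """
    if config is not None:
        view = camera.view_axis if config.axis_mode == "view" else None
        tractogram = assign_opacity(tractogram, config, view_axis=view)
    segments = build_segments(tractogram, camera)
    ordered = depth_sort_segments(segments)
    image = composite(ordered, background, camera.image_size)
    return image, tractogram


def save_png(image: np.ndarray, path) -> None:
    """Write a float [0, 1] RGB raster to an 8-bit PNG."""
    data = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="RGB").save(path)
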