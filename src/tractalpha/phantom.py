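"""Synthetic tractography phantoms.

Generates tractograms with known geometry for testing and demonstration:
straight bundles (corticospinal-tract-like), planar circular arcs
(U-fiber / callosal-like; a 90-degree arc has linear coefficient
c_l -> 2/pi and a 180-degree arc c_l -> 0 in the dense-sampling limit),
constant-pitch helices, and two straight bundles crossing at a set angle.
Per-streamline principal axes can be jittered by a Watson distribution to
emulate orientational dispersion within a bundle.  Output is deterministic
given the spec's seed, and ground-truth geometry is returned alongside the
tractogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .tract_io import Tractogram
from .watson import WatsonParams, sample_watson

_SHAPES = ("straight", "arc", "helix", "crossing")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bundle.

    shape : 'straight', 'arc', 'helix' or 'crossing'
    n_streamlines, points_per_streamline : counts
    length_mm : bundle length (straight/crossing) or axial extent (helix)
    arc_angle_deg : angular sweep of arcs and helices, in (0, 360)
    radius_mm : arc / helix radius
    spread_mm : side of the uniform cube of per-streamline offsets
    crossing_angle_deg : angle between the two bundles of a crossing
    jitter_kappa : Watson concentration of per-streamline axis jitter;
        ``None`` disables jitter (perfectly coherent bundle)
    seed : fixes all randomness
    """

    shape: str = "straight"
    n_streamlines: int = 50
    points_per_streamline: int = 100
    length_mm: float = 80.0
    arc_angle_deg: float = 90.0
    radius_mm: float = 30.0
    spread_mm: float = 4.0
    crossing_angle_deg: float = 90.0
    jitter_kappa: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ConfigurationError(f"unknown phantom shape {self.shape!r}")
        if self.n_streamlines < 1 or self.points_per_streamline < 2:
            raise ConfigurationError(
                "need n_streamlines >= 1 and points_per_streamline >= 2"
            )
        if not (0.0 < self.arc_angle_deg < 360.0):
            raise ConfigurationError("arc_angle_deg must lie in (0, 360)")
        if self.length_mm <= 0 or self.radius_mm <= 0 or self.spread_mm < 0:
            raise ConfigurationError("lengths and radii must be positive")
        if self.jitter_kappa is not None and self.jitter_kappa <= 0:
            raise ConfigurationError("jitter_kappa must be > 0 or None")


def _rotation_between(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector w."""
    c = float(np.clip(u @ w, -1.0, 1.0))
    axis = np.cross(u, w)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate pi about any axis orthogonal to u
        ortho = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            ortho = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, ortho)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _base_curve(spec: PhantomSpec, bundle_axis: np.ndarray) -> np.ndarray:
    n = spec.points_per_streamline
    if spec.shape in ("straight", "crossing"):
        s = np.linspace(-spec.length_mm / 2, spec.length_mm / 2, n)
        return s[:, None] * bundle_axis
    sweep = np.deg2rad(spec.arc_angle_deg)
    phi = np.linspace(np.pi / 2 - sweep / 2, np.pi / 2 + sweep / 2, n)
    if spec.shape == "arc":
        return np.column_stack([
            spec.radius_mm * np.cos(phi),
            spec.radius_mm * np.sin(phi),
            np.zeros(n),
        ])
    # helix: arc in-plane plus constant-pitch axial advance
    z = np.linspace(-spec.length_mm / 2, spec.length_mm / 2, n)
    return np.column_stack([
        spec.radius_mm * np.cos(phi),
        spec.radius_mm * np.sin(phi),
        z,
    ])


def _principal_axis(spec: PhantomSpec, bundle_axis: np.ndarray) -> np.ndarray:
    if spec.shape in ("straight", "crossing"):
        return bundle_axis
    if spec.shape == "helix":
        return np.array([0.0, 0.0, 1.0])
    # arc: dominant tangent direction is the chord-perpendicular in-plane axis
    return np.array([0.0, 1.0, 0.0])


def make_phantom(spec: PhantomSpec):
    """Build a synthetic tractogram per ``spec``.

    Returns ``(tractogram, ground_truth)`` where ``ground_truth`` is a
    JSON-serializable dict holding the canonical bundle axes, the arc
    angle, and (for crossings) per-streamline bundle labels.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "crossing":
        half = np.deg2rad(spec.crossing_angle_deg) / 2
        axes = [np.array([np.cos(half), np.sin(half), 0.0]),
                np.array([np.cos(half), -np.sin(half), 0.0])]
        n_a = spec.n_streamlines - spec.n_streamlines // 2
        labels = [0] * n_a + [1] * (spec.n_streamlines // 2)
    else:
        axes = [np.array([0.0, 0.0, 1.0])]
        labels = [0] * spec.n_streamlines

    streamlines = []
    jittered_axes = []
    for i, label in enumerate(labels):
        bundle_axis = axes[label]
        pts = _base_curve(spec, bundle_axis)
        principal = _principal_axis(spec, bundle_axis)
        if spec.jitter_kappa is not None:
            target = sample_watson(
                WatsonParams(principal, spec.jitter_kappa), 1,
                seed=rng.integers(2 ** 31),
            )[0]
            if target @ principal < 0:  # axial sample: align hemisphere
                target = -target
            pts = pts @ _rotation_between(principal, target).T
            jittered_axes.append(target.tolist())
        else:
            jittered_axes.append(principal.tolist())
        offset = rng.uniform(-spec.spread_mm / 2, spec.spread_mm / 2, 3)
        streamlines.append(pts + offset)

    tractogram = Tractogram(streamlines)
    tractogram.validate()
    ground_truth = {
        "shape": spec.shape,
        "bundle_axes": [a.tolist() for a in axes],
        "principal_axes": jittered_axes,
        "labels": labels,
        "arc_angle_deg": spec.arc_angle_deg,
        "seed": spec.seed,
    }
    return tractogram, ground_truth
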