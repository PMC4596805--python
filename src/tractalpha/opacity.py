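"""Orientation-to-opacity mapping.

Opacity alpha in [0, 1] (1 = opaque) is a function of the inner product
|n . t| between a streamline orientation axis n and the user-chosen opacity
axis t.  Two power functions are provided,

    alpha_decreasing = (1 - |n.t|)^c        (fade axis-parallel segments)
    alpha_increasing = |n.t|^c              (emphasize axis-parallel segments)

with c > 0 tuning the steepness, plus a piecewise-linear ramp in the angle
theta = acos|n.t|.  Orientation can be taken per point (local scale) or once
per streamline (endpoint chord or scatter mean axis).  Strongly dispersed
streamlines — linear coefficient c_l below a threshold T_cl — can be forced
fully opaque so curved bundles stay visible in every view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DomainError, EmptyInputError
from .geometry import endpoint_orientation, local_orientations, streamline_summary
from .tract_io import Tractogram

_SCALES = ("local", "global_endpoints", "global_scatter")
_FUNCTIONS = ("power_decreasing", "power_increasing", "linear_theta")
_DOT_SLACK = 1e-9


@dataclass
class OpacityConfig:
    """Options for orientation-dependent opacity assignment.

    scale : 'local', 'global_endpoints' or 'global_scatter'
    axis_mode : 'fixed' (use ``t``) or 'view' (caller supplies the viewing axis)
    t : unit opacity axis, required when ``axis_mode='fixed'``
    function : 'power_decreasing', 'power_increasing' or 'linear_theta'
    c : power-function exponent (> 0); default 3
    a, b : slope/intercept of the linear ramp in theta; defaults 2/pi and 0
    T_cl : optional dispersion gate in [0, 1]; streamlines with c_l below it
        are rendered fully opaque regardless of orientation
    """

    scale: str = "local"
    axis_mode: str = "view"
    t: Optional[np.ndarray] = None
    function: str = "power_decreasing"
    c: float = 3.0
    a: float = 2.0 / np.pi
    b: float = 0.0
    T_cl: Optional[float] = None

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.function not in _FUNCTIONS:
            raise ConfigurationError(f"unknown opacity function {self.function!r}")
        if self.axis_mode not in ("fixed", "view"):
            raise ConfigurationError(f"unknown axis_mode {self.axis_mode!r}")
        if self.axis_mode == "fixed":
            if self.t is None:
                raise ConfigurationError("axis_mode='fixed' requires an opacity axis t")
            self.t = np.asarray(self.t, dtype=float)
            norm = np.linalg.norm(self.t)
            if abs(norm - 1.0) > 1e-6:
                if norm == 0:
                    raise ConfigurationError("opacity axis t must be non-zero")
                self.t = self.t / norm
        if self.c <= 0:
            raise ConfigurationError("power exponent c must be > 0")
        if self.T_cl is not None and not (0.0 <= self.T_cl <= 1.0):
            raise ConfigurationError("T_cl must lie in [0, 1]")


def _check_dot(dot) -> np.ndarray:
    dot = np.asarray(dot, dtype=float)
    if np.any(dot < -_DOT_SLACK) or np.any(dot > 1.0 + _DOT_SLACK):
        raise DomainError("|n.t| outside [0, 1]: upstream axes are not unit vectors")
    return np.clip(dot, 0.0, 1.0)


def power_decreasing(dot, c: float = 3.0):
    """Opacity (1 - |n.t|)^c: parallel segments fade, orthogonal stay opaque."""
    if c <= 0:
        raise ConfigurationError("exponent c must be > 0")
    return (1.0 - _check_dot(dot)) ** c


def power_increasing(dot, c: float = 3.0):
    """Opacity |n.t|^c: parallel segments stay opaque, orthogonal fade."""
    if c <= 0:
        raise ConfigurationError("exponent c must be > 0")
    return _check_dot(dot) ** c


def linear_theta(theta, a: float = 2.0 / np.pi, b: float = 0.0):
    """Piecewise-linear opacity ramp in the angle theta = acos|n.t|.

    alpha = a*theta + b on the ramp, clamped to 0 below theta = -b/a and to
    1 above theta = (1 - b)/a; opacity increases with the angle.
    """
    if a == 0:
        raise ConfigurationError("linear_theta slope a must be non-zero")
    theta = np.asarray(theta, dtype=float)
    return np.clip(a * theta + b, 0.0, 1.0)


def _evaluate(config: OpacityConfig, dot):
    if config.function == "power_decreasing":
        return power_decreasing(dot, config.c)
    if config.function == "power_increasing":
        return power_increasing(dot, config.c)
    theta = np.arccos(_check_dot(dot))
    return linear_theta(theta, config.a, config.b)


def assign_opacity(tractogram: Tractogram, config: OpacityConfig,
                   view_axis=None) -> Tractogram:
    """Attach an ``"alpha"`` per-point channel per the configured options.

    Local scale evaluates the opacity function on each point's local
    orientation; global scales compute one opacity per streamline (endpoint
    chord or scatter mean axis) and broadcast it.  When ``T_cl`` is set,
    streamlines with c_l below it get alpha = 1.  Streamlines whose global
    axis is undefined (closed loops in endpoint mode) also get alpha = 1.
    """
    if config.axis_mode == "view":
        if view_axis is None:
            raise ConfigurationError("axis_mode='view' requires view_axis")
        t = np.asarray(view_axis, dtype=float)
        t = t / np.linalg.norm(t)
    else:
        if view_axis is not None:
            raise ConfigurationError("view_axis is only accepted with axis_mode='view'")
        t = config.t

    alphas = []
    for s in tractogram.streamlines:
        if config.T_cl is not None and streamline_summary(s).c_l < config.T_cl:
            alphas.append(np.ones(len(s)))
            continue
        if config.scale == "local":
            dots = np.abs(local_orientations(s) @ t)
            alphas.append(np.asarray(_evaluate(config, dots), dtype=float))
            continue
        if config.scale == "global_endpoints":
            axis = endpoint_orientation(s)
        else:
            axis = streamline_summary(s).s1
        if axis is None:
            alphas.append(np.ones(len(s)))
            continue
        a = float(_evaluate(config, abs(float(axis @ t))))
        alphas.append(np.full(len(s), a))
    return tractogram.with_scalar("alpha", alphas)


def dot_histogram(tractogram: Tractogram, scale: str, t, nbins: int = 20):
    """Histogram of |n.t| over a tractogram's orientations.

    Local scale contributes every point's local orientation; global scales
    contribute one axis per streamline.  Returns ``(counts, bin_edges)``
    with ``nbins`` equal-width bins on [0, 1]; counts sum to the number of
    contributing orientations (closed loops contribute nothing in endpoint
    mode).
    """
    if scale not in _SCALES:
        raise ConfigurationError(f"unknown scale {scale!r}")
    if nbins < 1:
        raise ConfigurationError("nbins must be >= 1")
    if len(tractogram) == 0:
        raise EmptyInputError("cannot histogram an empty tractogram")
    t = np.asarray(t, dtype=float)
    t = t / np.linalg.norm(t)
    dots = []
    for s in tractogram.streamlines:
        if scale == "local":
            dots.append(np.abs(local_orientations(s) @ t))
        elif scale == "global_endpoints":
            axis = endpoint_orientation(s)
            if axis is not None:
                dots.append([abs(float(axis @ t))])
        else:
            dots.append([abs(float(streamline_summary(s).s1 @ t))])
    values = np.clip(np.concatenate([np.asarray(d) for d in dots]), 0.0, 1.0)
    counts, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    return counts, edges
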