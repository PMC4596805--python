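"""Streamline orientation statistics and tolerance-based compression.

A streamline is an ordered sequence of 3D points in millimeters.  Its local
orientation at each point is the normalized central difference of the
neighboring points (one-sided at the ends).  Two global summaries are
available: the normalized endpoint chord, and the first eigenvector of the
scatter matrix S = (1/N) sum_i n_i n_i^T — the latter is also the maximum
likelihood mean axis of a bipolar Watson distribution fitted to the local
orientation axes.  The eigenvalues of S yield the linear coefficient

    c_l = (beta1 - beta2) / (beta1 + beta2 + beta3),

which is 1 for a perfectly straight streamline and approaches 0 when the
segment orientations have no single dominant axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError

_UNIT_TOL = 1e-9


@dataclass
class ScatterSummary:
    """Per-streamline orientation summary.

    Attributes
    ----------
    S : (3, 3) array
        Scatter matrix of the local orientation axes; symmetric PSD with
        unit trace.
    betas : (3,) array
        Eigenvalues of ``S`` sorted descending; they sum to 1.
    s1 : (3,) array
        Unit first eigenvector, sign-fixed so its largest-magnitude
        component is positive.
    c_l : float
        Linear coefficient in [0, 1].
    n_endpoints : (3,) array or None
        Normalized endpoint chord; ``None`` for closed loops.
    """

    S: np.ndarray
    betas: np.ndarray
    s1: np.ndarray
    c_l: float
    n_endpoints: Optional[np.ndarray]


def _as_points(streamline) -> np.ndarray:
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("streamline must be an (N, 3) array with N >= 2")
    return pts


def local_orientations(streamline) -> np.ndarray:
    """Per-point unit orientation axes from neighbor differences.

    Interior points use the central difference (next minus previous point,
    normalized); the first and last points use the one-sided difference.
    Returns an (N, 3) array of unit vectors.

    Raises
    ------
    DegenerateGeometryError
        If a difference vector used by some branch has zero norm
        (coincident points).
    """
    pts = _as_points(streamline)
    diffs = np.empty_like(pts)
    diffs[0] = pts[1] - pts[0]
    diffs[-1] = pts[-1] - pts[-2]
    if len(pts) > 2:
        diffs[1:-1] = pts[2:] - pts[:-2]
    norms = np.linalg.norm(diffs, axis=1)
    bad = np.nonzero(norms < _UNIT_TOL)[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"zero-length orientation vector at point index {int(bad[0])} "
            "(coincident points)"
        )
    return diffs / norms[:, None]


def endpoint_orientation(streamline) -> Optional[np.ndarray]:
    """Normalized chord from the first to the last point.

    Returns ``None`` when the endpoints coincide (closed loop), since no
    chord direction is defined.
    """
    pts = _as_points(streamline)
    chord = pts[-1] - pts[0]
    norm = np.linalg.norm(chord)
    if norm < _UNIT_TOL:
        return None
    return chord / norm


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # axes are +/- equivalent; make the largest-magnitude component positive
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def scatter_summary(orientations, endpoint_axis=None) -> ScatterSummary:
    """Scatter matrix, eigenvalues, mean axis and linear coefficient.

    Parameters
    ----------
    orientations : (N, 3) array of unit axes
    endpoint_axis : (3,) array or None
        Carried through onto the summary for downstream consumers.
    """
    n = np.asarray(orientations, dtype=float)
    if n.ndim != 2 or n.shape[1] != 3 or len(n) == 0:
        raise ValueError("orientations must be a non-empty (N, 3) array")
    S = (n.T @ n) / len(n)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    betas = np.clip(evals[order], 0.0, None)
    # rank-deficient scatter (e.g. a perfectly straight streamline) yields
    # eigenvalues at solver noise level; snap those to exact zero so the
    # c_l = 1 straight-line limit holds exactly
    betas[betas < 1e-12 * betas[0]] = 0.0
    s1 = _fix_sign(evecs[:, order[0]])
    c_l = float((betas[0] - betas[1]) / betas.sum())
    return ScatterSummary(S=S, betas=betas, s1=s1, c_l=c_l,
                          n_endpoints=endpoint_axis)


def streamline_summary(streamline) -> ScatterSummary:
    """Convenience: scatter summary of a streamline's local orientations."""
    return scatter_summary(local_orientations(streamline),
                           endpoint_orientation(streamline))


def global_orientation(streamline, method: str = "scatter") -> Optional[np.ndarray]:
    """Global streamline axis by ``endpoints`` chord or ``scatter`` eigenvector.

    The endpoints method returns ``None`` on closed loops; the scatter
    method is always defined.
    """
    if method == "endpoints":
        return endpoint_orientation(streamline)
    if method == "scatter":
        return streamline_summary(streamline).s1
    raise ConfigurationError(f"unknown global orientation method {method!r}")


def _point_segment_distance(points, a, b):
    """Distances from ``points`` to the segment [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < _UNIT_TOL ** 2:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def compress_streamline(streamline, tolerance_mm: float = 0.01) -> np.ndarray:
    """Remove redundant points in near-linear regions.

    Greedy sequential scan: starting from the last kept point, the candidate
    span is extended while every spanned point lies within ``tolerance_mm``
    of the segment joining the kept point and the candidate; when extension
    fails the previous candidate is kept and scanning restarts there.  The
    first and last points are always kept, and every removed point lies
    within tolerance of the compressed polyline.
    """
    if tolerance_mm < 0:
        raise ConfigurationError("compression tolerance must be >= 0")
    pts = _as_points(streamline)
    n = len(pts)
    if n <= 2:
        return pts.copy()
    kept = [0]
    anchor = 0
    j = anchor + 2
    while j < n:
        inner = pts[anchor + 1:j]
        if np.all(_point_segment_distance(inner, pts[anchor], pts[j]) <= tolerance_mm):
            j += 1
        else:
            kept.append(j - 1)
            anchor = j - 1
            j = anchor + 2
    kept.append(n - 1)
    return pts[kept]


def polyline_max_deviation(original, compressed) -> float:
    """Max distance from any original point to the compressed polyline.

    Used to verify the compression guarantee (a Hausdorff-style one-sided
    check against the piecewise-linear compressed curve).
    """
    orig = _as_points(original)
    comp = _as_points(compressed)
    dmin = np.full(len(orig), np.inf)
    for a, b in zip(comp[:-1], comp[1:]):
        dmin = np.minimum(dmin, _point_segment_distance(orig, a, b))
    return float(dmin.max())
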