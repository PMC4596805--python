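import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20151007)


@pytest.fixture
def straight_streamline():
    """50 evenly spaced points on a line along +z."""
    z = np.linspace(-40.0, 40.0, 50)
    return np.column_stack([np.zeros_like(z), np.zeros_like(z), z])


def planar_arc(angle_deg, n_points, radius=30.0):
    """Circular arc in the xy-plane, sweep centered on the +y apex.

    A 180-degree arc runs from (r, 0, 0) to (-r, 0, 0) through (0, r, 0).
    """
    sweep = np.deg2rad(angle_deg)
    phi = np.linspace(np.pi / 2 - sweep / 2, np.pi / 2 + sweep / 2, n_points)
    return np.column_stack([
        radius * np.cos(phi), radius * np.sin(phi), np.zeros(n_points)
    ])


@pytest.fixture
def make_arc():
    return planar_arc


def random_wiggly_streamline(rng, n_points=80, step=1.0, smooth=5):
    """Random smooth polyline: smoothed random-walk steps, cumulatively summed."""
    steps = rng.standard_normal((n_points, 3))
    kernel = np.ones(smooth) / smooth
    for k in range(3):
        steps[:, k] = np.convolve(steps[:, k], kernel, mode="same")
    steps += np.array([0.2, 0.0, 1.0])  # drift so consecutive points never coincide
    return np.cumsum(step * steps, axis=0)
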