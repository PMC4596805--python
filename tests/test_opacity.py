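"""Opacity functions, the option matrix, and the dispersion gate."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tractalpha import (
    ConfigurationError,
    DomainError,
    EmptyInputError,
    OpacityConfig,
    Tractogram,
    assign_opacity,
    dot_histogram,
    linear_theta,
    power_decreasing,
    power_increasing,
)
from .conftest import planar_arc


class TestPowerFunctions:
    @pytest.mark.parametrize("dot, c, expected", [
        (0.0, 3.0, 1.0),    # orthogonal segment fully opaque
        (1.0, 3.0, 0.0),    # parallel segment fully transparent
        (0.5, 3.0, 0.125),
    ])
    def test_decreasing_values(self, dot, c, expected):
        assert power_decreasing(dot, c) == pytest.approx(expected)

    @pytest.mark.parametrize("dot, c, expected", [
        (1.0, 3.0, 1.0), (1.0, 7.0, 1.0),
        (0.0, 3.0, 0.0), (0.5, 1.0, 0.5),
    ])
    def test_increasing_values(self, dot, c, expected):
        assert power_increasing(dot, c) == pytest.approx(expected)

    def test_monotonicity_and_reflection_on_grid(self):
        x = np.linspace(0.0, 1.0, 10_000)
        for c in (0.5, 1.0, 3.0, 7.0):
            dec, inc = power_decreasing(x, c), power_increasing(x, c)
            assert np.all(dec >= 0) and np.all(dec <= 1)
            assert np.all(np.diff(dec) <= 0)
            assert np.all(np.diff(inc) >= 0)
            npt.assert_allclose(dec, power_increasing(1.0 - x, c), atol=1e-12)

    def test_steeper_exponent_lowers_interior_opacity(self):
        x = np.linspace(0.01, 0.99, 500)
        assert np.all(power_decreasing(x, 7.0) < power_decreasing(x, 3.0))

    @given(dot=st.floats(0.0, 1.0), c=st.floats(0.1, 20.0))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_range_and_reflection_property(self, dot, c):
        dec = power_decreasing(dot, c)
        assert 0.0 <= dec <= 1.0
        assert dec == pytest.approx(power_increasing(1.0 - dot, c), abs=1e-12)

    def test_out_of_domain_dot_raises(self):
        with pytest.raises(DomainError):
            power_decreasing(1.5, 3.0)
        with pytest.raises(DomainError):
            power_increasing(-0.2, 3.0)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ConfigurationError):
            power_decreasing(0.5, 0.0)


class TestLinearTheta:
    def test_default_ramp_endpoints(self):
        assert linear_theta(0.0) == 0.0
        assert linear_theta(np.pi / 2) == pytest.approx(1.0)

    def test_shifted_ramp_midpoint(self):
        assert linear_theta(np.pi / 4, a=4 / np.pi, b=-0.5) == pytest.approx(0.5)

    def test_clamp_branches(self):
        a, b = 4 / np.pi, -0.5
        assert linear_theta(0.05, a, b) == 0.0          # theta < -b/a
        assert linear_theta(np.pi / 2, a, b) == 1.0     # theta > (1-b)/a

    def test_zero_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            linear_theta(0.3, a=0.0)


def _mean_alphas(tractogram):
    return [float(np.mean(v)) for v in tractogram.scalars["alpha"]]


class TestAssignOpacity:
    @pytest.mark.parametrize("scale", ["local", "global_endpoints", "global_scatter"])
    @pytest.mark.parametrize("function, expected", [
        ("power_decreasing", 0.0), ("power_increasing", 1.0),
    ])
    def test_straight_streamline_parallel_to_axis(self, straight_streamline,
                                                  scale, function, expected):
        tg = Tractogram([straight_streamline])
        cfg = OpacityConfig(scale=scale, axis_mode="fixed", t=[0, 0, 1],
                            function=function, c=1.0)
        out = assign_opacity(tg, cfg)
        npt.assert_allclose(out.scalars["alpha"][0], expected, atol=1e-12)

    def test_global_scale_is_constant_per_streamline(self, make_arc):
        tg = Tractogram([make_arc(120.0, 60)])
        cfg = OpacityConfig(scale="global_scatter", axis_mode="fixed", t=[1, 0, 0])
        out = assign_opacity(tg, cfg)
        assert np.ptp(out.scalars["alpha"][0]) == 0.0

    def test_local_matches_global_on_straight(self, straight_streamline):
        tg = Tractogram([straight_streamline])
        t = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        a_local = assign_opacity(tg, OpacityConfig(
            scale="local", axis_mode="fixed", t=t)).scalars["alpha"][0]
        a_glob = assign_opacity(tg, OpacityConfig(
            scale="global_scatter", axis_mode="fixed", t=t)).scalars["alpha"][0]
        npt.assert_allclose(a_local, a_glob, atol=1e-12)

    def test_dispersion_gate_semicircle_opaque_straight_functional(
            self, straight_streamline, make_arc):
        tg = Tractogram([make_arc(180.0, 200), straight_streamline])
        cfg = OpacityConfig(scale="global_scatter", axis_mode="fixed",
                            t=[0, 0, 1], function="power_decreasing", c=3.0,
                            T_cl=0.29)
        out = assign_opacity(tg, cfg)
        npt.assert_allclose(out.scalars["alpha"][0], 1.0)  # gated: c_l ~ 0
        npt.assert_allclose(out.scalars["alpha"][1], 0.0, atol=1e-12)

    def test_closed_loop_endpoint_mode_falls_back_opaque(self):
        phi = np.linspace(0, 2 * np.pi, 100)
        loop = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        loop[-1] = loop[0, :]
        tg = Tractogram([loop])
        out = assign_opacity(tg, OpacityConfig(
            scale="global_endpoints", axis_mode="fixed", t=[0, 0, 1]))
        npt.assert_allclose(out.scalars["alpha"][0], 1.0)

    def test_reversal_invariance(self, rng, make_arc):
        arc = make_arc(135.0, 80)
        t = np.array([0.3, -0.5, 0.8])
        t /= np.linalg.norm(t)
        for scale in ("local", "global_endpoints", "global_scatter"):
            cfg = OpacityConfig(scale=scale, axis_mode="fixed", t=t)
            fwd = assign_opacity(Tractogram([arc]), cfg).scalars["alpha"][0]
            rev = assign_opacity(Tractogram([arc[::-1]]), cfg).scalars["alpha"][0]
            npt.assert_allclose(rev, fwd[::-1], atol=1e-9)

    def test_view_axis_mode_requires_axis(self, straight_streamline):
        cfg = OpacityConfig(scale="local", axis_mode="view")
        with pytest.raises(ConfigurationError):
            assign_opacity(Tractogram([straight_streamline]), cfg)

    def test_alpha_in_unit_interval_for_random_inputs(self, rng):
        from .conftest import random_wiggly_streamline
        tg = Tractogram([random_wiggly_streamline(rng) for _ in range(10)])
        for function in ("power_decreasing", "power_increasing", "linear_theta"):
            cfg = OpacityConfig(scale="local", axis_mode="fixed", t=[0, 1, 0],
                                function=function)
            out = assign_opacity(tg, cfg)
            for v in out.scalars["alpha"]:
                assert v.min() >= 0.0 and v.max() <= 1.0


class TestDotHistogram:
    def test_straight_along_axis_fills_top_bin(self, straight_streamline):
        counts, _ = dot_histogram(Tractogram([straight_streamline]),
                                  "local", [0, 0, 1], nbins=10)
        assert counts[-1] == 50 and counts[:-1].sum() == 0

    def test_single_bin_conserves_counts(self, make_arc):
        tg = Tractogram([make_arc(90.0, 30), make_arc(45.0, 20)])
        counts, _ = dot_histogram(tg, "local", [1, 0, 0], nbins=1)
        assert counts.sum() == 50

    def test_global_scale_counts_one_per_streamline(self, make_arc):
        tg = Tractogram([make_arc(90.0, 30), make_arc(45.0, 20)])
        counts, _ = dot_histogram(tg, "global_scatter", [1, 0, 0], nbins=4)
        assert counts.sum() == 2

    def test_uniform_axes_give_uniform_dots(self, rng):
        # Archimedes: |n.t| of uniform sphere axes is uniform on [0, 1]
        n = 100_000
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        starts = rng.uniform(-50, 50, (n, 3))
        tg = Tractogram([np.stack([p, p + 5.0 * d])
                         for p, d in zip(starts, dirs)])
        counts, _ = dot_histogram(tg, "global_endpoints", [0, 0, 1], nbins=20)
        assert counts.sum() == n
        _, p_value = stats.chisquare(counts)
        assert p_value > 0.01

    def test_empty_tractogram_rejected(self):
        with pytest.raises(EmptyInputError):
            dot_histogram(Tractogram([]), "local", [0, 0, 1], nbins=5)
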