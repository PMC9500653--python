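"""Mechanics stage: Flamant strip-load stress field and its reductions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from skinpain.mechanics import (
    CompressionLoad,
    PlanePoint,
    StressState,
    stress_axis_closed,
    stress_quadrature,
    surface_limit,
    transduction_stress,
)


def oracle_axis_quadrature(q, a, x):
    """Independent oracle: brute-force adaptive quadrature of the strip-load
    kernels on the axis at very tight tolerance."""
    sx = quad(lambda xi: x**3 / (x * x + xi * xi) ** 2, -a, a, epsabs=1e-13, epsrel=1e-12)[0]
    sy = quad(lambda xi: x * xi * xi / (x * x + xi * xi) ** 2, -a, a, epsabs=1e-13, epsrel=1e-12)[0]
    return (-2 * q / math.pi * sx, -2 * q / math.pi * sy)


def literal_axis_form(q, a, x):
    """The full rational-polynomial on-axis expressions, before algebraic
    simplification."""
    t = math.atan(a / x)
    pref = -q / (math.pi * (a * a + x * x) ** 2)
    sx = pref * (2 * t * a**4 + 4 * t * a**2 * x**2 + 2 * t * x**4 + 2 * a**3 * x + 2 * a * x**3)
    sy = pref * (2 * t * a**4 + 4 * t * a**2 * x**2 + 2 * t * x**4 - 2 * a**3 * x - 2 * a * x**3)
    return (sx, sy)


class TestOnAxisStress:
    def test_depth_equal_to_half_width_matches_analytic_value(self):
        # At x = a the arctangent is pi/4, giving sigma_x = -(q/pi)(pi/2 + 1).
        load = CompressionLoad(q=25.0, a=10.0)
        s = stress_axis_closed(load, 10.0)
        assert s.sigma_x == pytest.approx(-(25.0 / math.pi) * (math.pi / 2 + 1), rel=1e-12)
        assert s.sigma_y == pytest.approx(-(25.0 / math.pi) * (math.pi / 2 - 1), rel=1e-12)
        assert s.sigma_x == pytest.approx(-20.46, abs=0.005)
        assert s.sigma_y == pytest.approx(-4.54, abs=0.005)

    @pytest.mark.parametrize(
        "q,a,x,expect_sigma_x",
        [
            (25.0, 10.0, 50.0, -6.20),  # deep nociceptor, frozen from the quadrature oracle
            (25.0, 10.0, 1.6, -24.96),  # epidermis-depth nociceptor
        ],
    )
    def test_frozen_reference_points(self, q, a, x, expect_sigma_x):
        s = stress_axis_closed(CompressionLoad(q=q, a=a), x)
        assert s.sigma_x == pytest.approx(expect_sigma_x, abs=0.005)
        ox, _ = oracle_axis_quadrature(q, a, x)
        assert s.sigma_x == pytest.approx(ox, rel=1e-9)

    @pytest.mark.parametrize("x_over_a", [0.1, 0.16, 0.5, 1.0, 2.0, 5.0, 10.0])
    @pytest.mark.parametrize("q,a", [(25.0, 10.0), (7.3, 2.5)])
    def test_closed_form_equals_quadrature_and_literal_form(self, q, a, x_over_a):
        x = x_over_a * a
        load = CompressionLoad(q=q, a=a)
        closed = stress_axis_closed(load, x)
        # against the production quadrature path
        byquad = stress_quadrature(load, PlanePoint(x=x, y=0.0))
        assert closed.sigma_x == pytest.approx(byquad.sigma_x, rel=1e-6)
        assert closed.sigma_y == pytest.approx(byquad.sigma_y, rel=1e-6)
        assert abs(byquad.tau_xy) < 1e-10 * abs(byquad.sigma_x)
        # against the unsimplified printed expressions
        lit_x, lit_y = literal_axis_form(q, a, x)
        assert closed.sigma_x == pytest.approx(lit_x, rel=1e-12)
        assert closed.sigma_y == pytest.approx(lit_y, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        q=st.floats(1.0, 200.0),
        a=st.floats(0.5, 50.0),
        ratio=st.floats(0.05, 20.0),
    )
    def test_ordering_and_magnitude_properties(self, q, a, ratio):
        # On the axis both principal stresses are compressive, sigma_x is the
        # minor principal stress, and it dominates in magnitude.
        s = stress_axis_closed(CompressionLoad(q=q, a=a), ratio * a)
        assert s.sigma_x < s.sigma_y < 0
        assert abs(s.sigma_x) >= abs(s.sigma_y)
        assert s.tau_xy == 0.0

    def test_linearity_in_pressure_amplitude(self):
        a, x = 10.0, 3.0
        s1 = stress_axis_closed(CompressionLoad(q=10.0, a=a), x)
        s3 = stress_axis_closed(CompressionLoad(q=30.0, a=a), x)
        assert s3.sigma_x == pytest.approx(3.0 * s1.sigma_x, rel=1e-12)
        assert s3.sigma_y == pytest.approx(3.0 * s1.sigma_y, rel=1e-12)

    def test_stress_magnitude_decays_monotonically_with_depth(self):
        load = CompressionLoad(q=25.0, a=10.0)
        depths = np.geomspace(0.1, 200.0, 40)
        mags = [abs(stress_axis_closed(load, x).sigma_x) for x in depths]
        assert all(m1 > m2 for m1, m2 in zip(mags, mags[1:]))

    def test_far_field_decay_to_zero(self):
        s = stress_axis_closed(CompressionLoad(q=25.0, a=10.0), 1e5)
        assert abs(s.sigma_x) < 1e-2 and abs(s.sigma_y) < 1e-4


class TestOffAxisQuadrature:
    def test_lateral_symmetry(self):
        load = CompressionLoad(q=25.0, a=10.0)
        sp = stress_quadrature(load, PlanePoint(x=10.0, y=5.0))
        sm = stress_quadrature(load, PlanePoint(x=10.0, y=-5.0))
        assert sp.sigma_x == pytest.approx(sm.sigma_x, rel=1e-10)
        assert sp.sigma_y == pytest.approx(sm.sigma_y, rel=1e-10)
        assert sp.tau_xy == pytest.approx(-sm.tau_xy, rel=1e-8)

    def test_surface_evaluation_rejected(self):
        with pytest.raises(ValueError, match="surface_limit"):
            stress_quadrature(CompressionLoad(q=25.0, a=10.0), PlanePoint(x=0.0, y=0.0))

    def test_off_axis_against_tight_oracle(self):
        q, a, x, y = 25.0, 10.0, 4.0, 7.0
        s = stress_quadrature(CompressionLoad(q=q, a=a), PlanePoint(x=x, y=y))
        ox = quad(lambda xi: x**3 / (x**2 + (y - xi) ** 2) ** 2, -a, a,
                  epsabs=1e-13, epsrel=1e-12)[0]
        assert s.sigma_x == pytest.approx(-2 * q / math.pi * ox, rel=1e-8)


class TestSurfaceLimit:
    def test_inside_strip_carries_applied_traction(self):
        s = surface_limit(CompressionLoad(q=20.0, a=10.0), 0.0)
        assert s == StressState(sigma_x=-20.0, sigma_y=-20.0, tau_xy=0.0)

    def test_outside_strip_traction_free(self):
        s = surface_limit(CompressionLoad(q=20.0, a=10.0), 30.0)
        assert s == StressState(0.0, 0.0, 0.0)

    def test_strip_edge_is_singular(self):
        with pytest.raises(ValueError, match="singular"):
            surface_limit(CompressionLoad(q=20.0, a=10.0), 10.0)

    def test_limit_consistent_with_shallow_quadrature(self):
        load = CompressionLoad(q=20.0, a=10.0)
        s = stress_quadrature(load, PlanePoint(x=1e-4, y=0.0))
        assert s.sigma_x == pytest.approx(-20.0, rel=1e-4)
        assert s.sigma_y == pytest.approx(-20.0, rel=1e-2)


class TestTransductionStress:
    @pytest.mark.parametrize(
        "sigma_x,expected",
        [(-20.46, 20.46), (0.0, 0.0), (-24.96, 24.96)],
    )
    def test_returns_minor_principal_stress_magnitude(self, sigma_x, expected):
        assert transduction_stress(StressState(sigma_x, sigma_x / 3, 0.0)) == expected


class TestValidation:
    @pytest.mark.parametrize("q,a", [(-1.0, 10.0), (0.0, 10.0), (25.0, 0.0), (math.nan, 10.0)])
    def test_invalid_load_rejected(self, q, a):
        with pytest.raises(ValueError):
            CompressionLoad(q=q, a=a)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            stress_axis_closed(CompressionLoad(q=25.0, a=10.0), -1.0)
        with pytest.raises(ValueError):
            PlanePoint(x=-1.0, y=0.0)
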