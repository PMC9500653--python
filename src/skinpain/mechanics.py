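"""Elastic stress in skin under a uniform strip compression.

The skin is idealised as a two-dimensional semi-infinite elastic solid
(plane strain) loaded on its surface by a uniform pressure of amplitude
``q`` over a strip of width ``2a``.  The stress field follows from the
classical Flamant half-plane solution by superposing line loads over the
strip.  Coordinate convention (fixed throughout the package): ``x`` is the
depth below the surface (positive downward), ``y`` is the lateral offset
along the surface, and the load is centred at ``y = 0``.

Units are millimetres for lengths and kilopascals for stresses; no internal
unit conversion is performed anywhere.

The component that drives mechanotransduction downstream is the minor
principal stress ``sigma_x`` (the largest-magnitude compressive component
on the load axis); :func:`transduction_stress` reduces a stress state to
that scalar magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "CompressionLoad",
    "PlanePoint",
    "StressState",
    "stress_quadrature",
    "stress_axis_closed",
    "surface_limit",
    "transduction_stress",
]

# Quadrature tolerances: the kernels are smooth for x > 0, so any adaptive
# rule converges; these sit far below the sensitivity of the neural model.
_QUAD_EPSABS = 1e-10
_QUAD_EPSREL = 1e-8


@dataclass(frozen=True)
class CompressionLoad:
    """Uniform strip pressure on the skin surface.

    Parameters
    ----------
    q : float
        Pressure amplitude, kPa.  Must be positive (compression).
    a : float
        Load half-width, mm; the strip spans ``y in [-a, a]``.
    """

    q: float
    a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q) and self.q > 0):
            raise ValueError(f"pressure amplitude q must be finite and > 0, got {self.q}")
        if not (math.isfinite(self.a) and self.a > 0):
            raise ValueError(f"load half-width a must be finite and > 0, got {self.a}")


@dataclass(frozen=True)
class PlanePoint:
    """Location of a nociceptor in the half-plane.

    ``x`` is depth below the surface (mm, >= 0, increasing downward);
    ``y`` is lateral offset from the load centre (mm).
    """

    x: float
    y: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and self.x >= 0):
            raise ValueError(f"depth x must be finite and >= 0, got {self.x}")
        if not math.isfinite(self.y):
            raise ValueError(f"lateral offset y must be finite, got {self.y}")


@dataclass(frozen=True)
class StressState:
    """Plane-strain stress components at a point (kPa).

    On the load axis (y = 0, x > 0) the shear vanishes, so ``sigma_x`` and
    ``sigma_y`` are the principal stresses and obey
    ``sigma_x < sigma_y < 0`` under compression.
    """

    sigma_x: float
    sigma_y: float
    tau_xy: float


def _check_finite(**vals: float) -> None:
    for name, v in vals.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")


def stress_quadrature(load: CompressionLoad, point: PlanePoint) -> StressState:
    """Stress at an interior point by adaptive quadrature of the Flamant kernels.

    Integrates the line-load influence functions over the loaded strip
    ``xi in [-a, a]`` with uniform pressure ``q``.  Valid for any lateral
    offset; requires ``point.x > 0`` because the kernels are singular on
    the surface (use :func:`surface_limit` for x = 0).
    """
    _check_finite(q=load.q, a=load.a, x=point.x, y=point.y)
    x, y = point.x, point.y
    if x == 0.0:
        raise ValueError(
            "stress_quadrature is singular at the surface (x = 0); "
            "use surface_limit for surface points"
        )
    q, a = load.q, load.a
    pref = -2.0 * q / math.pi

    def denom(xi: float) -> float:
        return (x * x + (y - xi) ** 2) ** 2

    kx = lambda xi: x**3 / denom(xi)
    ky = lambda xi: x * (y - xi) ** 2 / denom(xi)
    kxy = lambda xi: x**2 * (y - xi) / denom(xi)

    opts = dict(epsabs=_QUAD_EPSABS, epsrel=_QUAD_EPSREL, limit=200)
    # The kernels peak near xi = y; pointing the adaptive rule at it helps
    # when the point sits shallow under the strip edge.
    points = [y] if -a < y < a else None
    sx = quad(kx, -a, a, points=points, **opts)[0]
    sy = quad(ky, -a, a, points=points, **opts)[0]
    sxy = quad(kxy, -a, a, points=points, **opts)[0]
    return StressState(sigma_x=pref * sx, sigma_y=pref * sy, tau_xy=pref * sxy)


def stress_axis_closed(load: CompressionLoad, depth: float) -> StressState:
    """Closed-form on-axis stresses under the centre of the strip (y = 0).

    Evaluates the exact integrals of the Flamant kernels on the load axis::

        sigma_x = -(q/pi) [2 arctan(a/x) + 2 a x / (a^2 + x^2)]
        sigma_y = -(q/pi) [2 arctan(a/x) - 2 a x / (a^2 + x^2)]
        tau_xy  = 0

    which is the algebraic simplification of the full rational-polynomial
    form (the two are verified equal in the test suite).
    """
    _check_finite(q=load.q, a=load.a, depth=depth)
    if depth <= 0:
        raise ValueError(f"depth must be > 0 (got {depth}); use surface_limit at the surface")
    q, a, x = load.q, load.a, depth
    t = math.atan2(a, x)
    r = a * x / (a * a + x * x)
    return StressState(
        sigma_x=-(q / math.pi) * (2.0 * t + 2.0 * r),
        sigma_y=-(q / math.pi) * (2.0 * t - 2.0 * r),
        tau_xy=0.0,
    )


def surface_limit(load: CompressionLoad, lateral: float) -> StressState:
    """Analytic x -> 0+ limit of the stress field on the surface.

    Strictly inside the loaded strip the surface carries the full applied
    traction (sigma_x = sigma_y = -q, tau_xy = 0); strictly outside, the
    surface is traction-free and all components vanish.  At the strip edge
    |lateral| = a the field is singular and no value is returned.
    """
    _check_finite(q=load.q, a=load.a, lateral=lateral)
    if abs(lateral) == load.a:
        raise ValueError(
            f"surface stress is singular at the strip edge |y| = a = {load.a}"
        )
    if abs(lateral) < load.a:
        return StressState(sigma_x=-load.q, sigma_y=-load.q, tau_xy=0.0)
    return StressState(sigma_x=0.0, sigma_y=0.0, tau_xy=0.0)


def transduction_stress(state: StressState) -> float:
    """Scalar stress magnitude driving the mechanosensitive current.

    The minor principal stress sigma_x has the largest magnitude on the
    load axis, so its absolute value is the stress fed to the nociceptor
    membrane model.  Returns a nonnegative value in kPa.
    """
    return abs(state.sigma_x)


def stress_grid(load: CompressionLoad, depths: np.ndarray, laterals: np.ndarray):
    """Tabulate the stress field on a (depth, lateral) grid.

    Returns a pandas DataFrame with columns
    q_kPa, a_mm, x_mm, y_mm, sigma_x_kPa, sigma_y_kPa, tau_xy_kPa.
    On-axis points use the closed form; off-axis points use quadrature.
    """
    import pandas as pd

    rows = []
    for x in np.asarray(depths, dtype=float):
        for y in np.asarray(laterals, dtype=float):
            if x == 0.0:
                s = surface_limit(load, y)
            elif y == 0.0:
                s = stress_axis_closed(load, x)
            else:
                s = stress_quadrature(load, PlanePoint(x=x, y=y))
            rows.append(
                dict(
                    q_kPa=load.q,
                    a_mm=load.a,
                    x_mm=float(x),
                    y_mm=float(y),
                    sigma_x_kPa=s.sigma_x,
                    sigma_y_kPa=s.sigma_y,
                    tau_xy_kPa=s.tau_xy,
                )
            )
    return pd.DataFrame(rows)
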