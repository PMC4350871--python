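"""Pump characteristic: the periodic integrals I1, I2, the linear
pressure-rise / flow-rate relation, and its threshold fluxes.

Integrating ``dp/dz = (h^2 w(h) - q)/D`` over one wavelength gives the
pressure rise per wavelength

    ``delta_p = I1 - q I2``,
    ``I1 = int_0^1 h^2 w(h) / D dz``,   ``I2 = int_0^1 1 / D dz``,

with the constant wave-frame flux ``q = Qbar - 1 - eps^2/2``.  The
integrands are smooth and periodic, so the composite trapezoid rule
converges spectrally; resolution is doubled from 256 points until two
successive refinements agree to the requested tolerance.

Thresholds read off the characteristic:

* free-pumping flux — the ``delta_p = 0`` intercept;
* favorable-gradient threshold — the smallest ``Qbar`` above which
  ``dp/dz <= 0`` at every station (the numerator ``h^2 w(h) - q`` becomes
  uniformly nonpositive);
* epsilon-crossing flux — the ``Qbar`` at which the characteristics of
  two cilia-length values intersect (longer cilia raise ``|delta_p|``
  below it and lower it above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .casson import casson_resistance
from .errors import DegeneratePairError, QuadratureError
from .geometry import boundary_axial_velocity, tube_radius
from .params import CiliaParams, PumpState, gamma_factor

__all__ = [
    "PumpingIntegrals",
    "pumping_integrals",
    "pressure_rise",
    "mean_flow_rate",
    "free_pumping_flux",
    "favorable_gradient_threshold",
    "favorable_gradient_threshold_scan",
    "epsilon_crossing_flux",
    "epsilon_crossing_flux_bisect",
    "pump_curve",
]


@dataclass(frozen=True)
class PumpingIntegrals:
    """Converged quadrature values of I1 and I2 over one wavelength."""

    i1: float
    i2: float
    n_points: int
    est_error: float


def _integrands(z, p: CiliaParams):
    h = tube_radius(z, p)
    w_wall = boundary_axial_velocity(z, p)
    d = casson_resistance(h, p.hp)
    return h * h * w_wall / d, 1.0 / d


def pumping_integrals(p: CiliaParams, *, tol: float = 1e-10,
                      n_start: int = 256, n_max: int = 16384) -> PumpingIntegrals:
    """Evaluate I1 and I2 by periodic trapezoid quadrature with doubling.

    For a periodic analytic integrand the trapezoid rule on equispaced
    nodes is spectrally accurate, so convergence is reached within a few
    doublings for any valid parameter set.

    Raises
    ------
    QuadratureError
        If successive refinements still differ by more than ``tol`` at
        ``n_max`` points.
    """
    n = n_start
    prev = None
    while n <= n_max:
        z = np.arange(n) / n  # periodic: mean of samples == trapezoid
        f1, f2 = _integrands(z, p)
        i1, i2 = float(np.mean(f1)), float(np.mean(f2))
        if prev is not None:
            err = max(abs(i1 - prev[0]), abs(i2 - prev[1]))
            if err < tol:
                return PumpingIntegrals(i1=i1, i2=i2, n_points=n, est_error=err)
        prev = (i1, i2)
        n *= 2
    raise QuadratureError(
        f"I1/I2 quadrature did not converge to {tol} at {n_max} points"
    )


def pressure_rise(qbar: float, p: CiliaParams,
                  ints: PumpingIntegrals | None = None) -> float:
    """Pressure rise per wavelength ``delta_p = I1 - (Qbar - 1 - eps^2/2) I2``.

    Exactly affine in ``Qbar`` with slope ``-I2 < 0``.
    """
    if ints is None:
        ints = pumping_integrals(p)
    return ints.i1 - (qbar - gamma_factor(p.epsilon)) * ints.i2


def mean_flow_rate(delta_p: float, p: CiliaParams,
                   ints: PumpingIntegrals | None = None) -> float:
    """Time-mean flow rate ``Qbar = 1 + eps^2/2 + I1/I2 - delta_p/I2``
    (exact inverse of :func:`pressure_rise`)."""
    if ints is None:
        ints = pumping_integrals(p)
    return gamma_factor(p.epsilon) + ints.i1 / ints.i2 - delta_p / ints.i2


def free_pumping_flux(p: CiliaParams,
                      ints: PumpingIntegrals | None = None) -> float:
    """Mean flow rate delivered at zero pressure rise:
    ``Qbar0 = 1 + eps^2/2 + I1/I2``."""
    if ints is None:
        ints = pumping_integrals(p)
    return gamma_factor(p.epsilon) + ints.i1 / ints.i2


def _wall_momentum_max(p: CiliaParams) -> float:
    """Closed-form ``max_z h^2 w(h)``.

    ``h^2 w(h) = -(1 + eps c)^2 (1 + k c)`` with ``c = cos(2 pi z)`` and
    ``k = 2 pi eps alpha beta`` is a cubic in ``c``; the maximum over
    ``c in [-1, 1]`` is attained at an endpoint or at the interior
    stationary point ``c = -(2 eps + k)/(3 eps k)``.
    """
    e = p.epsilon
    k = 2.0 * np.pi * e * p.alpha * p.beta

    def g(c):
        return -((1.0 + e * c) ** 2) * (1.0 + k * c)

    candidates = [-1.0, 1.0]
    if e > 0 and k > 0:
        c_star = -(2.0 * e + k) / (3.0 * e * k)
        if -1.0 < c_star < 1.0:
            candidates.append(c_star)
    return max(g(c) for c in candidates)


def favorable_gradient_threshold(p: CiliaParams) -> float:
    """Smallest ``Qbar`` with ``dp/dz <= 0`` at every station (closed form).

    ``dp/dz = (h^2 w(h) - q)/D`` with ``D > 0``, so the gradient is
    uniformly favorable once ``q >= max_z h^2 w(h)``; the threshold is
    ``Qbar* = 1 + eps^2/2 + max_z h^2 w(h)``.
    """
    return gamma_factor(p.epsilon) + _wall_momentum_max(p)


def favorable_gradient_threshold_scan(p: CiliaParams, n: int = 200001) -> float:
    """Definitional version of :func:`favorable_gradient_threshold` by a
    dense scan of ``h^2 w(h)`` over one period (test oracle)."""
    z = np.arange(n) / n
    h = tube_radius(z, p)
    return gamma_factor(p.epsilon) + float(np.max(h * h * boundary_axial_velocity(z, p)))


def _crossing_inputs(p_base: CiliaParams, eps_pair):
    e1, e2 = eps_pair
    if e1 == e2:
        raise DegeneratePairError("epsilon pair must contain two distinct values")
    p1 = p_base.replace(epsilon=float(e1))
    p2 = p_base.replace(epsilon=float(e2))
    return p1, p2, pumping_integrals(p1), pumping_integrals(p2)


def epsilon_crossing_flux(p_base: CiliaParams, eps_pair) -> float:
    """``Qbar`` at which the pump characteristics of two cilia lengths cross.

    Setting ``delta_p(Qbar; eps1) = delta_p(Qbar; eps2)`` and solving the
    affine equality gives

    ``Qbar_x = [I1(e1) - I1(e2) + I2(e1) g(e1) - I2(e2) g(e2)]
               / [I2(e1) - I2(e2)]``,  ``g(e) = 1 + e^2/2``.
    """
    p1, p2, a, b = _crossing_inputs(p_base, eps_pair)
    denom = a.i2 - b.i2
    if abs(denom) < 1e-12:
        raise DegeneratePairError("I2 values coincide; characteristics are parallel")
    return (a.i1 - b.i1 + a.i2 * gamma_factor(p1.epsilon)
            - b.i2 * gamma_factor(p2.epsilon)) / denom


def epsilon_crossing_flux_bisect(p_base: CiliaParams, eps_pair, *,
                                 bracket=(-5.0, 5.0), xtol: float = 1e-9) -> float:
    """Root-finding cross-check of :func:`epsilon_crossing_flux`:
    bisection on ``delta_p(Q; eps1) - delta_p(Q; eps2)`` with bracket
    expansion."""
    p1, p2, a, b = _crossing_inputs(p_base, eps_pair)

    def f(qbar):
        return pressure_rise(qbar, p1, a) - pressure_rise(qbar, p2, b)

    lo, hi = bracket
    for _ in range(60):
        if f(lo) * f(hi) <= 0:
            break
        lo, hi = 2 * lo, 2 * hi
    else:
        raise DegeneratePairError("could not bracket a crossing point")
    return float(brentq(f, lo, hi, xtol=xtol))


def pump_curve(p: CiliaParams, qbar_values) -> "pandas.DataFrame":
    """Tabulate the linear characteristic ``delta_p(Qbar)`` at the given
    flow rates, with full parameter provenance columns."""
    import pandas as pd

    ints = pumping_integrals(p)
    rows = [
        {
            "eps": p.epsilon, "alpha": p.alpha, "beta": p.beta, "hp": p.hp,
            "qbar": float(qb), "delta_p": pressure_rise(float(qb), p, ints),
            "i1": ints.i1, "i2": ints.i2,
        }
        for qb in qbar_values
    ]
    return pd.DataFrame(rows, columns=[
        "eps", "alpha", "beta", "hp", "qbar", "delta_p", "i1", "i2",
    ])
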