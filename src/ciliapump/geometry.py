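"""Tube-wall envelope geometry and cilia-tip kinematics.

The beating cilia tips are modelled by the envelope approach: the tips
trace elliptical paths whose outer envelope forms a continuous waving
surface.  In the frame moving with the metachronal wave the surface is
the stationary wall ``h(z) = 1 + epsilon*cos(2*pi*z)``, with ``z``
measured in wavelengths and periodic on [0, 1).

Two levels of kinematics coexist here:

* the exact (unapproximated) tip velocities of the elliptical paths,
  exposed dimensionally by :func:`cilia_tip_velocity` for illustration;
* their long-wavelength leading order, :func:`boundary_axial_velocity`
  and :func:`boundary_radial_velocity`, which are the no-slip boundary
  conditions actually used by the flow solution.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterDomainError, SingularKinematicsError
from .params import CiliaParams

__all__ = [
    "tube_radius",
    "envelope_position",
    "cilia_tip_velocity",
    "boundary_axial_velocity",
    "boundary_radial_velocity",
]

TWO_PI = 2.0 * np.pi


def tube_radius(z, p: CiliaParams):
    """Dimensionless wave-frame wall radius ``h(z) = 1 + eps*cos(2 pi z)``.

    Periodic with period 1; ``1 - eps <= h <= 1 + eps``.
    """
    return 1.0 + p.epsilon * np.cos(TWO_PI * np.asarray(z, dtype=float))


def envelope_position(z_star, t_star, a: float, lambda_w: float, c: float,
                      p: CiliaParams):
    """Dimensional envelope radius ``R* = a(1 + eps*cos[(2pi/lam)(Z*-ct*)])``.

    ``a`` is the mean tube radius, ``lambda_w`` the metachronal wavelength
    and ``c`` the wave speed, all in consistent units.
    """
    if a <= 0 or lambda_w <= 0:
        raise ParameterDomainError("a and lambda_w must be positive")
    phase = (TWO_PI / lambda_w) * (np.asarray(z_star, dtype=float) - c * t_star)
    return a * (1.0 + p.epsilon * np.cos(phase))


def cilia_tip_velocity(z_star, t_star, a: float, lambda_w: float, c: float,
                       p: CiliaParams):
    """Exact dimensional tip velocities ``(W*, U*)`` of the elliptical paths.

    The tips move on ellipses; eliminating the reference position gives

    ``W* = -k eps alpha a c cos(phi) / (1 - k eps alpha a cos(phi))``,
    ``U* =  k eps a c sin(phi) / (1 - k eps alpha a cos(phi))``,

    with ``k = 2 pi / lambda_w`` and ``phi = k (Z* - c t*)``.  These are
    kinematic (no lubrication approximation); the flow solver uses their
    long-wavelength limit instead.

    Raises
    ------
    SingularKinematicsError
        If the denominator vanishes anywhere on the requested phase set
        (the envelope model cannot represent such steep tip paths).
    """
    if a <= 0 or lambda_w <= 0:
        raise ParameterDomainError("a and lambda_w must be positive")
    k = TWO_PI / lambda_w
    phase = k * (np.asarray(z_star, dtype=float) - c * t_star)
    cos_p, sin_p = np.cos(phase), np.sin(phase)
    denom = 1.0 - k * p.epsilon * p.alpha * a * cos_p
    if np.any(np.abs(denom) < 1e-12):
        raise SingularKinematicsError(
            "cilia-tip velocity denominator vanishes: 2*pi*eps*alpha*a/lambda = "
            f"{k * p.epsilon * p.alpha * a}"
        )
    w_tip = -k * p.epsilon * p.alpha * a * c * cos_p / denom
    u_tip = k * p.epsilon * a * c * sin_p / denom
    return w_tip, u_tip


def boundary_axial_velocity(z, p: CiliaParams):
    """Wave-frame axial wall velocity ``w(h) = -1 - 2 pi eps alpha beta cos(2 pi z)``.

    Leading lubrication order of the no-slip condition on the cilia-tip
    envelope.  The constant -1 is the wave-frame translation of the wall;
    the cosine term is the axial sweep of the elliptical tip motion.
    """
    return -1.0 - TWO_PI * p.epsilon * p.alpha * p.beta * np.cos(
        TWO_PI * np.asarray(z, dtype=float)
    )


def boundary_radial_velocity(z, p: CiliaParams):
    """Radial wall velocity, leading lubrication order.

    ``u(h) = 2 pi eps sin(2 pi z) + alpha beta (2 pi eps)^2 sin(2 pi z) cos(2 pi z)``

    This is the O(beta) expansion of the exact tip kinematics and equals
    ``w(h) * dh/dz`` exactly: the stationary wave-frame wall is a
    streamline, as mass conservation requires.
    """
    zz = TWO_PI * np.asarray(z, dtype=float)
    s, c = np.sin(zz), np.cos(zz)
    e = p.epsilon
    return TWO_PI * e * s + p.alpha * p.beta * (TWO_PI * e) ** 2 * s * c
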