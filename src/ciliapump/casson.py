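"""Casson constitutive core: plug radius, velocity profile, flux, and the
pressure-gradient inversion.

The Casson law reads ``sqrt(tau) = sqrt(tau0) + sqrt(mu * gamma_dot)`` for
``tau >= tau0`` and ``gamma_dot = 0`` below yield.  Under the lubrication
(long-wavelength, low-Reynolds) reduction the shear stress in the tube is
linear in radius, ``tau(r) = (r/2) dp/dz``, so the fluid moves as a rigid
plug inside the yield surface ``r = Hp = 2 tau0 / |dp/dz|`` and shears as
a Casson fluid outside it.

Everything here is algebraically closed-form.  The central object is the
flux-resistance denominator

    ``D(h, Hp) = h^3 [ (3h + 4 Hp)/24 - (2/7) sqrt(h Hp) ] - Hp^4 / 168``,

identically equal to the classical Casson-Poiseuille bracket
``(h^4 / 8) F(m)`` with ``m = Hp/h`` and
``F(m) = 1 - (16/7) m^{1/2} + (4/3) m - (1/21) m^4``, which gives the
wave-frame flux ``q = h^2 w(h) - D(h, Hp) dp/dz`` and its inversion
``dp/dz = (h^2 w(h) - q) / D``.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    ParameterDomainError,
    PlugExceedsTubeError,
    UnboundedPlugError,
)
from .geometry import boundary_axial_velocity, tube_radius
from .params import CiliaParams

__all__ = [
    "plug_radius_from_yield",
    "yield_stress_from_plug",
    "casson_bracket",
    "casson_resistance",
    "shear_stress",
    "pressure_gradient",
    "axial_velocity",
    "plug_velocity",
    "flux",
]


def plug_radius_from_yield(tau0: float, dpdz: float) -> float:
    """Plug radius ``Hp = 2 tau0 / |dp/dz|`` from the dimensionless yield stress.

    Pointwise utility: the pump solver treats ``Hp`` as a constant input
    parameter, so this conversion is not fed back into the flow solution.
    The magnitude of the gradient is used; a signed plug radius has no
    meaning.
    """
    if tau0 < 0:
        raise ParameterDomainError(f"yield stress tau0 must be >= 0, got {tau0}")
    if dpdz == 0.0:
        if tau0 == 0.0:
            return 0.0
        raise UnboundedPlugError(
            "dp/dz = 0 with tau0 > 0: the unyielded plug fills the whole tube"
        )
    return 2.0 * tau0 / abs(dpdz)


def yield_stress_from_plug(hp: float, dpdz: float) -> float:
    """Inverse of :func:`plug_radius_from_yield`: ``tau0 = Hp |dp/dz| / 2``."""
    if hp < 0:
        raise ParameterDomainError(f"hp must be >= 0, got {hp}")
    return 0.5 * hp * abs(dpdz)


def casson_bracket(m):
    """Classical Casson-Poiseuille bracket ``F(m) = 1 - (16/7) m^{1/2} + (4/3) m - m^4/21``.

    ``m = Hp/h`` is the plug fraction; ``F(0) = 1`` recovers Poiseuille.
    """
    m = np.asarray(m, dtype=float)
    return 1.0 - (16.0 / 7.0) * np.sqrt(m) + (4.0 / 3.0) * m - m**4 / 21.0


def casson_resistance(h, hp):
    """Flux-resistance denominator ``D(h, Hp)``; equals ``h^4/8`` for ``Hp = 0``.

    The ``-Hp^4/168`` term sits outside the ``h^3`` bracket; only that
    grouping makes ``D`` identical to ``(h^4/8) F(Hp/h)``.
    """
    h = np.asarray(h, dtype=float)
    hp = np.asarray(hp, dtype=float)
    if np.any(hp < 0):
        raise ParameterDomainError("plug radius hp must be >= 0")
    if np.any(hp >= h):
        raise PlugExceedsTubeError(
            "plug radius hp must be smaller than the tube radius h everywhere"
        )
    out = h**3 * ((3.0 * h + 4.0 * hp) / 24.0 - (2.0 / 7.0) * np.sqrt(h * hp)) \
        - hp**4 / 168.0
    return out if out.ndim else float(out)


def shear_stress(r, dpdz):
    """Wave-frame shear stress ``tau(r) = (r/2) dp/dz`` (regular on the axis)."""
    return 0.5 * np.asarray(r, dtype=float) * dpdz


def pressure_gradient(z, q: float, p: CiliaParams):
    """Axial pressure gradient from the constant wave-frame flux.

    ``dp/dz = (h^2 w(h) - q) / D(h, Hp)`` with ``h`` and ``w(h)`` evaluated
    at the station ``z``.  Vectorized over ``z``.
    """
    if not np.isfinite(q):
        raise ParameterDomainError(f"flux q must be finite, got {q}")
    h = tube_radius(z, p)
    w_wall = boundary_axial_velocity(z, p)
    return (h * h * w_wall - q) / casson_resistance(h, p.hp)


def _shear_profile_term(r, h, hp):
    """The bracket multiplying ``dp/dz / 4`` in the sheared-region profile:
    ``(r - h)(r + h + 2 Hp) - (8/3) sqrt(Hp) (r^{3/2} - h^{3/2})``."""
    return (r - h) * (r + h + 2.0 * hp) \
        - (8.0 / 3.0) * np.sqrt(hp) * (r**1.5 - h**1.5)


def plug_velocity(z, dpdz, p: CiliaParams):
    """Uniform axial velocity of the unyielded core ``r <= Hp`` at station ``z``."""
    h = tube_radius(z, p)
    if np.any(p.hp >= h):
        raise PlugExceedsTubeError("plug radius exceeds tube radius at this z")
    w_wall = boundary_axial_velocity(z, p)
    return w_wall + 0.25 * np.asarray(dpdz, dtype=float) \
        * _shear_profile_term(p.hp, h, p.hp)


def axial_velocity(r, z, dpdz, p: CiliaParams):
    """Wave-frame axial velocity ``w(r, z)`` of the piecewise Casson profile.

    For ``r >= Hp``:
    ``w = w(h) + (dp/dz / 4) [ (r-h)(r+h+2Hp) - (8/3) sqrt(Hp)(r^{3/2}-h^{3/2}) ]``;
    for ``r < Hp`` the plug value.  Continuous with zero slope at the
    yield surface, and ``w(h) = w(h)`` exactly (no slip).  The lab-frame
    velocity is ``w + 1``.
    """
    r = np.asarray(r, dtype=float)
    h = tube_radius(z, p)
    if np.any(r < 0) or np.any(r > h + 1e-12):
        raise ParameterDomainError("r must lie in [0, h(z)]")
    w_wall = boundary_axial_velocity(z, p)
    dpdz = np.asarray(dpdz, dtype=float)
    r_eff = np.maximum(r, p.hp)  # plug value for r < Hp
    w = w_wall + 0.25 * dpdz * _shear_profile_term(r_eff, h, p.hp)
    return w if w.ndim else float(w)


def flux(z, dpdz, p: CiliaParams):
    """Wave-frame flux ``q = 2 int_0^h r w dr = h^2 w(h) - D(h, Hp) dp/dz``."""
    h = tube_radius(z, p)
    w_wall = boundary_axial_velocity(z, p)
    return h * h * w_wall - casson_resistance(h, p.hp) * np.asarray(dpdz, dtype=float)
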