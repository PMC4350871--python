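"""Core parameter records for the ciliated-tube Casson pump model.

The model is fully nondimensional: lengths are scaled by the mean tube
radius ``a`` (radial) or the metachronal wavelength ``lambda`` (axial),
velocities by the wave speed ``c``.  Four dimensionless groups control
everything:

``epsilon``
    Cilia-length parameter: amplitude of the envelope of the beating
    cilia tips relative to the mean radius.  The stationary wave-frame
    wall is ``h(z) = 1 + epsilon*cos(2*pi*z)``.
``alpha``
    Eccentricity of the elliptical path traced by a cilium tip; ``alpha = 0``
    means purely radial tip motion.
``beta``
    Wavenumber ``a/lambda``.  The lubrication solution is the leading
    order in ``beta``; it enters the wall velocities only through the
    product ``epsilon*alpha*beta``.
``hp``
    Radius of the central plug-flow region of the Casson fluid, where the
    shear stress is below the yield stress and the fluid moves as a rigid
    rod.  ``hp = 0`` recovers a Newtonian fluid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ParameterDomainError

__all__ = ["CiliaParams", "PumpState", "gamma_factor"]


def gamma_factor(epsilon: float) -> float:
    """Offset ``1 + epsilon**2 / 2`` between the time-mean lab-frame flow
    rate and the (constant) wave-frame flux: ``Qbar = q + 1 + 0.5*eps**2``."""
    return 1.0 + 0.5 * epsilon * epsilon


@dataclass(frozen=True)
class CiliaParams:
    """Nondimensional inputs of the ciliated-tube Casson pump.

    Raises
    ------
    ParameterDomainError
        If any parameter lies outside its validity domain.  The plug must
        fit inside the narrowest tube section: ``hp < 1 - epsilon``.
    """

    epsilon: float = 0.25
    alpha: float = 0.4
    beta: float = 0.4
    hp: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0:
            raise ParameterDomainError(
                f"epsilon must satisfy 0 <= epsilon < 1, got {self.epsilon}"
            )
        if self.alpha < 0.0:
            raise ParameterDomainError(f"alpha must be >= 0, got {self.alpha}")
        if not self.beta > 0.0:
            raise ParameterDomainError(f"beta must be > 0, got {self.beta}")
        if not 0.0 <= self.hp < 1.0 - self.epsilon:
            raise ParameterDomainError(
                f"hp must satisfy 0 <= hp < 1 - epsilon = {1.0 - self.epsilon}, "
                f"got {self.hp}"
            )

    @property
    def h_min(self) -> float:
        return 1.0 - self.epsilon

    @property
    def h_max(self) -> float:
        return 1.0 + self.epsilon

    def replace(self, **kwargs) -> "CiliaParams":
        vals = dict(
            epsilon=self.epsilon, alpha=self.alpha, beta=self.beta, hp=self.hp
        )
        vals.update(kwargs)
        return CiliaParams(**vals)


@dataclass(frozen=True)
class PumpState:
    """Operating point of the pump.

    Exactly one of the pressure rise per wavelength ``delta_p`` or the
    time-mean flow rate ``qbar`` drives the pump; the other follows from
    the linear characteristic ``delta_p = I1 - q*I2``.  The wave-frame
    flux ``q = qbar - 1 - 0.5*eps**2`` is constant along the tube.
    """

    q: float
    qbar: float
    delta_p: float

    @staticmethod
    def from_qbar(qbar: float, params: CiliaParams, integrals) -> "PumpState":
        q = qbar - gamma_factor(params.epsilon)
        return PumpState(q=q, qbar=qbar, delta_p=integrals.i1 - q * integrals.i2)

    @staticmethod
    def from_delta_p(delta_p: float, params: CiliaParams, integrals) -> "PumpState":
        q = (integrals.i1 - delta_p) / integrals.i2
        return PumpState(
            q=q, qbar=q + gamma_factor(params.epsilon), delta_p=delta_p
        )
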