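"""Exception hierarchy for ciliapump.

All parameter-validation failures derive from :class:`ParameterDomainError`
(a ``ValueError``) so callers can catch one type at the CLI boundary.
"""


class CiliapumpError(Exception):
    """Base class for all ciliapump errors."""


class ParameterDomainError(CiliapumpError, ValueError):
    """A parameter lies outside its physical validity domain."""


class UnboundedPlugError(ParameterDomainError):
    """Yield stress with zero pressure gradient: the plug fills the tube."""


class SingularKinematicsError(CiliapumpError, ZeroDivisionError):
    """The cilia-tip velocity denominator vanishes (envelope model breaks down)."""


class PlugExceedsTubeError(ParameterDomainError):
    """Plug radius Hp is not smaller than the local tube radius h."""


class QuadratureError(CiliapumpError, ArithmeticError):
    """Periodic quadrature failed to converge at the maximum resolution."""


class DegeneratePairError(ParameterDomainError):
    """A two-parameter comparison was requested with indistinguishable members."""


class ConfigurationError(CiliapumpError, ValueError):
    """Missing or inconsistent dimensional scales / CLI configuration."""


class ResolutionError(CiliapumpError, RuntimeError):
    """Field grid too coarse for unambiguous contour extraction."""
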