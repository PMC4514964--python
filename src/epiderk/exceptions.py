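"""Exception hierarchy for epiderk.

All errors derive from :class:`EpiderkError` so callers can catch the
package's failures with a single except clause; each subclass names the
contract that was violated.
"""


class EpiderkError(ValueError):
    """Base class for all epiderk errors."""


class ConfigError(EpiderkError):
    """Invalid configuration (nonpositive counts, unknown options, ...)."""


class DomainError(EpiderkError):
    """A coordinate lies outside its documented domain (u not in [0,3], d not in [0,7])."""


class DegeneratePositionError(EpiderkError):
    """Both boundary distances are zero; the within-layer position is undefined."""


class DegenerateGroupError(EpiderkError):
    """A z-scoring group has zero variance or too few samples."""


class InsufficientDataError(EpiderkError):
    """Too few points to fit a smoother in some tissue layer."""


class EmptyInputError(EpiderkError):
    """No samples fall into any spatial partition."""


class DegenerateInputError(EpiderkError):
    """A statistic's input has zero variance or is otherwise degenerate."""


class IncompatibleProfileError(EpiderkError):
    """Partition profiles use different partition schemes."""


class ParameterError(EpiderkError):
    """Model parameters violate their invariants."""


class NumericalError(EpiderkError):
    """The integrator or root-finder produced non-finite values or failed."""


class FitError(EpiderkError):
    """All optimization starts failed, or the fit is unidentifiable."""
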