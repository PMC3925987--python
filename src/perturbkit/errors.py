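"""Exception hierarchy.

Two failure classes matter operationally: bad input (rejected up front,
CLI exit code 2) and data that is structurally valid but does not permit
the requested estimate (CLI exit code 3).
"""


class PerturbkitError(Exception):
    """Base class for all package errors."""


class ValidationError(PerturbkitError, ValueError):
    """Input violates a structural precondition (bounds, shapes, columns)."""


class DegenerateExposureError(PerturbkitError):
    """All subjects exposed or all unexposed: crude risks undefined."""


class DegenerateRiskError(PerturbkitError):
    """Total standardized risk is zero: SRR undefined."""


class NonEstimableError(PerturbkitError):
    """No valid stratum (or zero denominator) after applying the
    invalid-stratum policy: the adjusted risk ratio cannot be computed."""
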