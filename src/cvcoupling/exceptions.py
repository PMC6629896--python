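"""Exception hierarchy for cvcoupling.

All package errors derive from :class:`CvCouplingError` so callers can catch
one base class at pipeline level while tests can assert the specific failure
mode (bad file, bad parameter, degenerate data ...).
"""


class CvCouplingError(Exception):
    """Base class for all cvcoupling errors."""


class FormatError(CvCouplingError):
    """A delimited input file is malformed (missing column, bad cell)."""


class ValidationError(CvCouplingError):
    """Data violates a structural invariant (empty series, SBP <= DBP ...)."""


class ParameterError(CvCouplingError):
    """An argument is outside its allowed range."""


class InsufficientDataError(CvCouplingError):
    """The series is too short for the requested operation."""


class DegenerateInputError(CvCouplingError):
    """Input is degenerate for the estimator (zero variance, all flagged ...)."""


class StabilityError(CvCouplingError):
    """A recursion or model is unstable (spectral radius >= 1)."""


class PairingError(CvCouplingError):
    """Two sequences cannot be paired (length or alphabet mismatch)."""
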