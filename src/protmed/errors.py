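"""Exception hierarchy for the MR screening pipeline.

Every error raised by the package derives from :class:`ProtmedError` so
callers can isolate pipeline failures per exposure/protein/outcome pair.
"""


class ProtmedError(Exception):
    """Base class for all package errors."""


class FormatError(ProtmedError):
    """A file does not conform to the documented on-disk dialect."""


class ValidationError(ProtmedError):
    """Records violate a domain invariant (se <= 0, p outside (0, 1], ...).

    Parameters
    ----------
    message : str
    rows : list of int, optional
        1-based data-row numbers of the offending records.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class EmptyOverlapError(ProtmedError):
    """Exposure and outcome share no variants after proxy substitution."""


class VariantLookupError(ProtmedError):
    """A requested variant is absent from the LD reference."""


class EmptyInstrumentError(ProtmedError):
    """No variant passes the instrument-selection thresholds."""


class DegenerateInstrumentError(ProtmedError):
    """A Wald ratio was requested for a variant with zero exposure effect."""


class InsufficientSNPsError(ProtmedError):
    """An estimator received fewer variants than its minimum."""


class CollinearityError(ProtmedError):
    """The multivariable design matrix is (numerically) rank deficient."""


class DomainError(ProtmedError):
    """An argument lies outside the mathematical domain of an operation."""
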