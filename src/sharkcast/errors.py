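"""Exception hierarchy shared across the package."""


class SharkcastError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SharkcastError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(SharkcastError):
    """One or more rows failed validation.

    Parameters
    ----------
    message :
        Human-readable summary.
    row_errors :
        Optional list of ``(row_number, message)`` pairs, 1-based and
        counted over data rows (the header is row 0).
    """

    def __init__(self, message, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class AlignmentError(SharkcastError):
    """Two series that must share year/region coverage do not."""


class DegenerateSeriesError(SharkcastError):
    """A series is degenerate for the requested operation (e.g. all zero)."""


class SamplerDegeneracyError(SharkcastError):
    """Residual pools are too small or too uniform to build a sampler."""


class FitError(SharkcastError):
    """A model fit failed to converge or produced an infeasible solution."""


class ConfigError(SharkcastError):
    """Invalid configuration value."""
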