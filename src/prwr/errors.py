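"""Exception hierarchy for prwr.

All package errors derive from :class:`PrwrError` so callers can catch one
type at the CLI boundary while tests assert the precise subclass.
"""


class PrwrError(Exception):
    """Base class for all errors raised by prwr."""


class DataError(PrwrError):
    """Malformed or empty input data."""


class FormatError(DataError):
    """A file does not conform to the documented CSV layout."""


class AlignmentError(DataError):
    """Occurrence sites are missing from the environment table."""


class ConsistencyError(PrwrError):
    """Two objects that must share provenance do not (e.g. weights not
    derived from the matrix being scored, or a predictor column missing)."""


class ConfigError(PrwrError):
    """An invalid configuration value (subset too small, bad q, ...)."""


class PreprocessingError(PrwrError):
    """A variable cannot enter the analysis (e.g. zero variance)."""


class CapabilityError(PrwrError):
    """The requested exact computation is infeasible at this problem size."""


class EvaluationError(PrwrError):
    """An evaluation produced no usable steps (e.g. all steps degenerate)."""
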