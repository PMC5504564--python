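"""Exception hierarchy for semgrecal."""


class SemgrecalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SemgrecalError):
    """A configuration object failed validation; the message names the field."""


class FormatError(SemgrecalError):
    """An input file is missing a required variable or is otherwise malformed."""


class AlignmentError(SemgrecalError):
    """Signal, label and repetition streams disagree in length."""


class VersionError(SemgrecalError):
    """An internal container was written by an incompatible schema version."""


class EmptySelectionError(SemgrecalError):
    """A repetition split selected no samples."""


class ParameterError(SemgrecalError):
    """An operation received parameters inconsistent with its input."""


class DivergenceError(SemgrecalError):
    """Training produced a non-finite loss."""
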