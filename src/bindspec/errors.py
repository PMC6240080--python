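"""Exception hierarchy shared by all analysis stages."""


class BindspecError(Exception):
    """Base class for all bindspec errors."""


class SpectrumParseError(BindspecError):
    """A spectrum file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class InsufficientDataError(BindspecError):
    """Fewer usable data points than the operation requires."""


class OrderingError(BindspecError):
    """Titration concentrations are not strictly increasing."""


class MissingReferenceError(BindspecError):
    """The quencher-free reference point (F0) is absent."""


class OutOfRangeError(BindspecError):
    """A requested axis position lies outside the recorded range."""


class IncompatibleGridError(BindspecError):
    """Two spectra do not share a usable common axis."""


class InvalidInputError(BindspecError):
    """An argument violates the operation's preconditions."""


class DegenerateSignalError(BindspecError):
    """A fluorescence intensity is zero or negative where positivity is required."""


class InvalidCompositionError(InvalidInputError):
    """Structure fractions are negative or do not sum to one."""
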