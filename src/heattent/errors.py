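"""Exception hierarchy shared across the package."""


class HeatTentError(Exception):
    """Base class for all package errors."""


class ConfigError(HeatTentError):
    """Invalid configuration or specification values."""


class DomainError(HeatTentError):
    """Argument outside the physically meaningful domain of an operation."""


class SimulationError(HeatTentError):
    """Closed-loop simulation cannot proceed (e.g. weather gap)."""


class AlignmentError(HeatTentError):
    """Sensor streams have no usable temporal overlap."""


class LogParseError(HeatTentError):
    """Malformed controller log row."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class IncompleteDesignError(HeatTentError):
    """A genotype is missing a treatment arm in a trial table."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "genotypes missing a treatment arm: " + ", ".join(map(str, self.offenders))
        )


class EmptyWindowError(HeatTentError):
    """A statistic was requested over a window containing no samples."""
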