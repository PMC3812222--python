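"""Exception hierarchy shared across the toolkit."""


class BoltzwalkerError(Exception):
    """Base class for all toolkit errors."""


class TrajectoryParseError(BoltzwalkerError):
    """A trajectory file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyTrajectoryError(BoltzwalkerError):
    """A preprocessing step left no usable points."""


class DegenerateGeometryError(BoltzwalkerError):
    """An operation received geometrically degenerate input (identical points,
    zero resultant, zero duration...)."""


class ConfigError(BoltzwalkerError):
    """Invalid parameter or configuration value."""


class EmptySectorError(BoltzwalkerError):
    """A heading sector required for simulation has no observations."""
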