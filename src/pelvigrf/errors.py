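"""Exception types raised by the pipeline stages."""


class PelvigrfError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PelvigrfError, ValueError):
    """A parameter is outside its valid range (e.g. cutoff beyond Nyquist)."""


class TooShortError(PelvigrfError, ValueError):
    """A series is too short for the requested operation."""


class NotStillError(PelvigrfError, ValueError):
    """A window supposed to be motionless shows too much angular rate."""


class DegenerateCalibrationError(PelvigrfError, ValueError):
    """Bowing axis indistinguishable from vertical; calibration impossible."""


class DegenerateHeadingError(PelvigrfError, ValueError):
    """Step velocity has no usable horizontal component."""


class BootstrapError(PelvigrfError, ValueError):
    """Not enough steps to bootstrap the initial heading."""


class SchemaError(PelvigrfError, ValueError):
    """A CSV or config file does not match its documented schema."""


class PipelineStageError(PelvigrfError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
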