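"""Exception hierarchy shared across the package."""


class ImagingGremlError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ImagingGremlError, ValueError):
    """Invalid configuration value (range, shape or consistency violation)."""


class ParseError(ImagingGremlError, ValueError):
    """Malformed input file; the message names the offending line/field."""


class DecompositionError(ImagingGremlError, ValueError):
    """A matrix required to be positive (semi-)definite is not."""


class DesignError(ImagingGremlError, ValueError):
    """Block design and volume count are inconsistent."""


class QcError(ImagingGremlError, ValueError):
    """An operation received data that violates its QC preconditions."""


class OptimizerError(ImagingGremlError, RuntimeError):
    """Internal optimizer fault (e.g. full-model likelihood below the null)."""


class PipelineError(ImagingGremlError, RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")
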