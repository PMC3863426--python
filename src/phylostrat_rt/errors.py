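"""Exception hierarchy shared across the pipeline stages."""


class PhylostratRTError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhylostratRTError):
    """A configuration value is invalid or inconsistent."""


class DataError(PhylostratRTError):
    """Input data violates a documented contract."""


class GeneTreeParseError(DataError):
    """A gene-family tree could not be parsed from NHX text."""


class CapacityError(ConfigurationError):
    """More genes requested than fit on the simulated chromosomes."""


class PipelineStageError(PhylostratRTError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
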