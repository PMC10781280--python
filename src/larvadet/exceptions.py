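"""Exception hierarchy used across the pipeline."""


class LarvadetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LarvadetError, ValueError):
    """A configuration value is invalid (unknown wavelet family, bad spec)."""


class SceneError(LarvadetError, ValueError):
    """A synthetic scene specification violates its geometric constraints."""


class FormatError(LarvadetError, ValueError):
    """An image does not have the expected layout (e.g. channel count)."""


class InputError(LarvadetError, ValueError):
    """An input array is unusable for the requested operation."""


class UsageError(LarvadetError, ValueError):
    """An operation was called with arguments outside its contract."""


class PipelineError(LarvadetError, RuntimeError):
    """An end-to-end pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
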