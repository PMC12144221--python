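"""Exception hierarchy shared across the pipeline stages."""


class PhantomQAError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhantomQAError):
    """A parameter set does not cover the requested lesion/reconstruction,
    or a config file is inconsistent."""


class ValidationError(PhantomQAError):
    """An input value is outside its documented domain."""


class FormatError(PhantomQAError):
    """An image stack or table is not in the expected format
    (non-RGB pixels, mixed dimensions, missing slice indices, ...)."""


class RenderError(PhantomQAError):
    """A synthetic label cannot be drawn (blob entirely outside bounds)."""


class CompletenessError(PhantomQAError):
    """A table does not cover the full study design; carries the gaps."""

    def __init__(self, message: str, missing: list | None = None):
        super().__init__(message)
        self.missing = missing or []
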