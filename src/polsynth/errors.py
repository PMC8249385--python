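"""Exception types shared across the package."""


class PolsynthError(Exception):
    """Base class for package errors."""


class ConfigurationError(PolsynthError, ValueError):
    """Invalid or inconsistent configuration."""


class EmptyResultError(PolsynthError, ValueError):
    """An operation would return an empty image or dataset."""


class EmptyMaskError(PolsynthError, ValueError):
    """No pixel survives the intensity threshold."""
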