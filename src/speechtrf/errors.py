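"""Exception hierarchy shared across the package."""


class SpeechTRFError(Exception):
    """Base class for all package errors."""


class ConfigError(SpeechTRFError):
    """Invalid configuration or argument combination."""


class DataError(SpeechTRFError):
    """Malformed, missing, or inconsistent data."""


class FitError(SpeechTRFError):
    """Model estimation cannot proceed (e.g., zero-variance input)."""
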