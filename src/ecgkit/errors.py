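"""Exception hierarchy shared across the toolkit."""


class EcgKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(EcgKitError, ValueError):
    """A parameter or configuration value is invalid or infeasible."""


class FormatError(EcgKitError, ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(EcgKitError, ValueError):
    """A file parses but is internally inconsistent (lengths, truncation)."""
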