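"""Package-wide exception types."""


class PsnAtlasError(Exception):
    """Base class for all errors raised by psn_atlas."""


class ConfigurationError(PsnAtlasError):
    """A parameter or configuration object violates its contract."""


class InputError(PsnAtlasError):
    """An input object (matrix, table, trace) is missing required content."""
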