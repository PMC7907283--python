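"""Exception hierarchy for mifscape."""


class MifscapeError(Exception):
    """Base class for all mifscape errors."""


class FormatError(MifscapeError):
    """Malformed input table (missing column, unparseable value)."""


class IntegrityError(MifscapeError):
    """Input violates a data-model invariant (e.g. duplicate cell_id)."""


class ConfigurationError(MifscapeError):
    """Invalid or inconsistent configuration."""


class ParameterError(MifscapeError):
    """Invalid parameter value passed to an operation."""
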