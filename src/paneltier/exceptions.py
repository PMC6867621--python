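"""Exception hierarchy used across the package."""


class PanelTierError(Exception):
    """Base class for all package errors."""


class ParseError(PanelTierError):
    """A file could not be parsed (malformed line, bad token)."""


class SchemaError(PanelTierError):
    """A table is missing required columns/fields or holds unknown enum tokens."""


class ValidationError(PanelTierError, ValueError):
    """Parsed content violates a domain invariant (empty panel, VAF outside [0,1], ...)."""


class ConfigError(PanelTierError):
    """A pipeline configuration is missing a required key or names a missing input."""


class StateError(PanelTierError):
    """An operation was invoked on an object not yet in the required processing state."""
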