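"""Exception hierarchy shared across the package."""


class IslandscopeError(Exception):
    """Base class for all package errors."""


class FormatError(IslandscopeError):
    """A file or serialized payload does not parse under its declared format."""


class ValidationError(IslandscopeError):
    """An object violates a domain invariant (coordinates, labels, config)."""


class ConfigurationError(IslandscopeError):
    """A configuration names an unavailable resource (e.g. missing weights)."""


class LookupError_(IslandscopeError):
    """A referenced identifier (gene, genome) does not exist."""
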