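"""Exception hierarchy."""


class VomError(Exception):
    """Base class for package errors."""


class ConfigurationError(VomError, ValueError):
    """Invalid configuration or specification values."""


class FormatError(VomError, ValueError):
    """Malformed input file."""


class DomainError(VomError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class InvariantError(VomError, ValueError):
    """A model invariant (e.g. cover constraint) would be violated."""
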