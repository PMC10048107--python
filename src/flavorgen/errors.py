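"""Exception hierarchy shared across the package."""


class FlavorgenError(Exception):
    """Base class for all package errors."""


class ValidityError(FlavorgenError):
    """A SMILES string or molecular graph is chemically invalid."""

    def __init__(self, message: str, smiles: str | None = None):
        super().__init__(message)
        self.smiles = smiles


class InvalidActionError(FlavorgenError):
    """A graph-building action cannot be applied to the current graph."""


class UnsupportedInputError(FlavorgenError):
    """Structurally valid input outside the supported domain (e.g. disconnected)."""


class FormatError(FlavorgenError):
    """A data file does not match its documented layout."""


class ConfigError(FlavorgenError):
    """A configuration value violates its invariant."""


class SizeError(FlavorgenError):
    """A graph exceeds the model's node capacity."""


class ContractError(FlavorgenError):
    """A caller violated an operation's precondition."""
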