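"""Exception hierarchy shared across the package."""


class CamagreeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CamagreeError, ValueError):
    """Invalid configuration value (sizes, fractions, severities, ...)."""


class DomainError(CamagreeError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ContractError(CamagreeError, ValueError):
    """Inputs violate an operation's shape/pairing contract."""


class DegenerateInputError(CamagreeError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant image)."""


class TrainingError(CamagreeError, RuntimeError):
    """Training diverged; carries the per-epoch trace gathered so far."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []
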