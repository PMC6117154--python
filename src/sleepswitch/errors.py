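"""Exception types shared across the package."""


class SleepSwitchError(Exception):
    """Base class for package errors."""


class ConfigurationError(SleepSwitchError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class FormatError(SleepSwitchError, ValueError):
    """An input trace or table violates a structural contract."""


class EmptySelectionError(SleepSwitchError, ValueError):
    """A subset filter left no trials/flies to analyze."""


class InsufficientDataError(SleepSwitchError, ValueError):
    """Too few observations for the requested computation."""


class ContractError(SleepSwitchError, ValueError):
    """Caller passed data that violates an operation's precondition."""


class DependencyError(SleepSwitchError, RuntimeError):
    """A required upstream analysis stage is missing."""
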