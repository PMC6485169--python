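"""Exception types shared across the package."""


class EvoDiverseError(Exception):
    """Base class for all package-specific errors."""


class InputError(EvoDiverseError, ValueError):
    """A caller-supplied value violates an operation's preconditions."""


class FormatError(EvoDiverseError, ValueError):
    """A file being parsed does not follow the expected format."""


class BudgetExhausted(EvoDiverseError):
    """Raised by a capped ScoreModel when the evaluation budget is spent."""
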