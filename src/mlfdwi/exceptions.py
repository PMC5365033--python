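"""Exception types shared across the package."""


class MlfdwiError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MlfdwiError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class AccuracyError(MlfdwiError, ArithmeticError):
    """A numerical routine could not reach the requested accuracy.

    The message names the accuracy actually achieved where it is known.
    """


class InputError(MlfdwiError, ValueError):
    """User-supplied data (curves, images, b-value tables) is malformed
    or inconsistent."""


class ConfigError(MlfdwiError, ValueError):
    """An invalid configuration value (unknown law, model, or class name)."""
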